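# restwise

**Reliability-gated analysis of resting-state EEG measures.**

Resting-state EEG yields two popular families of candidate trait
markers: oscillatory **band power** (delta 1–4, theta 4–8, alpha 8–14,
beta 14–30, gamma 30–75 Hz; absolute and relative) and **microstate**
statistics (mean GFP, mean duration, occurrence, coverage of a few
prototypical scalp topographies). Findings that relate these measures
to cognition are notoriously inconsistent, and a prime suspect is
measurement reliability: a measure that does not agree with itself
across sessions cannot correlate stably with anything else. `restwise`
implements the full workflow for a two-session design:

1. extract band-power and microstate measures from multichannel
   resting-state recordings,
2. estimate **test-retest reliability** with ICC(2,1) and
   **split-half reliability** with the Spearman–Brown correction,
3. admit only measures passing a dual gate (ICC ≥ 0.75 *and* both
   sessions' split-half ≥ 0.75) to a Bonferroni-controlled Pearson
   screen against a behavioral long-term-memory change score
   (session-2 minus session-1 vocabulary percentage),

plus a **synthetic cohort generator** that plants known variance
components, microstate dwell processes, and behavior correlations, so
every stage can be validated end to end without any recordings.

It is aimed at EEG researchers running longitudinal or test-retest
designs, and at methodologists who want a fully seeded, reproducible
reference implementation of the reliability-gated screening workflow.

## The statistics at the core

**ICC(2,1)** — two-way random-effects, absolute agreement, single
measurement. With subjects × sessions mean squares MS_B (between
subjects), MS_R (between sessions), MS_E (residual), k sessions and n
subjects:

```
ICC(2,1) = (MS_B − MS_E) / (MS_B + (k−1)·MS_E + k·(MS_R − MS_E)/n)
```

The test against zero uses F = MS_B/MS_E on (n−1, (n−1)(k−1)) df; the
95% CI is the Shrout–Fleiss/McGraw–Wong F-based interval. Absolute
agreement penalizes constant session offsets — a desirable property for
trait markers.

**Split-half reliability** — each recording is split into contiguous
halves, measures computed per half, correlated across subjects, and
stepped up to full length with Spearman–Brown: r_full = 2r/(1+r).

**Microstates** — polarity-invariant modified k-means on GFP-peak
topographies (assignment by squared spatial correlation, template
update by the dominant eigenvector of the assigned maps' cross-product
matrix, best of 20 restarts by global explained variance), hierarchical
aggregation to grand-mean templates, backfitting by maximal absolute
spatial correlation, and per-class duration/occurrence/coverage/GFP.

**Association screen** — per measure-outcome pair, subjects beyond
2 SD on either variable are excluded (single pass), then Pearson r with
Fisher-z CIs; p-values are Bonferroni-corrected by the family size m
(the number of correlations computed, or a study-wide m such as 21).

## Worked example

Simulate a small two-session cohort, run the whole pipeline, and look
at the reliability gate and the gated screen:

```python
from restwise import PipelineConfig, run_all

cfg = PipelineConfig(n_subjects=12, n_channels=16, srate=250.0,
                     duration_s=10.0, microstate_restarts=5, seed=42)
res = run_all(cfg, "out")
print(res["reliability"].summary().head(10).round(2).to_string(index=False))
```

```
  measure  icc  ci_lo  ci_hi    p  splithalf_T1  splithalf_T2  reliable  n_icc
abs_delta 0.71   0.24   0.91 0.00          0.99          0.99     False     12
rel_delta 0.51  -0.07   0.83 0.04          0.99          0.99     False     12
abs_theta 0.40  -0.22   0.78 0.10          0.98          0.99     False     12
rel_theta 0.43  -0.20   0.80 0.08          0.99          0.99     False     12
abs_alpha 0.91   0.72   0.97 0.00          0.99          1.00      True     12
rel_alpha 0.91   0.72   0.97 0.00          1.00          1.00      True     12
 abs_beta 0.81   0.41   0.94 0.00          0.99          1.00      True     12
 rel_beta 0.69   0.24   0.90 0.00          1.00          0.99     False     12
abs_gamma 0.61   0.08   0.87 0.02          1.00          1.00     False     12
rel_gamma 0.38  -0.26   0.78 0.11          0.99          0.99     False     12
```

Split-half coefficients are uniformly high (within-session stability),
while the test-retest ICC separates the bands: the generator plants the
highest between-subject stability in the alpha band, and the gate
admits alpha (and here beta) power while rejecting the rest — even
though every measure came from identical processing. The gated screen
then reports, per admitted measure, the correlation with the vocabulary
change score:

```
  measure     r  ci_lo  ci_hi  df  p_raw  p_bonferroni  n_used
abs_alpha 0.197 -0.457  0.713   9  0.561         1.000      11
rel_alpha 0.445 -0.173  0.812  10  0.147         0.441      12
 abs_beta 0.388 -0.239  0.787  10  0.212         0.636      12
```

(at n = 12 nothing survives correction, as it should). The paired
session comparison is available as
`res["behavior_tests"]["paired_t"]` → `t(11) = 10.37, p = 5.1e-07,
d = 2.99` for this cohort's planted vocabulary gain.

The same stages are exposed on the command line:

```bash
restwise simulate --n 12 --channels 16 --srate 250 --duration 10 --seed 42 --out sim/
restwise run-all --seed 42 --out out/
restwise microstates --in sim/S001_T1.vhdr --k 4 --restarts 20 --seed 7 --out maps.json
```

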