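"""ICC(2,1), split-half machinery, and the dual reliability gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from restwise.eeg_io import Recording
from restwise.reliability import (
    ReliabilityAnalysis,
    icc_2_1,
    spearman_brown,
    split_measure,
)

from conftest import make_recording


def icc_2_1_oracle(x: np.ndarray) -> float:
    """Independent explicit-summation two-way ANOVA oracle."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((r - grand) ** 2 for r in row)
    ssr = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msb = ssb / (n - 1)
    msr = ssr / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msb - mse) / (msb + (k - 1) * mse + k * (msr - mse) / n)


class TestIcc21:
    def test_perfect_agreement_is_one(self):
        x = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5.0]])
        r = icc_2_1(x)
        assert r.icc == 1.0
        assert r.ci95 == (1.0, 1.0)
        assert r.p_value == 0.0

    def test_constant_offset_penalized(self):
        base = np.array([1, 2, 3, 4, 5.0])
        x = np.column_stack([base, base + 2.0])
        assert icc_2_1(x).icc < 1.0

    def test_matches_summation_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 31))
            x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            assert icc_2_1(x).icc == pytest.approx(icc_2_1_oracle(x), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for trial in range(25):
            n = int(rng.integers(4, 40))
            x = rng.normal(size=(n, 2)) + 0.8 * rng.normal(size=(n, 1))
            r = icc_2_1(x)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), 2),
                    "raters": np.tile([0, 1], n),
                    "scores": x.ravel(),
                }
            )
            row = pg.intraclass_corr(df, "targets", "raters", "scores")
            row = row[row["Type"] == "ICC(A,1)"].iloc[0]
            assert r.icc == pytest.approx(row["ICC"], abs=1e-10)
            assert r.f_stat == pytest.approx(row["F"], abs=1e-8)
            assert r.p_value == pytest.approx(row["pval"], abs=1e-10)
            # pingouin rounds its CI to 2 decimals
            assert np.allclose(r.ci95, row["CI95"], atol=6e-3)

    def test_shift_and_scale_invariance(self, rng):
        x = rng.normal(size=(10, 2))
        a = icc_2_1(x).icc
        assert icc_2_1(x + 13.7).icc == pytest.approx(a, abs=1e-10)
        assert icc_2_1(x * 4.2).icc == pytest.approx(a, abs=1e-10)

    def test_all_identical_reported_missing(self):
        r = icc_2_1(np.full((5, 2), 3.0))
        assert not r.defined
        assert "identical" in r.msg

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            icc_2_1(np.zeros((2, 2)))

    def test_negative_estimates_not_truncated(self, rng):
        # anti-correlated sessions → negative ICC by the formula
        base = np.array([1.0, 2, 3, 4, 5, 6])
        x = np.column_stack([base, base[::-1]])
        assert icc_2_1(x).icc < 0

    def test_planted_icc_point_recovery(self):
        rng = np.random.default_rng(77)
        truth = 0.75
        sb, se = np.sqrt(truth), np.sqrt(1 - truth)
        est = []
        for _ in range(200):
            b = sb * rng.standard_normal((100, 1))
            x = b + se * rng.standard_normal((100, 2))
            est.append(icc_2_1(x).icc)
        assert abs(np.mean(est) - truth) <= 0.02

    def test_ci_coverage_at_n90(self):
        rng = np.random.default_rng(42)
        truth = 0.75
        sb, se = np.sqrt(truth), np.sqrt(1 - truth)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            b = sb * rng.standard_normal((90, 1))
            x = b + se * rng.standard_normal((90, 2))
            lo, hi = icc_2_1(x).ci95
            hits += lo <= truth <= hi
        assert 92.0 <= 100.0 * hits / n_rep <= 98.0


class TestSplitMeasure:
    def test_even_split(self):
        rec = make_recording(np.zeros((2, 180_000)), srate=1000.0)
        a, b = split_measure(rec)
        assert a.n_samples == b.n_samples == 90_000

    def test_odd_split_extra_sample_first(self):
        rec = make_recording(np.zeros((2, 181)), srate=1.0)
        a, b = split_measure(rec)
        assert (a.n_samples, b.n_samples) == (91, 90)

    def test_concatenation_identity(self, rng):
        rec = make_recording(rng.normal(size=(3, 101)))
        a, b = split_measure(rec)
        assert np.array_equal(np.concatenate([a.data, b.data], axis=1), rec.data)


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.0), (0.6, 0.75)])
    def test_closed_form(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected, abs=1e-12)

    def test_undefined_at_minus_one(self):
        assert np.isnan(spearman_brown(-1.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(-0.999, 1.0),
        gap=st.floats(1e-6, 0.5),
    )
    def test_monotone_increasing(self, a, gap):
        b = min(a + gap, 1.0)
        if b > a:
            assert spearman_brown(b) > spearman_brown(a)


def _long_table(values: np.ndarray, measure: str) -> pd.DataFrame:
    n = values.shape[0]
    rows = []
    for i in range(n):
        rows.append((f"S{i}", "T1", measure, values[i, 0]))
        rows.append((f"S{i}", "T2", measure, values[i, 1]))
    return pd.DataFrame(rows, columns=["subject_id", "session", "measure", "value"])


def _half_table(h1: np.ndarray, h2: np.ndarray, measure: str) -> pd.DataFrame:
    rows = []
    for sess in ("T1", "T2"):
        for i in range(h1.shape[0]):
            rows.append((f"S{i}", sess, 1, measure, h1[i]))
            rows.append((f"S{i}", sess, 2, measure, h2[i]))
    return pd.DataFrame(
        rows, columns=["subject_id", "session", "half", "measure", "value"]
    )


class TestReliabilityGate:
    def test_reliable_when_all_components_high(self, rng):
        # strong trait, light session/half noise → all three coefficients high
        trait = rng.normal(size=(40, 1))
        full = trait + 0.25 * rng.normal(size=(40, 2))
        h = trait[:, 0]
        res = ReliabilityAnalysis(
            _long_table(full, "m"),
            _half_table(h + 0.1 * rng.normal(size=40), h + 0.1 * rng.normal(size=40), "m"),
        ).fit(threshold=0.75)
        row = res.table.iloc[0]
        assert row.icc >= 0.75 and row.splithalf_T1 >= 0.75 and row.splithalf_T2 >= 0.75
        assert bool(row.reliable)

    def test_low_icc_fails_gate_despite_high_split_half(self, rng):
        full = rng.normal(size=(40, 2))  # no trait: ICC ≈ 0
        h = rng.normal(size=40)
        res = ReliabilityAnalysis(
            _long_table(full, "m"),
            _half_table(h, h + 1e-6 * rng.normal(size=40), "m"),
        ).fit(threshold=0.75)
        row = res.table.iloc[0]
        assert row.icc < 0.75 and row.splithalf_T1 > 0.99
        assert not bool(row.reliable)

    def test_low_split_half_fails_gate_despite_high_icc(self, rng):
        trait = rng.normal(size=(40, 1))
        full = trait + 0.1 * rng.normal(size=(40, 2))  # ICC ≈ 0.99
        res = ReliabilityAnalysis(
            _long_table(full, "m"),
            _half_table(rng.normal(size=40), rng.normal(size=40), "m"),
        ).fit(threshold=0.75)
        row = res.table.iloc[0]
        assert row.icc > 0.9
        assert not bool(row.reliable)

    def test_missing_sessions_dropped_listwise_and_counted(self, rng):
        full = _long_table(rng.normal(size=(10, 2)), "m")
        full = full.drop(full[(full.subject_id == "S3") & (full.session == "T2")].index)
        res = ReliabilityAnalysis(full).fit()
        assert res.table.iloc[0].n_icc == 9
        assert res.table.iloc[0].n_dropped == 1
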