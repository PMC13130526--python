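"""End-to-end orchestration: simulate/load → preprocess → band power →
microstates → reliability → association, with provenance.

Every stage is a pure function of (inputs, config, seed); the run
manifest (config hash, seed, package versions) suffices to reproduce
any output table bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationScreen, ltm_change, paired_change_test
from .eeg_io import Recording, read_behavior, read_recording, write_table
from .microstates import (
    TopographySet,
    aggregate_templates,
    backfit,
    gfp,
    gfp_peaks,
    microstate_stats,
    modified_kmeans,
)
from .preprocess import PreprocessConfig, preprocess
from .reliability import ReliabilityAnalysis, split_measure
from .spectral import DEFAULT_BANDS, band_power_table
from .synthetic_data import CohortSpec, TraitSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("restwise")


@dataclass
class PipelineConfig:
    """Declarative run description; round-trips losslessly through YAML."""

    simulate: bool = True
    # synthetic cohort (used when simulate=True)
    n_subjects: int = 36
    n_channels: int = 64
    srate: float = 1000.0
    duration_s: float = 180.0
    group: str = "adults"  # trait preset: adults | children
    # real-data inputs (used when simulate=False)
    input_dir: str | None = None
    behavior_file: str | None = None
    # preprocessing; None → PreprocessConfig.for_srate(srate)
    preprocess: dict | None = None
    # microstates
    microstate_k: int = 4
    microstate_restarts: int = 20
    # statistics
    reliability_threshold: float = 0.75
    family_size: str | int = "auto"
    outlier_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.reliability_threshold <= 1:
            raise ValueError("reliability threshold must be in (0, 1]")
        if self.outlier_sd <= 0:
            raise ValueError("outlier SD multiplier must be positive")
        if isinstance(self.family_size, str) and self.family_size != "auto":
            raise ValueError("family_size must be 'auto' or an integer")

    def preprocess_config(self) -> PreprocessConfig:
        if self.preprocess is None:
            return PreprocessConfig.for_srate(self.srate)
        return PreprocessConfig(**self.preprocess)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


MS_STATS = ("mean_gfp", "duration_ms", "occurrence", "coverage_pct")


def _power_long(table: pd.DataFrame) -> pd.DataFrame:
    """Band-power table → long (subject, session, measure, value) rows.

    Absolute powers enter on the log10 scale (the scale used for
    statistics); relative powers as fractions.
    """
    rows = []
    for _, r in table.iterrows():
        rows.append((r.subject_id, r.session, f"abs_{r.band}", r.log10_abs))
        rows.append((r.subject_id, r.session, f"rel_{r.band}", r.rel))
    return pd.DataFrame(rows, columns=["subject_id", "session", "measure", "value"])


def _ms_long(stats: pd.DataFrame, subject: str, session: str) -> list[tuple]:
    rows = []
    for _, r in stats.iterrows():
        c = int(r["class"])
        for stat in MS_STATS:
            rows.append((subject, session, f"ms{c}_{stat}", r[stat]))
    return rows


def _load_recordings(config: PipelineConfig) -> tuple[list[Recording], pd.DataFrame]:
    root = Path(config.input_dir)
    recs = []
    for path in sorted(list(root.glob("*.vhdr")) + list(root.glob("*.edf"))):
        # filenames follow <subject>_<session>.<ext>
        stem = path.stem
        try:
            subject, session = stem.rsplit("_", 1)
        except ValueError as exc:
            raise ValueError(f"cannot parse subject/session from {path.name}") from exc
        recs.append(read_recording(path, subject_id=subject, session=session))
    if not recs:
        raise FileNotFoundError(f"no .vhdr/.edf recordings under {root}")
    behavior = read_behavior(config.behavior_file)
    return recs, behavior


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; writes result tables and a manifest to out_dir.

    Returns the in-memory results: band powers, microstate stats and
    templates, the reliability table, the gated association table, and
    behavioral tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    cohort_truth = None
    if config.simulate:
        cohort = CohortSpec(
            n_subjects=config.n_subjects,
            n_channels=config.n_channels,
            srate=config.srate,
            duration_s=config.duration_s,
            seed=config.seed,
        )
        traits = (
            TraitSpec.children() if config.group == "children" else TraitSpec.adults()
        )
        log.info("simulating cohort: %s", cohort)
        data = simulate_cohort(cohort, traits)
        recordings, behavior = data.recordings, data.behavior
        cohort_truth = data.truth
    else:
        recordings, behavior = _load_recordings(config)

    pp_cfg = config.preprocess_config()
    clean = [preprocess(r, pp_cfg) for r in recordings]

    # --- spectral stage -----------------------------------------------------
    power_full = band_power_table(clean)
    halves = {idx: split_measure(rec) for idx, rec in enumerate(clean)}
    half_rows = []
    for idx, rec in enumerate(clean):
        for h, part in enumerate(halves[idx], start=1):
            t = band_power_table([part])
            for _, r in t.iterrows():
                half_rows.append(
                    (rec.subject_id, rec.session, h, f"abs_{r.band}", r.log10_abs)
                )
                half_rows.append((rec.subject_id, rec.session, h, f"rel_{r.band}", r.rel))

    # --- microstate stage ---------------------------------------------------
    indiv_sets = []
    for idx, rec in enumerate(clean):
        trace = gfp(rec)
        peaks = gfp_peaks(trace)
        maps = rec.data[:, peaks].T
        topo, _ = modified_kmeans(
            maps,
            config.microstate_k,
            rec.channel_labels,
            n_restarts=config.microstate_restarts,
            seed=config.seed + idx,
        )
        indiv_sets.append(topo)
    by_session: dict[str, list[TopographySet]] = {}
    for rec, topo in zip(clean, indiv_sets):
        by_session.setdefault(rec.session, []).append(topo)
    session_means = [
        aggregate_templates(
            sets, config.microstate_k, seed=config.seed, source="group_mean"
        )
        for _, sets in sorted(by_session.items())
    ]
    grand = aggregate_templates(
        session_means, config.microstate_k, seed=config.seed, source="grand_mean"
    )

    ms_rows, ms_half_rows = [], []
    ms_stats_tables = []
    for idx, rec in enumerate(clean):
        seg = backfit(rec, grand)
        stats = microstate_stats(seg)
        stats.insert(0, "session", rec.session)
        stats.insert(0, "subject_id", rec.subject_id)
        ms_stats_tables.append(stats)
        ms_rows.extend(_ms_long(stats, rec.subject_id, rec.session))
        for h, part in enumerate(halves[idx], start=1):
            hstats = microstate_stats(backfit(part, grand))
            for row in _ms_long(hstats, rec.subject_id, rec.session):
                ms_half_rows.append((row[0], row[1], h, row[2], row[3]))

    full_long = pd.concat(
        [
            _power_long(power_full),
            pd.DataFrame(ms_rows, columns=["subject_id", "session", "measure", "value"]),
        ],
        ignore_index=True,
    )
    half_long = pd.DataFrame(
        half_rows + ms_half_rows,
        columns=["subject_id", "session", "half", "measure", "value"],
    )

    # --- reliability stage --------------------------------------------------
    rel_results = ReliabilityAnalysis(full_long, half_long).fit(
        threshold=config.reliability_threshold
    )

    # --- association stage --------------------------------------------------
    ltm = ltm_change(behavior)
    t1_wide = (
        full_long[full_long["session"] == "T1"]
        .pivot(index="subject_id", columns="measure", values="value")
        .reset_index()
    )
    family = None if config.family_size == "auto" else int(config.family_size)
    assoc = AssociationScreen(
        t1_wide,
        ltm,
        rel_results.reliable_measures,
        family_size=family,
        sd_mult=config.outlier_sd,
    ).fit()
    behavior_tests = {"paired_t": paired_change_test(behavior)}

    # --- outputs ------------------------------------------------------------
    write_table(power_full, out / "band_powers.csv")
    write_table(pd.concat(ms_stats_tables, ignore_index=True), out / "microstate_stats.csv")
    grand.to_json(out / "microstate_templates.json")
    rel_results.to_csv(out / "reliability.csv")
    assoc.to_csv(out / "associations.csv")
    write_table(behavior, out / "behavior.csv")

    manifest = {
        "restwise_version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": yaml.safe_load(config.to_yaml()),
        "n_recordings": len(clean),
        "family_size": assoc.family_size,
        "behavior_tests": {
            k: {kk: (None if isinstance(vv, float) and np.isnan(vv) else vv)
                for kk, vv in v.items()}
            for k, v in behavior_tests.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("wrote results to %s", out)

    return {
        "band_powers": power_full,
        "measures_full": full_long,
        "measures_half": half_long,
        "microstate_templates": grand,
        "reliability": rel_results,
        "associations": assoc,
        "behavior": behavior,
        "behavior_tests": behavior_tests,
        "truth": cohort_truth,
    }
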