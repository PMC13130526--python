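"""Test-retest and split-half reliability of per-subject measures.

Test-retest reliability is ICC(2,1): the intraclass correlation from a
two-way random-effects ANOVA (subjects × sessions), absolute agreement,
single measurement,

    ICC(2,1) = (MS_B − MS_E) / (MS_B + (k−1) MS_E + k (MS_R − MS_E) / n)

with the F-test against zero using F = MS_B / MS_E on (n−1, (n−1)(k−1))
degrees of freedom and the Shrout–Fleiss/McGraw–Wong F-based 95% CI.
Split-half reliability is the Pearson correlation across subjects
between the two half-recording values, stepped up to full length with
the Spearman–Brown formula 2r/(1+r). A measure passes the reliability
gate when ICC and both sessions' split-half coefficients are all at or
above the threshold (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .eeg_io import Recording

__all__ = [
    "ICCResult",
    "icc_2_1",
    "split_measure",
    "spearman_brown",
    "ReliabilityAnalysis",
    "ReliabilityResults",
]


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n_used: int
    msg: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.icc)


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects × sessions) ANOVA mean squares (MS_B, MS_R, MS_E)."""
    n, k = x.shape
    grand = x.mean()
    rm = x.mean(axis=1)
    cm = x.mean(axis=0)
    msb = k * np.sum((rm - grand) ** 2) / (n - 1)
    msr = n * np.sum((cm - grand) ** 2) / (k - 1)
    resid = x - rm[:, None] - cm[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msb), float(msr), float(mse)


def icc_2_1(x: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) on an n-subjects × k-sessions matrix without missing cells.

    Negative estimates are reported as computed (not truncated). When
    all cells are identical the coefficient is undefined and returned as
    missing with a reason.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an n × k matrix with k ≥ 2")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("missing cells must be dropped before icc_2_1")

    msb, msr, mse = _anova_mean_squares(x)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if msb <= 0 and mse <= 0:
        return ICCResult(
            np.nan, (np.nan, np.nan), np.nan, df1, df2, np.nan, n,
            msg="all cells identical; ICC undefined",
        )
    icc = (msb - mse) / (msb + (k - 1) * mse + k * (msr - mse) / n)

    if mse > 0:
        f_stat = msb / mse
        p = float(sps.f.sf(f_stat, df1, df2))
    else:  # perfect agreement: infinitely strong evidence against ICC = 0
        f_stat, p = np.inf, 0.0

    # McGraw & Wong (1996) case-2A interval via a Satterthwaite df
    if mse > 0:
        fj = msr / mse
        vn = df2 * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = df1 * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f2u = sps.f.ppf(1 - alpha / 2, df1, v)
        f2l = sps.f.ppf(1 - alpha / 2, v, df1)
        lo = n * (msb - f2u * mse) / (f2u * (k * msr + (k * n - k - n) * mse) + n * msb)
        hi = n * (f2l * msb - mse) / (k * msr + (k * n - k - n) * mse + n * f2l * msb)
    else:
        lo = hi = 1.0
    return ICCResult(float(icc), (float(lo), float(hi)), float(f_stat), df1, df2, p, n)


def split_measure(rec: Recording) -> tuple[Recording, Recording]:
    """Split a recording into contiguous halves (odd counts: extra sample first)."""
    if rec.n_samples < 2:
        raise ValueError("cannot split a recording with < 2 samples")
    mid = (rec.n_samples + 1) // 2
    return rec.crop(0, mid), rec.crop(mid, rec.n_samples)


def spearman_brown(r_half: float) -> float:
    """Step a half-length correlation up to full length: 2r/(1+r).

    Undefined (NaN) at r = −1.
    """
    if r_half < -1 or r_half > 1:
        raise ValueError("correlation must be in [-1, 1]")
    if r_half == -1:
        return np.nan
    return 2.0 * r_half / (1.0 + r_half)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class ReliabilityAnalysis:
    """Reliability model over a long table of per-subject measures.

    Parameters
    ----------
    full : DataFrame
        Long format with columns (subject_id, session, measure, value):
        one value per subject × session × measure from full-length
        recordings. Used for test-retest ICC(2,1).
    halves : DataFrame, optional
        Long format with columns (subject_id, session, half, measure,
        value) where half is 1 or 2, from half-length recordings
        processed independently. Used for split-half reliability.
    sessions : sequence of str
        Session order (default T1, T2).

    Subjects with missing cells are dropped listwise per measure; the
    counts appear in the results table (``n_icc``).
    """

    def __init__(
        self,
        full: pd.DataFrame,
        halves: pd.DataFrame | None = None,
        sessions: Sequence[str] = ("T1", "T2"),
    ):
        for col in ("subject_id", "session", "measure", "value"):
            if col not in full.columns:
                raise ValueError(f"full table missing column {col!r}")
        if halves is not None:
            for col in ("subject_id", "session", "half", "measure", "value"):
                if col not in halves.columns:
                    raise ValueError(f"halves table missing column {col!r}")
        self.full = full
        self.halves = halves
        self.sessions = list(sessions)

    def fit(self, threshold: float = 0.75) -> "ReliabilityResults":
        measures = list(pd.unique(self.full["measure"]))
        rows = []
        details: dict[str, ICCResult] = {}
        for m in measures:
            sub = self.full[self.full["measure"] == m]
            wide = sub.pivot(index="subject_id", columns="session", values="value")
            wide = wide.reindex(columns=self.sessions).dropna()
            n_dropped = sub["subject_id"].nunique() - len(wide)
            icc = icc_2_1(wide.to_numpy())
            details[m] = icc
            row = {
                "measure": m,
                "icc": icc.icc,
                "ci_lo": icc.ci95[0],
                "ci_hi": icc.ci95[1],
                "f": icc.f_stat,
                "df1": icc.df1,
                "df2": icc.df2,
                "p": icc.p_value,
                "n_icc": icc.n_used,
                "n_dropped": n_dropped,
            }
            for sess in self.sessions:
                row[f"splithalf_{sess}"] = self._split_half(m, sess)
            gate = icc.icc >= threshold if icc.defined else False
            for sess in self.sessions:
                sh = row[f"splithalf_{sess}"]
                gate = gate and np.isfinite(sh) and sh >= threshold
            row["reliable"] = bool(gate)
            rows.append(row)
        return ReliabilityResults(pd.DataFrame(rows), details, threshold)

    def _split_half(self, measure: str, session: str) -> float:
        if self.halves is None:
            return np.nan
        sub = self.halves[
            (self.halves["measure"] == measure) & (self.halves["session"] == session)
        ]
        wide = sub.pivot(index="subject_id", columns="half", values="value")
        wide = wide.reindex(columns=[1, 2]).dropna()
        if len(wide) < 3:
            return np.nan
        r = float(np.corrcoef(wide[1], wide[2])[0, 1])
        if not np.isfinite(r):
            return np.nan
        return spearman_brown(r)


@dataclass
class ReliabilityResults:
    """Per-measure reliability table with the dual gate applied."""

    table: pd.DataFrame
    icc_details: dict[str, ICCResult]
    threshold: float

    def summary(self) -> pd.DataFrame:
        cols = [
            "measure", "icc", "ci_lo", "ci_hi", "p",
            *[c for c in self.table.columns if c.startswith("splithalf_")],
            "reliable", "n_icc",
        ]
        return self.table[cols].copy()

    @property
    def reliable_measures(self) -> list[str]:
        return list(self.table.loc[self.table["reliable"], "measure"])

    def to_csv(self, path) -> None:
        from .eeg_io import write_table

        write_table(self.table, path)
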