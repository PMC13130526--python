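"""Behavioral change scores and reliability-gated association screening.

The behavioral outcome is the vocabulary change score Δ = vocab%(T2) −
vocab%(T1) per subject, a proxy for long-term-memory performance gain.
Only measures that passed the reliability gate enter the screen: for
each such measure at T1, a Pearson correlation with Δ is computed after
excluding, per pair, subjects lying more than 2 SD from the mean on
either variable (single pass, sample SD). Raw p-values are
Bonferroni-corrected by the family size m (by default the number of
correlations actually computed). Correlation CIs use the Fisher
z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ltm_change",
    "exclude_outliers",
    "pearson_with_ci",
    "AssociationScreen",
    "AssociationResults",
    "paired_change_test",
    "one_sample_test",
    "age_adjusted_regression",
]


def ltm_change(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-subject T2 − T1 vocabulary difference in percentage points.

    Subjects lacking either session are dropped (count in attrs).
    Carries age and group from the T1 row when present.
    """
    wide = behavior.pivot(index="subject_id", columns="session", values="vocab_percent")
    complete = wide.dropna(subset=["T1", "T2"]) if {"T1", "T2"} <= set(wide.columns) else wide.iloc[0:0]
    out = pd.DataFrame(
        {
            "subject_id": complete.index,
            "delta": (complete["T2"] - complete["T1"]).to_numpy(),
        }
    ).reset_index(drop=True)
    for extra in ("age", "group"):
        if extra in behavior.columns:
            t1 = behavior[behavior["session"] == "T1"].set_index("subject_id")[extra]
            out[extra] = out["subject_id"].map(t1)
    out.attrs["n_dropped"] = int(behavior["subject_id"].nunique() - len(out))
    return out


def exclude_outliers(values: np.ndarray, sd_mult: float = 2.0) -> np.ndarray:
    """Boolean keep-mask: drop points with |x − mean| > sd_mult · SD.

    Mean and sample SD are computed once on the full vector (no
    iteration). Zero SD → nothing excluded.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3:
        raise ValueError("outlier screening needs at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.size, dtype=bool)
    return np.abs(values - values.mean()) <= sd_mult * sd


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float], int, float]:
    """Pearson r, Fisher-z 95% CI, df (n−2), and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    r, p = sps.pearsonr(x, y)
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (np.nan, np.nan)
    return float(r), ci, n - 2, float(p)


class AssociationScreen:
    """Gated correlation screen of T1 measures against the change score.

    Parameters
    ----------
    measures : DataFrame
        Wide per-subject table of T1 measures (index or column
        ``subject_id``, one column per measure).
    ltm : DataFrame
        Output of :func:`ltm_change` (subject_id, delta).
    reliable : sequence of str
        Measures that passed the reliability gate; the screen is a hard
        filter to this set.
    family_size : int, optional
        Bonferroni m; defaults to the number of tests computed. May be
        set larger (e.g. a study-wide family).
    sd_mult : float
        Outlier threshold in SD units (per pair, union over the two
        variables).
    """

    def __init__(
        self,
        measures: pd.DataFrame,
        ltm: pd.DataFrame,
        reliable: Sequence[str],
        family_size: int | None = None,
        sd_mult: float = 2.0,
    ):
        if "subject_id" in measures.columns:
            measures = measures.set_index("subject_id")
        self.measures = measures
        self.ltm = ltm.set_index("subject_id")["delta"]
        self.reliable = [m for m in reliable if m in measures.columns]
        self.family_size = family_size
        self.sd_mult = sd_mult

    def fit(self) -> "AssociationResults":
        rows = []
        m = self.family_size or max(len(self.reliable), 1)
        if m < len(self.reliable):
            raise ValueError("family_size smaller than the number of tests")
        for meas in self.reliable:
            joined = pd.concat([self.measures[meas], self.ltm], axis=1).dropna()
            if len(joined) < 3:
                rows.append(self._skipped(meas, len(joined)))
                continue
            x = joined[meas].to_numpy()
            y = joined["delta"].to_numpy()
            keep = exclude_outliers(x, self.sd_mult) & exclude_outliers(y, self.sd_mult)
            excluded = list(joined.index[~keep])
            if keep.sum() < 4:
                rows.append(self._skipped(meas, int(keep.sum()), excluded))
                continue
            r, ci, df, p = pearson_with_ci(x[keep], y[keep])
            rows.append(
                {
                    "measure": meas,
                    "outcome": "ltm_change",
                    "r": r,
                    "ci_lo": ci[0],
                    "ci_hi": ci[1],
                    "df": df,
                    "p_raw": p,
                    "p_bonferroni": min(1.0, p * m),
                    "n_used": df + 2,
                    "excluded_subjects": ";".join(map(str, excluded)),
                    "skipped": "",
                }
            )
        return AssociationResults(pd.DataFrame(rows), family_size=m)

    @staticmethod
    def _skipped(measure: str, n: int, excluded: list | None = None) -> dict:
        return {
            "measure": measure,
            "outcome": "ltm_change",
            "r": np.nan,
            "ci_lo": np.nan,
            "ci_hi": np.nan,
            "df": np.nan,
            "p_raw": np.nan,
            "p_bonferroni": np.nan,
            "n_used": n,
            "excluded_subjects": ";".join(map(str, excluded or [])),
            "skipped": f"only {n} usable subjects",
        }


@dataclass
class AssociationResults:
    table: pd.DataFrame
    family_size: int

    def summary(self) -> pd.DataFrame:
        cols = ["measure", "r", "ci_lo", "ci_hi", "df", "p_raw", "p_bonferroni", "n_used"]
        return self.table[cols].copy() if len(self.table) else self.table

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[t["p_bonferroni"] < alpha]

    def to_csv(self, path) -> None:
        from .eeg_io import write_table

        write_table(self.table, path)


# ---------------------------------------------------------------------------
# simple tests
# ---------------------------------------------------------------------------


def paired_change_test(behavior: pd.DataFrame) -> dict:
    """Paired t-test of vocab% T2 vs T1 with Cohen's d = mean(Δ)/SD(Δ)."""
    deltas = ltm_change(behavior)["delta"].to_numpy()
    if deltas.size < 3:
        raise ValueError("paired test needs at least 3 complete pairs")
    sd = deltas.std(ddof=1)
    if sd == 0:
        # no variability: identical sessions give exactly no evidence of
        # change; a nonzero constant shift is infinitely strong evidence
        mean = deltas.mean()
        t = 0.0 if mean == 0 else float(np.sign(mean) * np.inf)
        return {
            "t": t, "df": deltas.size - 1, "p": 1.0 if mean == 0 else 0.0,
            "cohens_d": np.nan, "n": deltas.size,
            "msg": "zero variance of change scores; d undefined",
        }
    t, p = sps.ttest_1samp(deltas, 0.0)
    return {
        "t": float(t), "df": deltas.size - 1, "p": float(p),
        "cohens_d": float(deltas.mean() / sd), "n": deltas.size, "msg": "",
    }


def one_sample_test(values: np.ndarray, mu0: float = 0.0) -> dict:
    """One-sample t-test against mu0; zero variance is flagged, not raised."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("one-sample test needs n ≥ 2")
    if values.std(ddof=1) == 0:
        return {
            "t": np.nan, "df": values.size - 1, "p": np.nan,
            "msg": "zero variance",
        }
    t, p = sps.ttest_1samp(values, mu0)
    return {"t": float(t), "df": values.size - 1, "p": float(p), "msg": ""}


def age_adjusted_regression(
    measure: np.ndarray, delta: np.ndarray, age: np.ndarray
) -> pd.DataFrame:
    """OLS of the change score on (measure, age) with per-coefficient tests.

    Returns a table with coefficient, 95% CI, t, and p per predictor
    (const, measure, age). Collinear predictors raise, naming columns.
    """
    import statsmodels.api as sm

    measure = np.asarray(measure, float)
    delta = np.asarray(delta, float)
    age = np.asarray(age, float)
    if not (measure.size == delta.size == age.size):
        raise ValueError("inputs must have equal length")
    if measure.size < 4:
        raise ValueError("need at least predictors + 2 complete cases")
    X = pd.DataFrame({"measure": measure, "age": age})
    Xc = sm.add_constant(X)
    cond = np.linalg.cond(Xc.to_numpy())
    if cond > 1e8:
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}): "
            f"columns {list(X.columns)}"
        )
    fit = sm.OLS(delta, Xc).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "term": Xc.columns,
            "coef": fit.params.to_numpy(),
            "ci_lo": ci[0].to_numpy(),
            "ci_hi": ci[1].to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "df_resid": fit.df_resid,
        }
    )
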