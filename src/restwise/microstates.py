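"""EEG microstate analysis: polarity-invariant modified k-means on GFP
peaks, hierarchical template aggregation, backfitting, and per-class
statistics.

A microstate is a quasi-stable scalp topography; a recording is
segmented into a sequence of a few prototypical classes. Clustering and
labeling ignore polarity throughout: spatial similarity between two maps
is the absolute Pearson correlation across channels of their
average-referenced forms, and templates are updated as the dominant
eigenvector of the assigned maps' cross-product matrix (the
polarity-invariant least-squares optimum — plain averaging would cancel
under sign flips).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .eeg_io import Recording

__all__ = [
    "TopographySet",
    "MicrostateSegmentation",
    "gfp",
    "gfp_peaks",
    "spatial_correlation",
    "ModifiedKMeans",
    "modified_kmeans",
    "aggregate_templates",
    "backfit",
    "microstate_stats",
]


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------


def gfp(rec: Recording | np.ndarray) -> np.ndarray:
    """Global field power: per-sample RMS of the average-referenced frame.

    Equals the population standard deviation across channels at each
    time point, in µV.
    """
    data = rec.data if isinstance(rec, Recording) else np.asarray(rec, float)
    if data.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return data.std(axis=0, ddof=0)


def gfp_peaks(trace: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a GFP trace.

    A plateau that is higher than both flanking samples counts once, at
    its first sample. Endpoints are never peaks. May return an empty
    array (e.g. monotone traces).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 3:
        raise ValueError("trace must have at least 3 samples")
    d = np.diff(trace)
    rising = d > 0
    falling = d < 0
    peaks = []
    last_rise = -1
    for i in range(d.size):
        if rising[i]:
            last_rise = i
        elif falling[i] and last_rise >= 0:
            peaks.append(last_rise + 1)  # first sample of the plateau/top
            last_rise = -1
    return np.asarray(peaks, dtype=np.intp)


def _demean_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference each row and scale to unit L2 norm.

    Returns (normalized maps, original norms); zero rows keep norm 0 and
    are returned as zeros.
    """
    maps = np.asarray(maps, dtype=np.float64)
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return centered / safe[:, None], norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between rows of ``a`` and ``b``.

    Both inputs are average-referenced internally. Returns an
    (n_a, n_b) matrix (signed; take ``abs`` for polarity-free use).
    """
    a_n, _ = _demean_normalize(np.atleast_2d(a))
    b_n, _ = _demean_normalize(np.atleast_2d(b))
    return a_n @ b_n.T


# ---------------------------------------------------------------------------
# template containers
# ---------------------------------------------------------------------------


@dataclass
class TopographySet:
    """k microstate template maps (rows: zero-mean, unit L2 norm)."""

    maps: np.ndarray  # (k, n_channels)
    channel_labels: list[str]
    source: str = "individual"  # individual | group_mean | grand_mean
    gev: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        maps, norms = _demean_normalize(np.atleast_2d(self.maps))
        if np.any(norms == 0):
            raise ValueError("template maps must be nonzero")
        self.maps = maps
        self.channel_labels = list(self.channel_labels)
        if self.maps.shape[1] != len(self.channel_labels):
            raise ValueError("maps and channel_labels disagree on channel count")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "channel_labels": self.channel_labels,
                    "maps": self.maps.tolist(),
                    "k": self.k,
                    "source": self.source,
                    "gev": self.gev,
                    "seed": self.seed,
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TopographySet":
        d = json.loads(Path(path).read_text())
        return cls(
            maps=np.asarray(d["maps"]),
            channel_labels=d["channel_labels"],
            source=d.get("source", "individual"),
            gev=d.get("gev"),
            seed=d.get("seed"),
        )


@dataclass
class MicrostateSegmentation:
    """Per-sample class labels plus the GFP trace they were fit on."""

    labels: np.ndarray  # (n_samples,), int in 0..k-1
    srate: float
    gfp_trace: np.ndarray
    n_classes: int
    n_zero_gfp: int = 0  # QC: frames with no topography, label carried over

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        self.gfp_trace = np.asarray(self.gfp_trace, dtype=np.float64)
        if self.labels.size != self.gfp_trace.size:
            raise ValueError("labels and gfp_trace lengths differ")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError("labels out of range")


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------


class ModifiedKMeans:
    """Polarity-invariant topographic k-means, best of ``n_restarts``.

    Fitted attributes: ``maps_`` (k × channels, zero-mean unit-norm),
    ``gev_`` (global explained variance of the returned solution),
    ``gev_per_restart_``, ``labels_`` (assignment of the training maps).
    Restart ``r`` derives its RNG from ``seed + r``, so a fixed seed
    fixes the whole ensemble.
    """

    def __init__(
        self,
        k: int,
        n_restarts: int = 20,
        max_iter: int = 300,
        tol: float = 1e-7,
        seed: int | None = 0,
    ):
        if k < 1:
            raise ValueError("k must be ≥ 1")
        self.k = k
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = 0 if seed is None else int(seed)

    def fit(self, maps: np.ndarray) -> "ModifiedKMeans":
        maps = np.atleast_2d(np.asarray(maps, dtype=np.float64))
        n, _ = maps.shape
        if n < self.k:
            raise ValueError(f"need at least k={self.k} maps, got {n}")
        x_norm, norms = _demean_normalize(maps)
        if np.any(norms == 0):
            raise ValueError("degenerate all-zero map in clustering input")
        w = norms**2  # GFP² weights for the GEV objective

        best = None
        gevs = []
        for r in range(self.n_restarts):
            rng = np.random.default_rng(self.seed + r)
            templates, labels, gev = self._one_restart(x_norm, w, rng)
            gevs.append(gev)
            if best is None or gev > best[2]:
                best = (templates, labels, gev)
        self.maps_, self.labels_, self.gev_ = best
        self.gev_per_restart_ = np.asarray(gevs)
        return self

    def _one_restart(self, x: np.ndarray, w: np.ndarray, rng) -> tuple:
        n = x.shape[0]
        templates = x[rng.choice(n, self.k, replace=False)].copy()
        prev_gev = -np.inf
        labels = np.zeros(n, dtype=np.intp)
        for _ in range(self.max_iter):
            corr = x @ templates.T
            labels = np.argmax(corr**2, axis=1)
            for j in range(self.k):
                members = x[labels == j]
                if members.shape[0] == 0:
                    # re-seed an empty class with the worst-explained map
                    worst = np.argmin(np.max(corr**2, axis=1))
                    templates[j] = x[worst]
                    continue
                templates[j] = self._principal_map(members)
            corr = x @ templates.T
            labels = np.argmax(corr**2, axis=1)
            picked = corr[np.arange(n), labels]
            gev = float((w * picked**2).sum() / w.sum())
            if gev - prev_gev < self.tol * max(abs(prev_gev), 1e-30):
                prev_gev = gev
                break
            prev_gev = gev
        return templates, labels, prev_gev

    @staticmethod
    def _principal_map(members: np.ndarray) -> np.ndarray:
        s = members.T @ members
        _, vecs = np.linalg.eigh(s)
        v = vecs[:, -1]
        v = v - v.mean()
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("degenerate principal map")
        return v / nrm


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    channel_labels: Sequence[str],
    n_restarts: int = 20,
    seed: int = 0,
    source: str = "individual",
) -> tuple[TopographySet, float]:
    """Cluster GFP-peak maps into ``k`` templates; returns (set, GEV)."""
    model = ModifiedKMeans(k=k, n_restarts=n_restarts, seed=seed).fit(peak_maps)
    topo = TopographySet(
        maps=model.maps_,
        channel_labels=list(channel_labels),
        source=source,
        gev=model.gev_,
        seed=seed,
    )
    return topo, model.gev_


def align_to(reference: TopographySet, other: TopographySet) -> TopographySet:
    """Reorder/sign-flip ``other`` to best match ``reference``.

    Hungarian assignment on |spatial correlation|; signs flipped so the
    matched correlation is positive.
    """
    c = spatial_correlation(reference.maps, other.maps)
    row, col = linear_sum_assignment(-np.abs(c))
    order = np.empty(reference.k, dtype=np.intp)
    order[row] = col
    signs = np.sign(c[row, col])
    signs[signs == 0] = 1.0
    maps = other.maps[order] * signs[np.argsort(row)][:, None]
    return TopographySet(
        maps=maps,
        channel_labels=other.channel_labels,
        source=other.source,
        gev=other.gev,
        seed=other.seed,
    )


def aggregate_templates(
    sets: Sequence[TopographySet],
    k: int | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    source: str = "group_mean",
) -> TopographySet:
    """Mean templates across a list of sets (subject → group → grand mean).

    Pools every member map and re-clusters them with the same
    polarity-invariant k-means; applying the function to group means
    yields grand means. Invariant to member row order and polarity.
    """
    if not sets:
        raise ValueError("no template sets to aggregate")
    labels0 = sets[0].channel_labels
    for s in sets:
        if s.channel_labels != labels0:
            raise ValueError("montage mismatch between template sets")
    if k is None:
        k = sets[0].k
    pooled = np.vstack([s.maps for s in sets])
    topo, _ = modified_kmeans(
        pooled, k, labels0, n_restarts=n_restarts, seed=seed, source=source
    )
    return topo


# ---------------------------------------------------------------------------
# backfitting and statistics
# ---------------------------------------------------------------------------


def backfit(rec: Recording, templates: TopographySet) -> MicrostateSegmentation:
    """Label every sample with its best-matching template (polarity-free).

    Frames with zero GFP carry the previous sample's label (class 0 at
    the very start) and are counted in ``n_zero_gfp``.
    """
    if rec.channel_labels != templates.channel_labels:
        raise ValueError("recording and templates use different montages")
    frames = rec.data.T  # (n_samples, n_channels)
    x_norm, norms = _demean_normalize(frames)
    corr = x_norm @ templates.maps.T
    labels = np.argmax(np.abs(corr), axis=1).astype(np.intp)

    zero = norms == 0
    n_zero = int(zero.sum())
    if n_zero:
        idx = np.flatnonzero(zero)
        for i in idx:
            labels[i] = labels[i - 1] if i > 0 else 0
    return MicrostateSegmentation(
        labels=labels,
        srate=rec.srate,
        gfp_trace=gfp(rec),
        n_classes=templates.k,
        n_zero_gfp=n_zero,
    )


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encoding → (class, start, length) arrays."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [labels.size])))
    return labels[starts], starts, lengths


def microstate_stats(seg: MicrostateSegmentation) -> pd.DataFrame:
    """Per-class mean GFP, mean duration, occurrence, and coverage.

    Contiguous runs define segments. Runs touching a recording boundary
    count for occurrence and coverage but are excluded from the mean
    duration (their true length is censored). A class that never occurs
    gets occurrence/coverage 0 and missing duration/GFP.
    """
    labels = seg.labels
    if labels.size == 0:
        raise ValueError("empty segmentation")
    classes, starts, lengths = _runs(labels)
    duration_s = labels.size / seg.srate
    interior = (starts > 0) & (starts + lengths < labels.size)

    rows = []
    for c in range(seg.n_classes):
        sel = classes == c
        n_runs = int(sel.sum())
        cov = 100.0 * lengths[sel].sum() / labels.size
        occ = n_runs / duration_s
        inner = lengths[sel & interior]
        dur_ms = float(inner.mean() / seg.srate * 1000.0) if inner.size else np.nan
        in_class = labels == c
        mgfp = float(seg.gfp_trace[in_class].mean()) if in_class.any() else np.nan
        rows.append(
            {
                "class": c,
                "mean_gfp": mgfp,
                "duration_ms": dur_ms,
                "occurrence": occ,
                "coverage_pct": cov,
            }
        )
    return pd.DataFrame(rows)
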