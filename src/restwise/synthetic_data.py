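"""Synthetic two-session EEG cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be validated without real data:

* **Band-power traits.** Each subject carries a stable log10 band-power
  trait per frequency band (between-subject SD σ_b); each session adds
  independent state noise (within-subject SD σ_e), giving a known true
  test-retest reliability ICC = σ_b²/(σ_b² + σ_e²). The session value
  10^x µV² is realized as additive band-limited noise of exactly that
  channel-averaged variance.
* **Microstates.** A 4-class dwell process (exponential dwell times,
  no self-transitions) switches between fixed orthonormal template
  topographies, amplitude-modulated by a rhythmic envelope that never
  vanishes; the label sequence and per-class statistics are recorded as
  exact ground truth.
* **Background.** 1/f-shaped noise plus white sensor noise at
  amplitudes that leave the alpha-band signal-to-background ratio ≈ 5.
* **Behavior.** Vocabulary scores whose T2 − T1 change has a planted
  correlation with the subject's alpha trait; change-score sample
  moments are calibrated exactly to the configured mean/SD.

The cohort signal is a sum of the microstate component, the per-band
trait noise, and the backgrounds. Additive mixing keeps the planted ICC
of log band power intact to first order (constant additive power only
rescales the log-power variance components jointly), whereas modulating
a single shared band-limited amplitude by the ~80 ms template switching
would smear power across bands and corrupt the planted per-band traits.

A fixed master seed fixes every draw; (subject, session) streams are
independent SeedSequence children, so any single recording can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy import stats as sps

from .eeg_io import Recording
from .microstates import MicrostateSegmentation, TopographySet, microstate_stats

__all__ = [
    "CohortSpec",
    "TraitSpec",
    "CohortData",
    "default_montage",
    "make_templates",
    "simulate_subject_eeg",
    "simulate_cohort",
    "simulate_behavior",
    "simulate_microstate_eeg",
]

BAND_EDGES: Mapping[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 75.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-scale layout: who is recorded, how long, at what rate."""

    n_subjects: int = 90
    n_channels: int = 64
    srate: float = 1000.0
    duration_s: float = 180.0
    sessions: tuple[str, ...] = ("T1", "T2")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_channels) < 1 or self.srate <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.srate))


def _sigma_e_from_icc(sigma_b: float, icc: float) -> float:
    if not 0 < icc <= 1:
        raise ValueError("true ICC must be in (0, 1]")
    return sigma_b * np.sqrt((1.0 - icc) / icc)


@dataclass(frozen=True)
class TraitSpec:
    """Planted population parameters (the generator's ground truth).

    Band powers are channel-averaged absolute powers in µV² on a log10
    scale; per-band true ICC follows from (σ_b, σ_e). Behavior plants
    the change-score moments and its correlation with the alpha trait.
    """

    band_log10_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "delta": 1.35, "theta": 1.0, "alpha": 1.3, "beta": 0.9, "gamma": 0.5
        }
    )
    band_sigma_b: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.30 for b in BAND_EDGES}
    )
    band_sigma_e: Mapping[str, float] = field(
        default_factory=lambda: {
            # σ_e chosen so true ICCs mirror typical adult values
            "delta": _sigma_e_from_icc(0.30, 0.66),
            "theta": _sigma_e_from_icc(0.30, 0.77),
            "alpha": _sigma_e_from_icc(0.30, 0.86),
            "beta": _sigma_e_from_icc(0.30, 0.80),
            "gamma": _sigma_e_from_icc(0.30, 0.64),
        }
    )
    # microstate dwell process
    n_states: int = 4
    mean_dwell_ms: tuple[float, ...] = (80.0, 80.0, 80.0, 80.0)
    relative_intensity: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    dwell_dist: str = "exponential"  # or "gamma" (shape 2)
    min_dwell_ms: float = 10.0
    envelope_freq_hz: float = 10.0
    envelope_floor: float = 0.2
    microstate_power_uV2: float = 6.0  # channel-avg power of the ms component
    # backgrounds
    one_over_f_exponent: float = 1.0
    background_alpha_power_uV2: float = 4.0  # 1/f power inside alpha band
    sensor_noise_uV: float = 1.0
    # behavior (defaults: adult cohort)
    group: str = "adults"
    t1_mean: float = 0.0
    t1_sd: float = 0.5
    delta_mean: float = 65.13
    delta_sd: float = 21.75
    target_corr: float = 0.38
    age_mean: float = 28.96
    age_sd: float = 6.85
    age_range: tuple[float, float] = (18.0, 40.0)

    def __post_init__(self) -> None:
        if len(self.mean_dwell_ms) != self.n_states:
            raise ValueError("one mean dwell per state required")
        if min(self.mean_dwell_ms) < 20.0:
            raise ValueError("mean dwell times must be ≥ 20 ms")
        if not abs(self.target_corr) < 1:
            raise ValueError("|target_corr| must be < 1")
        if not 0 <= self.envelope_floor < 1:
            raise ValueError("envelope_floor must be in [0, 1)")

    @classmethod
    def adults(cls, **overrides) -> "TraitSpec":
        return cls(**overrides)

    @classmethod
    def children(cls, **overrides) -> "TraitSpec":
        base = dict(
            group="children",
            t1_mean=14.51, t1_sd=11.04,
            delta_mean=27.65, delta_sd=17.49,
            target_corr=0.0,
            age_mean=11.22, age_sd=1.16, age_range=(9.0, 15.0),
        )
        base.update(overrides)
        return cls(**base)

    def true_icc(self, band: str) -> float:
        sb = self.band_sigma_b[band]
        se = self.band_sigma_e[band]
        return sb**2 / (sb**2 + se**2)


# ---------------------------------------------------------------------------
# montage and templates
# ---------------------------------------------------------------------------


_MONTAGE_CACHE: dict[int, tuple[list[str], np.ndarray]] = {}


def default_montage(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Channel labels and unit-sphere positions.

    64 channels → the standard BioSemi 64 layout (10–20 naming);
    other counts → a Fibonacci lattice on the upper hemisphere with
    generic labels.
    """
    if n_channels in _MONTAGE_CACHE:
        labels, pos = _MONTAGE_CACHE[n_channels]
        return list(labels), pos.copy()
    if n_channels == 64:
        import mne

        mont = mne.channels.make_standard_montage("biosemi64")
        pos_dict = mont.get_positions()["ch_pos"]
        labels = list(mont.ch_names)
        pos = np.array([pos_dict[ch] for ch in labels])
    else:
        i = np.arange(n_channels)
        z = 0.15 + 0.84 * (i + 0.5) / n_channels  # upper hemisphere band
        golden = np.pi * (3.0 - np.sqrt(5.0))
        theta = golden * i
        r = np.sqrt(1 - z**2)
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        labels = [f"E{j + 1:02d}" for j in range(n_channels)]
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    _MONTAGE_CACHE[n_channels] = (labels, pos)
    return list(labels), pos.copy()


def make_templates(positions: np.ndarray, k: int = 4) -> np.ndarray:
    """k orthonormal, zero-mean template topographies from smooth
    low-order patterns of electrode position (dipolar/quadrupolar-like).
    """
    x, y, z = positions.T
    patterns = [x, y, z, x * y, x * z, y * z, x**2 - y**2]
    if k > len(patterns):
        raise ValueError(f"at most {len(patterns)} planted templates supported")
    P = np.array(patterns[:k], dtype=np.float64)
    P = P - P.mean(axis=1, keepdims=True)
    Q, _ = np.linalg.qr(P.T)  # columns orthonormal, span unchanged
    maps = Q.T[:k]
    # deterministic sign: largest-magnitude channel positive
    for row in maps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return maps


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _draw_labels(
    traits: TraitSpec, n_samples: int, srate: float, rng: np.random.Generator
) -> np.ndarray:
    """Dwell-process class labels, one per sample, no self-transitions."""
    k = traits.n_states
    labels = np.empty(n_samples, dtype=np.intp)
    pos = 0
    current = int(rng.integers(k))
    while pos < n_samples:
        mean = traits.mean_dwell_ms[current]
        if traits.dwell_dist == "exponential":
            dur_ms = rng.exponential(mean)
        elif traits.dwell_dist == "gamma":
            dur_ms = rng.gamma(2.0, mean / 2.0)
        else:
            raise ValueError(f"unknown dwell distribution {traits.dwell_dist!r}")
        dur_ms = max(dur_ms, traits.min_dwell_ms)
        n = max(int(round(dur_ms * srate / 1000.0)), 1)
        labels[pos : pos + n] = current
        pos += n
        if k > 1:
            step = int(rng.integers(k - 1))
            current = (current + 1 + step) % k
    return labels


def _band_limited_noise(
    n_ch: int, n_samples: int, srate: float, low: float, high: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance (per channel) noise band-limited to [low, high] Hz."""
    high = min(high, 0.499 * srate)
    if high <= low:
        raise ValueError("band above Nyquist for this sampling rate")
    white = rng.standard_normal((n_ch, n_samples))
    sos = sig.butter(4, [low, high], btype="bandpass", fs=srate, output="sos")
    x = sig.sosfiltfilt(sos, white, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _one_over_f_noise(
    n_ch: int, n_samples: int, srate: float, exponent: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """1/f^β noise, unit variance per channel; also returns the expected
    fraction of that variance inside the alpha band (8–14 Hz)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(rng.standard_normal((n_ch, n_samples)), axis=1) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    power = shape**2
    in_alpha = power[(freqs >= 8.0) & (freqs <= 14.0)].sum() / power.sum()
    return x / sd, float(in_alpha)


def _envelope(traits: TraitSpec, n_samples: int, srate: float) -> np.ndarray:
    t = np.arange(n_samples) / srate
    s2 = np.sin(2 * np.pi * traits.envelope_freq_hz * t) ** 2
    return np.sqrt(traits.envelope_floor + (1 - traits.envelope_floor) * s2)


def _draw_traits(cohort: CohortSpec, traits: TraitSpec) -> dict:
    """Subject traits and per-session values for every band (log10 µV²)."""
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 7919]))
    n, s = cohort.n_subjects, len(cohort.sessions)
    out = {"g": {}, "x": {}}
    for band in BAND_EDGES:
        g = traits.band_log10_mean[band] + traits.band_sigma_b[band] * rng.standard_normal(n)
        e = traits.band_sigma_e[band] * rng.standard_normal((n, s))
        out["g"][band] = g
        out["x"][band] = g[:, None] + e
    return out


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def simulate_subject_eeg(
    cohort: CohortSpec,
    traits: TraitSpec,
    subject: int,
    session: int,
    session_values: Mapping[str, float] | None = None,
    noise_key: int | None = None,
) -> tuple[Recording, dict]:
    """One subject-session EEG plus its ground truth.

    ``session_values`` are the per-band log10 powers x_ij; when omitted
    they are drawn from the cohort's trait stream (matching
    :func:`simulate_cohort`). ``noise_key`` overrides the per-session
    noise stream (passing the same key for both sessions makes the
    session recordings identical whenever σ_e = 0).
    """
    if session_values is None:
        session_values = {
            b: _draw_traits(cohort, traits)["x"][b][subject, session]
            for b in BAND_EDGES
        }
    key = session if noise_key is None else noise_key
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, subject, key]))
    labels_mont, pos = default_montage(cohort.n_channels)
    n_ch, n_samp, srate = cohort.n_channels, cohort.n_samples, cohort.srate

    templates = make_templates(pos, traits.n_states)
    ms_labels = _draw_labels(traits, n_samp, srate, rng)
    env = _envelope(traits, n_samp, srate)
    rel = np.asarray(traits.relative_intensity)
    mod = rel[ms_labels] * env
    env_ms = float(np.mean(mod**2))
    amp = np.sqrt(traits.microstate_power_uV2 * n_ch / max(env_ms, 1e-12))
    data = templates[ms_labels].T * (amp * mod)[None, :]

    for band, (low, high) in BAND_EDGES.items():
        var = 10.0 ** session_values[band]
        data += np.sqrt(var) * _band_limited_noise(n_ch, n_samp, srate, low, high, rng)

    bg, alpha_frac = _one_over_f_noise(
        n_ch, n_samp, srate, traits.one_over_f_exponent, rng
    )
    data += bg * np.sqrt(traits.background_alpha_power_uV2 / max(alpha_frac, 1e-12))
    data += traits.sensor_noise_uV * rng.standard_normal((n_ch, n_samp))

    rec = Recording(
        data=data,
        srate=srate,
        channel_labels=labels_mont,
        channel_positions=pos,
        subject_id=f"S{subject + 1:03d}",
        session=cohort.sessions[session],
    )
    truth = {
        "templates": templates,
        "ms_labels": ms_labels,
        "session_values": dict(session_values),
    }
    return rec, truth


def simulate_behavior(cohort: CohortSpec, traits: TraitSpec, g_alpha: np.ndarray) -> pd.DataFrame:
    """Behavior table with a planted corr(alpha trait, change score).

    The change-score sample is affinely recalibrated to the exact
    configured mean/SD (preserving planted correlations, which are
    invariant to affine maps). Draws whose T2 = T1 + Δ would leave
    [0, 100] are redrawn so the recalibration stays exact; only if
    redrawing fails to converge is a final clip applied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 104729]))
    n = cohort.n_subjects
    rho = traits.target_corr
    z_g = (g_alpha - g_alpha.mean()) / max(g_alpha.std(), 1e-12)
    eps = rng.standard_normal(n)

    if traits.t1_sd > 0:
        a, b = (0 - traits.t1_mean) / traits.t1_sd, (100 - traits.t1_mean) / traits.t1_sd
        t1 = sps.truncnorm.rvs(
            a, b, loc=traits.t1_mean, scale=traits.t1_sd, size=n, random_state=rng
        )
    else:
        t1 = np.full(n, float(traits.t1_mean))

    delta = np.empty(n)
    noise_sd = np.sqrt(1 - rho**2)
    for _ in range(100):
        raw = rho * z_g + noise_sd * eps
        m, s = raw.mean(), max(raw.std(ddof=1), 1e-12)
        delta = traits.delta_mean + traits.delta_sd * (raw - m) / s
        bad = (t1 + delta > 100.0) | (t1 + delta < 0.0)
        if not bad.any():
            break
        # redraw offending noise from within each subject's headroom,
        # mapped through the current affine recalibration
        for i in np.flatnonzero(bad):
            r_hi = m + s * (100.0 - t1[i] - traits.delta_mean) / traits.delta_sd
            r_lo = m + s * (0.0 - t1[i] - traits.delta_mean) / traits.delta_sd
            e_hi = (r_hi - rho * z_g[i]) / noise_sd
            e_lo = (r_lo - rho * z_g[i]) / noise_sd
            # shrink the window slightly so the next re-standardization
            # stays inside
            e_hi, e_lo = e_hi - 0.05, e_lo + 0.05
            if e_lo >= e_hi:
                eps[i] = 0.5 * (e_lo + e_hi)
            else:
                eps[i] = sps.truncnorm.rvs(e_lo, e_hi, random_state=rng)
    t2 = np.clip(t1 + delta, 0.0, 100.0)

    lo, hi = traits.age_range
    age = np.clip(traits.age_mean + traits.age_sd * rng.standard_normal(n), lo, hi)
    rows = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        rows.append((sid, "T1", t1[i], age[i], traits.group))
        rows.append((sid, "T2", t2[i], age[i], traits.group))
    return pd.DataFrame(
        rows, columns=["subject_id", "session", "vocab_percent", "age", "group"]
    )


@dataclass
class CohortData:
    """A fully materialized synthetic cohort with its ground-truth sidecar."""

    cohort: CohortSpec
    traits: TraitSpec
    recordings: list[Recording]
    behavior: pd.DataFrame
    truth: dict

    def iter_recordings(self) -> Iterator[Recording]:
        return iter(self.recordings)


def simulate_cohort(
    cohort: CohortSpec, traits: TraitSpec | None = None, materialize: bool = True
) -> CohortData:
    """Generate the full cohort: EEG per subject × session, behavior, truth.

    The truth sidecar carries per-subject traits and session values,
    per-band true ICCs, the planted templates and per-recording label
    statistics, and the planted behavior correlation. With
    ``materialize=False`` the recordings list is left empty (behavior
    and truth only) for callers that stream recordings one at a time via
    :func:`simulate_subject_eeg`.
    """
    traits = traits or TraitSpec()
    tr = _draw_traits(cohort, traits)
    behavior = simulate_behavior(cohort, traits, tr["g"]["alpha"])

    recordings: list[Recording] = []
    label_stats: dict[tuple[str, str], pd.DataFrame] = {}
    templates = None
    if materialize:
        for i in range(cohort.n_subjects):
            for s, sess in enumerate(cohort.sessions):
                rec, truth_one = simulate_subject_eeg(
                    cohort, traits, i, s,
                    session_values={b: tr["x"][b][i, s] for b in BAND_EDGES},
                )
                recordings.append(rec)
                templates = truth_one["templates"]
                seg = MicrostateSegmentation(
                    labels=truth_one["ms_labels"],
                    srate=cohort.srate,
                    gfp_trace=np.zeros(cohort.n_samples),
                    n_classes=traits.n_states,
                )
                label_stats[(rec.subject_id, sess)] = microstate_stats(seg)[
                    ["class", "duration_ms", "occurrence", "coverage_pct"]
                ]
    else:
        _, pos = default_montage(cohort.n_channels)
        templates = make_templates(pos, traits.n_states)

    truth = {
        "band_traits": tr["g"],
        "band_session_values": tr["x"],
        "true_icc": {b: traits.true_icc(b) for b in BAND_EDGES},
        "templates": templates,
        "label_stats": label_stats,
        "target_corr": traits.target_corr,
        "delta": behavior.pivot(
            index="subject_id", columns="session", values="vocab_percent"
        ).eval("T2 - T1").to_numpy(),
    }
    return CohortData(cohort, traits, recordings, behavior, truth)


def simulate_microstate_eeg(
    n_states: int = 4,
    duration_s: float = 180.0,
    srate: float = 250.0,
    n_channels: int = 64,
    mean_dwell_ms: float = 80.0,
    snr: float = 10.0,
    envelope_floor: float = 0.2,
    envelope_freq_hz: float = 10.0,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Dedicated microstate test signal: templates × dwell process + white noise.

    SNR is the channel-averaged variance ratio of the clean microstate
    signal to the sensor noise. Returns the recording and a truth dict
    with the planted templates, the per-sample label sequence, and the
    per-class statistics of that sequence (exact ground truth for
    clustering, backfitting, and the statistics estimators).
    """
    traits = TraitSpec(
        n_states=n_states,
        mean_dwell_ms=(mean_dwell_ms,) * n_states,
        relative_intensity=(1.0,) * n_states,
        envelope_floor=envelope_floor,
        envelope_freq_hz=envelope_freq_hz,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    labels_mont, pos = default_montage(n_channels)
    n_samp = int(round(duration_s * srate))
    templates = make_templates(pos, n_states)
    ms_labels = _draw_labels(traits, n_samp, srate, rng)
    env = _envelope(traits, n_samp, srate)

    clean = templates[ms_labels].T * env[None, :]
    signal_power = float(np.mean(clean**2))
    noise_sd = np.sqrt(signal_power / snr)
    data = clean + noise_sd * rng.standard_normal((n_channels, n_samp))

    gfp_clean = clean.std(axis=0, ddof=0)
    seg = MicrostateSegmentation(
        labels=ms_labels, srate=srate, gfp_trace=gfp_clean, n_classes=n_states
    )
    truth = {
        "templates": templates,
        "labels": ms_labels,
        "stats": microstate_stats(seg),
        "noise_sd": noise_sd,
    }
    rec = Recording(
        data=data,
        srate=srate,
        channel_labels=labels_mont,
        channel_positions=pos,
        subject_id="SIM",
        session="T1",
    )
    return rec, truth
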