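"""Deterministic preprocessing: common average reference, zero-phase
band-pass/notch filtering, and spherical-spline interpolation of bad
channels.

The chain mirrors a conventional resting-state pipeline: average
reference → 0.5–80 Hz band-pass → line-noise notches (50 Hz and
harmonics) → bad-channel interpolation → re-reference. Automatic
artifact rejection and ICA-based component removal are deliberately not
re-implemented; :func:`preprocess` exposes a hook for externally cleaned
data instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .eeg_io import Recording

__all__ = [
    "PreprocessConfig",
    "common_average_reference",
    "bandpass_notch",
    "interpolate_bad_channels",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Filter/reference settings.

    Filters are 4th-order Butterworth applied forward–backward
    (zero-phase); notches are ±1 Hz band-stops at each listed frequency.
    """

    highpass_hz: float = 0.5
    lowpass_hz: float = 80.0
    notch_hz: tuple[float, ...] = (50.0, 100.0, 150.0)
    rereference: str = "common_average"
    bad_channels: tuple[str, ...] = ()
    filter_order: int = 4
    notch_halfwidth_hz: float = 1.0

    @classmethod
    def for_srate(cls, srate: float, **overrides) -> "PreprocessConfig":
        """Default chain with line-noise notches restricted to below Nyquist.

        Keeps the 0.5–80 Hz pass band, so the sampling rate must exceed
        160 Hz.
        """
        notch = tuple(f for f in (50.0, 100.0, 150.0) if f + 1.0 < srate / 2)
        cfg = cls(notch_hz=notch, **overrides)
        cfg.validate(srate)
        return cfg

    def validate(self, srate: float) -> None:
        nyq = srate / 2.0
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass_hz < lowpass_hz")
        if self.lowpass_hz >= nyq:
            raise ValueError(
                f"lowpass_hz={self.lowpass_hz} requires srate > "
                f"{2 * self.lowpass_hz} Hz (got {srate})"
            )
        for f0 in self.notch_hz:
            if f0 + self.notch_halfwidth_hz >= nyq:
                raise ValueError(f"notch at {f0} Hz exceeds Nyquist ({nyq} Hz)")
        if self.rereference != "common_average":
            raise ValueError("only common_average rereferencing is supported")


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs ≥ 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def _sos_bandpass(cfg: PreprocessConfig, srate: float):
    return signal.butter(
        cfg.filter_order,
        [cfg.highpass_hz, cfg.lowpass_hz],
        btype="bandpass",
        fs=srate,
        output="sos",
    )


def bandpass_notch(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase band-pass plus narrow band-stop notches."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.srate)
    data = signal.sosfiltfilt(_sos_bandpass(cfg, rec.srate), rec.data, axis=1)
    for f0 in cfg.notch_hz:
        sos = signal.butter(
            cfg.filter_order,
            [f0 - cfg.notch_halfwidth_hz, f0 + cfg.notch_halfwidth_hz],
            btype="bandstop",
            fs=rec.srate,
            output="sos",
        )
        data = signal.sosfiltfilt(sos, data, axis=1)
    return rec.copy_with(data)


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin-style)
# ---------------------------------------------------------------------------


def _g_matrix(cosang: np.ndarray, stiffness: int, n_terms: int) -> np.ndarray:
    """Spherical spline kernel g(cos γ) truncated to n_terms Legendre terms."""
    g = np.zeros_like(cosang, dtype=np.float64)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** stiffness * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def interpolate_bad_channels(
    rec: Recording,
    bad: Sequence[str],
    stiffness: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> Recording:
    """Replace listed channels with spherical-spline estimates.

    Requires unit-sphere channel positions. Good channels are untouched.
    Default spline: stiffness (Legendre order) 4, 7-term truncation,
    ridge regularization 1e-5 on the kernel diagonal.
    """
    bad = list(bad)
    if not bad:
        return rec.copy_with(rec.data.copy())
    if rec.channel_positions is None:
        raise ValueError("interpolation requires channel_positions")
    unknown = set(bad) - set(rec.channel_labels)
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    bad_idx = np.array([rec.channel_labels.index(b) for b in bad])
    good_idx = np.array(
        [i for i in range(rec.n_channels) if i not in set(bad_idx)]
    )
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")

    pos = rec.channel_positions
    cos_gg = np.clip(pos[good_idx] @ pos[good_idx].T, -1.0, 1.0)
    cos_bg = np.clip(pos[bad_idx] @ pos[good_idx].T, -1.0, 1.0)
    n_good = len(good_idx)
    G = _g_matrix(cos_gg, stiffness, n_terms) + reg * np.eye(n_good)
    Gto = _g_matrix(cos_bg, stiffness, n_terms)

    # solve [[G, 1], [1ᵀ, 0]] [c; d] = [v; 0] per time point
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    rhs = np.zeros((n_good + 1, rec.n_samples))
    rhs[:n_good] = rec.data[good_idx]
    sol = np.linalg.solve(A, rhs)
    c, d = sol[:n_good], sol[n_good]

    data = rec.data.copy()
    data[bad_idx] = Gto @ c + d[None, :]
    return rec.copy_with(data)


def preprocess(
    rec: Recording,
    cfg: PreprocessConfig | None = None,
    artifact_hook: Callable[[Recording], Recording] | None = None,
) -> Recording:
    """Full chain: reference → filter/notch → (hook) → interpolate → re-reference.

    ``artifact_hook`` is a pass-through slot for externally supplied
    artifact cleaning (e.g. data already cleaned elsewhere); it runs
    between filtering and interpolation and defaults to the identity.
    """
    cfg = cfg or PreprocessConfig()
    out = common_average_reference(rec)
    out = bandpass_notch(out, cfg)
    if artifact_hook is not None:
        out = artifact_hook(out)
    if cfg.bad_channels:
        out = interpolate_bad_channels(out, cfg.bad_channels)
    return common_average_reference(out)
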