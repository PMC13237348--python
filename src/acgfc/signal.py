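"""Signal utilities: mirror-padded zero-phase band-pass, resampling, baseline
correction, and analytic phase extraction."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .data import EpochSet

__all__ = ["bandpass_mirror", "resample_to", "baseline_correct", "analytic_phase"]


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}")


def bandpass_mirror(data: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Both ends are mirror-extended by the full signal length before the
    forward-backward pass, then cropped, so filter transients never touch the
    retained samples and the output length equals the input length.
    """
    _check_band(low, high, fs)
    data = np.asarray(data, dtype=np.float64)
    T = data.shape[-1]
    if T < 4:
        raise ValueError("signal too short to filter")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    pad = T - 1
    ext = np.concatenate(
        [data[..., pad:0:-1], data, data[..., -2 : -pad - 2 : -1]], axis=-1
    )
    out = sps.sosfiltfilt(sos, ext, axis=-1, padtype=None)
    return out[..., pad : pad + T]


def resample_to(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling along the last axis; fs_out must not exceed fs_in."""
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out > fs_in:
        raise ValueError("upsampling is not supported; fs_out must be <= fs_in")
    if fs_out == fs_in:
        return np.asarray(data, dtype=np.float64).copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    data = np.asarray(data, dtype=np.float64)
    out = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    # output length = round(T * fs_out / fs_in); polyphase may overshoot by one
    target = int(round(data.shape[-1] * fs_out / fs_in))
    return out[..., :target]


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-epoch, per-node mean over ``window_ms`` (half-open)."""
    t_start, t_end = window_ms
    t = epochs.times_ms
    mask = (t >= t_start) & (t < t_end)
    if not mask.any():
        raise ValueError(f"baseline window [{t_start}, {t_end}) ms selects no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.labels, epochs.subjects, epochs.fs, epochs.t0_ms)


def analytic_phase(data: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Instantaneous phase (rad) of the band-limited analytic signal.

    Band-pass with mirror padding, then Hilbert transform along the last axis.
    """
    filtered = bandpass_mirror(data, fs, band[0], band[1])
    return np.angle(sps.hilbert(filtered, axis=-1))
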