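"""Sliding-window Freezing-Index baseline.

The Freezing Index (FI) of a trailing window is the ratio of spectral power
in the freeze band (3-8 Hz) to the power in the locomotor band. The
locomotor band defaults to 0.5-3 Hz — the DC/trend bin is excluded because
a biased accelerometer otherwise drives the ratio to zero; pass
``locomotor_band=(0.0, 3.0)`` for the literal reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .data_io import FogaitError

__all__ = ["FiSeries", "freezing_index", "fi_detect", "fi_multiaxis_vote"]

FREEZE_BAND = (3.0, 8.0)
LOCOMOTOR_BAND = (0.5, 3.0)


@dataclass(frozen=True)
class FiSeries:
    """Per-window freezing-index values; windows are trailing and causal."""

    t: np.ndarray        # window end times, s
    fi: np.ndarray       # power ratio, >= 0, +inf when locomotor power vanishes
    window_s: float

    def __len__(self) -> int:
        return int(self.t.size)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)  # inclusive-exclusive band edges
    return float(np.sum(psd[mask]))


def freezing_index(
    signal: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    hop: int = 1,
    freeze_band: tuple[float, float] = FREEZE_BAND,
    locomotor_band: tuple[float, float] = LOCOMOTOR_BAND,
) -> FiSeries:
    """Freezing index over trailing windows advancing by ``hop`` samples.

    Each window is linearly detrended and Hann-tapered before the
    periodogram. Windows shorter than 16 samples are rejected. When the
    locomotor-band power falls below machine epsilon the FI is reported as
    ``+inf``.
    """
    signal = np.asarray(signal, dtype=float)
    n_win = int(round(window_s * fs))
    if n_win < 16:
        raise FogaitError(f"window of {n_win} samples is too short (need >= 16)")
    if signal.size < n_win:
        raise FogaitError("signal shorter than one window")
    times, values = [], []
    for end in range(n_win, signal.size + 1, hop):
        seg = signal[end - n_win:end]
        freqs, psd = periodogram(seg, fs=fs, window="hann", detrend="linear")
        p_freeze = _band_power(freqs, psd, freeze_band)
        p_loco = _band_power(freqs, psd, locomotor_band)
        if p_loco < np.finfo(float).eps:
            # silence in both bands is not freezing; freeze power without
            # locomotor power saturates the ratio
            values.append(np.inf if p_freeze >= np.finfo(float).eps else 0.0)
        else:
            values.append(p_freeze / p_loco)
        times.append((end - 1) / fs)
    return FiSeries(t=np.asarray(times), fi=np.asarray(values), window_s=window_s)


def fi_detect(series: FiSeries, threshold: float) -> np.ndarray:
    """Binary per-window labels: FoG where FI exceeds the threshold."""
    if threshold <= 0:
        raise FogaitError("threshold must be positive")
    return (series.fi > threshold).astype(int)


def fi_multiaxis_vote(
    channels: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    threshold: float = 1.0,
    hop: int = 1,
    majority: int = 4,
) -> np.ndarray:
    """Majority vote over the six per-axis freezing indexes.

    ``channels`` is (n, 6): three accelerometer plus three gyro axes. A
    window counts as FoG when at least ``majority`` (default 4 of 6, the
    strict majority) per-axis FI values exceed the threshold.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2 or channels.shape[1] != 6:
        raise FogaitError(f"expected (n, 6) channel array, got {channels.shape}")
    votes = None
    for j in range(6):
        series = freezing_index(channels[:, j], fs, window_s, hop=hop)
        axis_vote = (series.fi > threshold).astype(int)
        votes = axis_vote if votes is None else votes + axis_vote
    return (votes >= majority).astype(int)
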