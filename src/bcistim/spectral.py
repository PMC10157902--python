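"""Band power in dB and ERD/ERS time courses.

Band power is the Hann-windowed periodogram integrated over the (half-open)
band, reported as 10*log10(power / 1 µV²).  A 10 µV-amplitude sinusoid inside
the band therefore measures ~10*log10(50) = 17.0 dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import ROI_9, BandDefinition, EpochSet, filter_signal, ms_to_sample

__all__ = [
    "band_power",
    "band_power_db",
    "BandPowerResult",
    "prestimulus_power",
    "erd_timecourse",
]


def band_power(segment: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Linear band power (µV²) per channel of a (…, n_samples) segment:
    integral of the Hann periodogram density over [lo, hi)."""
    x = np.asarray(segment, dtype=float)
    n = x.shape[-1]
    if n < 2 * fs / band.lo:
        raise ValueError(
            f"segment of {n} samples is shorter than two periods of {band.lo} Hz"
        )
    freqs, pxx = signal.periodogram(x, fs=fs, window="hann", axis=-1)
    df = freqs[1] - freqs[0]
    sel = (freqs >= band.lo) & (freqs < band.hi)
    return pxx[..., sel].sum(axis=-1) * df


def band_power_db(segment: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Band power per channel in dB re 1 µV²."""
    p = band_power(segment, fs, band)
    return 10.0 * np.log10(np.maximum(p, np.finfo(float).tiny))


@dataclass
class BandPowerResult:
    channel_db: dict  # label -> dB
    band: BandDefinition
    window_ms: tuple
    c3c4_mean: float  # dB (averaged in the dB domain)
    roi_values: np.ndarray  # ordered as ROI_9
    n_trials: int


def prestimulus_power(
    epochs: EpochSet,
    band: BandDefinition,
    prestim_window_ms: tuple = (-1000.0, 0.0),
    db_average: bool = True,
) -> BandPowerResult:
    """Pre-stimulus band power: per-trial power on the pre-onset sub-window,
    averaged over trials, then converted to dB.

    ``epochs`` are expected to be cut with a window that covers
    ``prestim_window_ms`` (study pipeline: (-1000, 4000) ms, 1-40 Hz filtered,
    rejection applied, online-phase trials only).
    """
    if epochs.n_trials == 0:
        raise ValueError("no surviving trials")
    if prestim_window_ms[0] < epochs.window_ms[0] or prestim_window_ms[1] > epochs.window_ms[1]:
        raise ValueError("pre-stimulus window not covered by the epoch window")
    offset = ms_to_sample(epochs.window_ms[0], epochs.fs)
    lo = ms_to_sample(prestim_window_ms[0], epochs.fs) - offset
    hi = ms_to_sample(prestim_window_ms[1], epochs.fs) - offset
    seg = epochs.data[:, :, lo:hi]
    p_trial = band_power(seg, epochs.fs, band)  # (trials, channels)
    p_mean = p_trial.mean(axis=0)
    ch_db = 10.0 * np.log10(np.maximum(p_mean, np.finfo(float).tiny))
    channel_db = dict(zip(epochs.channel_labels, ch_db))
    if db_average:
        c3c4 = 0.5 * (channel_db["C3"] + channel_db["C4"])
    else:
        c3c4 = 10.0 * np.log10(
            0.5 * (p_mean[epochs.channel_index("C3")] + p_mean[epochs.channel_index("C4")])
        )
    roi = np.array([channel_db[c] for c in ROI_9 if c in channel_db])
    return BandPowerResult(
        channel_db=channel_db,
        band=band,
        window_ms=tuple(prestim_window_ms),
        c3c4_mean=float(c3c4),
        roi_values=roi,
        n_trials=epochs.n_trials,
    )


def erd_timecourse(
    epochs: EpochSet,
    band: BandDefinition,
    baseline_window_ms: tuple = (-1000.0, 0.0),
    smooth_ms: float = 250.0,
):
    """ERD%(t) per channel: 100 * (P(t) - P_ref) / P_ref.

    P(t) is the trial-averaged squared band-filtered signal smoothed with a
    ``smooth_ms`` moving average; P_ref is its mean over the baseline window
    (which must precede the onset).

    Returns ``(times_ms, erd)`` with ``erd`` of shape (n_channels, n_times).
    """
    if baseline_window_ms[1] > 0:
        raise ValueError("baseline window must precede the stimulus onset")
    filt = filter_signal(epochs.data, epochs.fs, "bandpass", band)
    power = (filt**2).mean(axis=0)  # (channels, time)
    k = max(1, round(smooth_ms * epochs.fs / 1000.0))
    kernel = np.ones(k) / k
    smoothed = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, power
    )
    times = epochs.times()
    base = (times >= baseline_window_ms[0]) & (times < baseline_window_ms[1])
    if not base.any():
        raise ValueError("baseline window outside the epoch")
    p_ref = smoothed[:, base].mean(axis=1, keepdims=True)
    if np.any(p_ref <= 0):
        raise ValueError("zero baseline power")
    erd = 100.0 * (smoothed - p_ref) / p_ref
    return times, erd
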