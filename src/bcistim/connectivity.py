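"""Across-trial phase-locking value (PLV) and the ROI-averaged global PLV.

PLV_t = (1/N) |sum_n exp(j * theta(t, n))| where theta is the phase difference
of a channel pair in trial n at time t.  A pair's scalar is the time average
of PLV_t; the global value is the mean over the 36 unordered ROI pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal as _signal

from .io import ROI_9, BandDefinition, EpochSet, filter_signal, ms_to_sample

__all__ = [
    "instantaneous_phase",
    "plv_timecourse",
    "global_plv",
    "PlvResult",
]


def instantaneous_phase(
    epochs: EpochSet,
    band: BandDefinition,
    crop_ms: tuple = (500.0, 3500.0),
) -> tuple:
    """Analytic-signal phase of the band-filtered epochs, cropped to
    ``crop_ms`` after filtering so edge artifacts fall outside the window.

    Returns ``(phases, times_ms)`` with phases (trials, channels, samples).
    """
    if band.hi >= epochs.fs / 2:
        raise ValueError("band outside Nyquist")
    if crop_ms[0] < epochs.window_ms[0] or crop_ms[1] > epochs.window_ms[1]:
        raise ValueError("crop window not covered by the epochs")
    filt = filter_signal(epochs.data, epochs.fs, "bandpass", band)
    analytic = _signal.hilbert(filt, axis=-1)
    offset = ms_to_sample(epochs.window_ms[0], epochs.fs)
    lo = ms_to_sample(crop_ms[0], epochs.fs) - offset
    hi = ms_to_sample(crop_ms[1], epochs.fs) - offset
    phases = np.angle(analytic[:, :, lo:hi])
    times = epochs.times()[lo:hi]
    return phases, times


def plv_timecourse(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    """PLV_t over trials for one channel pair: arrays of shape (trials, time)."""
    phase_a = np.asarray(phase_a)
    phase_b = np.asarray(phase_b)
    if phase_a.shape != phase_b.shape:
        raise ValueError("trial-count/length mismatch between the two phase sets")
    if phase_a.shape[0] < 2:
        raise ValueError("PLV needs at least two trials")
    return np.abs(np.mean(np.exp(1j * (phase_a - phase_b)), axis=0))


@dataclass
class PlvResult:
    pairs: list  # [(chA, chB), ...] unordered ROI pairs
    pair_values: np.ndarray  # time-averaged PLV per pair
    global_value: float  # mean over pairs
    band: str
    label: str
    session: str = ""
    plv_timecourses: np.ndarray | None = None  # (n_pairs, n_times), optional

    def pair_matrix(self, channels=ROI_9) -> np.ndarray:
        m = np.eye(len(channels))
        idx = {c: i for i, c in enumerate(channels)}
        for (a, b), v in zip(self.pairs, self.pair_values):
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
        return m


def global_plv(
    epochs: EpochSet,
    band: BandDefinition,
    label: str,
    roi=ROI_9,
    crop_ms: tuple = (500.0, 3500.0),
    session: str = "",
    keep_timecourses: bool = False,
) -> PlvResult:
    """Global PLV for one class: per-pair time-averaged PLV over the ROI,
    averaged over the unordered pairs."""
    sel = epochs.labels == label
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 trials of class {label!r}")
    sub = EpochSet(
        data=epochs.data[sel],
        window_ms=epochs.window_ms,
        labels=epochs.labels[sel],
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
    ).pick_channels(roi)
    phases, _ = instantaneous_phase(sub, band, crop_ms)
    pairs = list(combinations(range(len(roi)), 2))
    tcs = np.stack(
        [plv_timecourse(phases[:, i, :], phases[:, j, :]) for i, j in pairs]
    )
    pair_values = tcs.mean(axis=1)
    return PlvResult(
        pairs=[(roi[i], roi[j]) for i, j in pairs],
        pair_values=pair_values,
        global_value=float(pair_values.mean()),
        band=band.name,
        label=label,
        session=session,
        plv_timecourses=tcs if keep_timecourses else None,
    )
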