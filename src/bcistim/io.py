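"""Recording/event containers, standard-format I/O, filtering, epoching and
trial/subject rejection rules.

Conventions
-----------
* Samples are microvolts, channels x time, float64.
* Time windows are half-open ``[start_ms, end_ms)`` relative to the stimulus
  onset; the sample index of a millisecond offset is ``round(ms * fs / 1000)``.
* Events travel in a TSV sidecar with columns
  ``onset_sample, class, block, phase, session``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import edf as _edf

#: 19-channel 10–20 montage in recording order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Nine-channel central region of interest used for scoring, band power and PLV.
ROI_9 = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")

#: Channels exempt from the amplitude rejection rule ("near the eyes").
EYE_CHANNELS = ("Fp1", "Fp2")

EVENT_COLUMNS = ("onset_sample", "class", "block", "phase", "session")


@dataclass
class BandDefinition:
    """A named frequency band, half-open ``[lo, hi)`` Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: ({self.lo}, {self.hi})")


ALPHA = BandDefinition("alpha", 8.0, 13.0)
LOW_BETA = BandDefinition("low_beta", 13.0, 20.0)
HIGH_BETA = BandDefinition("high_beta", 20.0, 30.0)
BANDS = {b.name: b for b in (ALPHA, LOW_BETA, HIGH_BETA)}


@dataclass
class RawRecording:
    """Continuous multichannel EEG in µV."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length does not match samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def validate_study_conformant(self, n_channels: int = 19, fs: float = 300.0):
        if len(self.channel_labels) != n_channels:
            raise ValueError(
                f"study-conformant recordings have {n_channels} channels, "
                f"got {len(self.channel_labels)}"
            )
        if abs(self.fs - fs) > 1e-9:
            raise ValueError(f"study-conformant recordings are sampled at {fs} Hz")


@dataclass
class EventTable:
    """Trial onsets and labels, one row per trial."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        if len(self.df) == 0:
            raise ValueError("event table is empty")
        onsets = self.df["onset_sample"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, session=None, phase=None, block=None, label=None) -> "EventTable":
        """Filter trials; ``block`` may be an int or a sequence of ints."""
        m = np.ones(len(self.df), dtype=bool)
        if session is not None:
            m &= (self.df["session"] == session).to_numpy()
        if phase is not None:
            m &= (self.df["phase"] == phase).to_numpy()
        if block is not None:
            blocks = [block] if np.isscalar(block) else list(block)
            m &= self.df["block"].isin(blocks).to_numpy()
        if label is not None:
            m &= (self.df["class"] == label).to_numpy()
        if not m.any():
            raise ValueError("selector matched no trials")
        return EventTable(self.df[m])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        if len(df) == 0:
            raise ValueError(f"event file {path} contains no events")
        return cls(df)


@dataclass
class EpochSet:
    """Trials x channels x samples cut from a recording."""

    data: np.ndarray
    window_ms: tuple
    labels: np.ndarray
    fs: float
    channel_labels: tuple
    events: pd.DataFrame | None = None
    rejection_mask: np.ndarray | None = None  # True = rejected

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channel_labels = tuple(self.channel_labels)
        n_samp = round((self.window_ms[1] - self.window_ms[0]) * self.fs / 1000)
        if self.data.shape[2] != n_samp:
            raise ValueError("epoch length inconsistent with window_ms and fs")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def pick_channels(self, labels: Sequence[str]) -> "EpochSet":
        idx = [self.channel_index(lab) for lab in labels]
        return replace(self, data=self.data[:, idx, :], channel_labels=tuple(labels))

    def times(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus onset."""
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs


def ms_to_sample(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def filter_signal(
    x: np.ndarray,
    fs: float,
    kind: str,
    band: BandDefinition,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-pass or band-stop."""
    if band.hi >= fs / 2:
        raise ValueError(f"band edge {band.hi} Hz at or above Nyquist ({fs / 2} Hz)")
    if kind not in ("bandpass", "bandstop"):
        raise ValueError(f"kind must be 'bandpass' or 'bandstop', got {kind!r}")
    sos = signal.butter(order, [band.lo, band.hi], btype=kind, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def extract_epochs(
    raw: RawRecording,
    events: EventTable,
    window_ms: tuple,
    session=None,
    phase=None,
    block=None,
    label=None,
) -> EpochSet:
    """Cut half-open windows ``[onset+start, onset+end)`` around each onset."""
    if any(v is not None for v in (session, phase, block, label)):
        events = events.select(session=session, phase=phase, block=block, label=label)
    start = ms_to_sample(window_ms[0], raw.fs)
    stop = ms_to_sample(window_ms[1], raw.fs)
    onsets = events.df["onset_sample"].to_numpy()
    if (onsets + start < 0).any() or (onsets + stop > raw.n_samples).any():
        raise ValueError("requested epoch window exceeds recording bounds")
    data = np.stack([raw.samples[:, o + start : o + stop] for o in onsets])
    return EpochSet(
        data=data,
        window_ms=tuple(window_ms),
        labels=events.df["class"].to_numpy(),
        fs=raw.fs,
        channel_labels=raw.channel_labels,
        events=events.df.copy(),
    )


def reject_epochs(
    epochs: EpochSet,
    threshold_uv: float = 100.0,
    excluded_channels: Sequence[str] = EYE_CHANNELS,
):
    """Flag trials whose amplitude exceeds ±threshold on any non-excluded channel.

    The rule is strict ("greater than"): a peak of exactly ``threshold_uv``
    is kept.  Returns ``(kept_epochs, mask)`` where ``mask[i]`` is True for
    rejected trials of the input set.
    """
    excluded = [c for c in excluded_channels if c in epochs.channel_labels]
    unknown = set(excluded_channels) - set(CHANNELS_1020) - set(epochs.channel_labels)
    if unknown:
        raise KeyError(f"unknown excluded channels {sorted(unknown)}")
    keep_ch = [i for i, c in enumerate(epochs.channel_labels) if c not in excluded]
    peak = np.abs(epochs.data[:, keep_ch, :]).max(axis=(1, 2))
    mask = peak > threshold_uv
    kept = replace(
        epochs,
        data=epochs.data[~mask],
        labels=epochs.labels[~mask],
        events=None if epochs.events is None else epochs.events[~mask],
        rejection_mask=np.zeros(int((~mask).sum()), dtype=bool),
    )
    return kept, mask


def subject_quality(mask: np.ndarray) -> str:
    """'exclude' iff more than 30% of trials are bad (strict inequality)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty rejection mask")
    return "exclude" if mask.mean() > 0.30 else "keep"


def write_recording(raw: RawRecording, events: EventTable, out_dir) -> Path:
    """Write ``recording.edf`` + ``events.tsv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _edf.write_edf(
        out / "recording.edf",
        raw.samples,
        raw.fs,
        raw.channel_labels,
        patient=str(raw.meta.get("subject", "X")),
    )
    events.to_tsv(out / "events.tsv")
    return out


def read_recording(path, study_conformant: bool = False):
    """Read a subject directory (``recording.edf`` + ``events.tsv``)."""
    p = Path(path)
    edf_path = p / "recording.edf" if p.is_dir() else p
    samples, fs, labels = _edf.read_edf(edf_path)
    raw = RawRecording(samples=samples, fs=fs, channel_labels=labels)
    if study_conformant:
        raw.validate_study_conformant()
    events = EventTable.from_tsv(edf_path.parent / "events.tsv")
    last = events.df["onset_sample"].max()
    if last >= raw.n_samples:
        raise ValueError("event onsets exceed recording length")
    return raw, events
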