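"""Offline simulator of the closed-loop alpha-falling-phase vibrotactile trigger.

Per trial, a 500 ms window of the contralateral central channel (C4 for
left-hand imagery, C3 for right-hand) is taken every 50 ms (450 ms overlap),
causally band-pass filtered 8-13 Hz with a 10th-order elliptic IIR filter, and
the FFT-dominant in-band component yields a sine model used to predict the
phase one step ahead.  When the predicted phase is falling (cosine convention,
phase in (0, pi)) and no stimulation/ISI lock is active, a 100 ms stimulation
is logged, followed by a 100 ms inter-stimulation interval.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, signal, stats

from .io import EventTable, RawRecording

__all__ = [
    "StimParams",
    "PhaseEstimate",
    "StimulationEvent",
    "StimulationLog",
    "estimate_phase",
    "predict_phase_at",
    "simulate_closed_loop",
    "stimulation_metrics",
    "StimulationMetrics",
]

TWO_PI = 2.0 * np.pi


@dataclass
class StimParams:
    window_s: float = 0.5
    step_s: float = 0.05
    band: tuple = (8.0, 13.0)
    filter_order: int = 10  # band-pass order (2 x design sections)
    ripple_db: float = 1.0
    stop_db: float = 40.0
    stim_duration_s: float = 0.1
    isi_s: float = 0.1
    horizon_s: float = 0.05  # prediction horizon = one step
    imagery_s: float = 4.0
    nfft: int = 4096

    @property
    def lockout_s(self) -> float:
        return self.stim_duration_s + self.isi_s


@dataclass
class PhaseEstimate:
    window_end_time: float  # s, relative to the window stream origin
    dominant_freq: float  # Hz, inside the band
    phase_at_window_end: float  # radians in [0, 2pi), cosine convention
    amplitude: float  # µV
    low_confidence: bool = False


@dataclass
class StimulationEvent:
    trial: int
    onset_time: float  # s relative to the stimulus (imagery) onset
    duration_s: float
    driving_channel: str
    predicted_phase: float


@dataclass
class StimulationLog:
    events: list
    params: StimParams

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"params": asdict(self.params), "events": [asdict(e) for e in self.events]}
            )
        )

    @classmethod
    def from_json(cls, path) -> "StimulationLog":
        d = json.loads(Path(path).read_text())
        return cls(
            events=[StimulationEvent(**e) for e in d["events"]],
            params=StimParams(**{k: tuple(v) if k == "band" else v
                                 for k, v in d["params"].items()}),
        )


def design_filter(fs: float, params: StimParams | None = None):
    p = params or StimParams()
    if p.filter_order % 2:
        raise ValueError("band-pass filter order must be even")
    return signal.ellip(
        p.filter_order // 2, p.ripple_db, p.stop_db, p.band, btype="bandpass",
        fs=fs, output="sos",
    )


def _sine_fit(window_f: np.ndarray, f: float, fs: float):
    """Least-squares cos/sin fit at frequency f; returns (a, b, residual)."""
    t = np.arange(len(window_f)) / fs
    basis = np.column_stack([np.cos(TWO_PI * f * t), np.sin(TWO_PI * f * t)])
    coef, *_ = np.linalg.lstsq(basis, window_f, rcond=None)
    r = window_f - basis @ coef
    return coef[0], coef[1], float(r @ r)


def _phase_from_filtered(window_f: np.ndarray, fs: float, p: StimParams, sos):
    """Sine-model fit of a causally filtered window.

    The dominant in-band bin of the zero-padded FFT seeds a least-squares
    sinusoid fit whose frequency is refined by residual minimization inside
    the band (the two-component cos/sin basis removes the negative-frequency
    leakage that biases a bare FFT-peak phase).  The fitted phase is corrected
    for the causal filter's phase response at the refined frequency and
    propagated analytically to the window-end instant.
    """
    n = len(window_f)
    spec = np.fft.rfft(window_f, n=p.nfft)
    freqs = np.fft.rfftfreq(p.nfft, d=1.0 / fs)
    inband = (freqs >= p.band[0]) & (freqs <= p.band[1])
    mags = np.abs(spec[inband])
    k = int(np.argmax(mags))
    f0 = float(freqs[inband][k])
    if mags[k] <= 0.0:
        return sum(p.band) / 2.0, 0.0, 0.0, True
    lo = max(p.band[0], f0 - 1.2)
    hi = min(p.band[1], f0 + 1.2)
    res = optimize.minimize_scalar(
        lambda f: _sine_fit(window_f, f, fs)[2],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-5},
    )
    f_hat = float(res.x)
    a, b, _ = _sine_fit(window_f, f_hat, fs)
    _, h = signal.sosfreqz(sos, worN=[f_hat], fs=fs)
    h = complex(h[0])
    gain = abs(h)
    amp_f = float(np.hypot(a, b))
    low_conf = amp_f <= 0.0 or gain < 1e-12
    amp = amp_f / max(gain, 1e-12)
    phase_start = np.arctan2(-b, a)
    phase_end = phase_start + TWO_PI * f_hat * (n / fs)
    if not low_conf:
        phase_end -= np.angle(h)
    return f_hat, float(np.mod(phase_end, TWO_PI)), amp, bool(low_conf)


def estimate_phase(window: np.ndarray, fs: float, params: StimParams | None = None) -> PhaseEstimate:
    """Phase/frequency estimate from one 500 ms single-channel window.

    The causal elliptic filter is warm-started by running it over the window a
    few times carrying its state (periodic-extension steady state), so a lone
    window gives the same answer a continuous stream would.
    """
    p = params or StimParams()
    window = np.asarray(window, dtype=float).ravel()
    expected = round(p.window_s * fs)
    if len(window) != expected:
        raise ValueError(f"window must hold {expected} samples at fs={fs}")
    sos = design_filter(fs, p)
    zi = np.zeros((sos.shape[0], 2))
    for _ in range(8):  # warm-up passes
        _, zi = signal.sosfilt(sos, window, zi=zi)
    wf, _ = signal.sosfilt(sos, window, zi=zi)
    if not np.any(window):
        return PhaseEstimate(p.window_s, sum(p.band) / 2, 0.0, 0.0, low_confidence=True)
    f_hat, phase_end, amp, low_conf = _phase_from_filtered(wf, fs, p, sos)
    return PhaseEstimate(
        window_end_time=len(window) / fs,
        dominant_freq=f_hat,
        phase_at_window_end=phase_end,
        amplitude=amp,
        low_confidence=low_conf,
    )


def predict_phase_at(estimate: PhaseEstimate, horizon: float):
    """Extrapolate the sine model: phase(t+h) = phase(t) + 2 pi f h, and flag
    whether the cosine is falling there (phase in (0, pi))."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    phase = np.mod(estimate.phase_at_window_end + TWO_PI * estimate.dominant_freq * horizon, TWO_PI)
    return float(phase), bool(0.0 < phase < np.pi)


def simulate_closed_loop(
    raw: RawRecording,
    events: EventTable,
    params: StimParams | None = None,
    session=None,
    phase=None,
) -> StimulationLog:
    """Run the streaming trigger over every (selected) imagery trial.

    The driving channel is C4 for left-hand trials and C3 for right-hand
    trials.  Decisions are causal: the decision issued at window end t applies
    one step later (the prediction horizon), and each stimulation locks the
    trigger for stim duration + ISI.
    """
    p = params or StimParams()
    fs = raw.fs
    sos = design_filter(fs, p)
    if session is not None or phase is not None:
        events = events.select(session=session, phase=phase)
    for ch in ("C3", "C4"):
        raw.channel_index(ch)
    win = round(p.window_s * fs)
    step = round(p.step_s * fs)
    span = round(p.imagery_s * fs)
    out: list = []
    onsets = events.df["onset_sample"].to_numpy()
    classes = events.df["class"].to_numpy()
    warm = round(1.0 * fs)  # causal pre-onset warmup of the filter state
    for ti, (onset, lab) in enumerate(zip(onsets, classes)):
        drive = "C4" if lab == "left" else "C3"
        ci = raw.channel_index(drive)
        pre = raw.samples[ci, max(0, onset - warm) : onset]
        x = raw.samples[ci, onset : onset + span]
        _, zi = signal.sosfilt(sos, pre, zi=np.zeros((sos.shape[0], 2)))
        xf, _ = signal.sosfilt(sos, x, zi=zi)  # one causal pass per trial
        lock_until = -np.inf
        for end in range(win, len(x) + 1, step):
            f_hat, phase_end, amp, low_conf = _phase_from_filtered(
                xf[end - win : end], fs, p, sos
            )
            if low_conf or amp <= 1e-9:
                continue
            est = PhaseEstimate(end / fs, f_hat, phase_end, amp, low_conf)
            pred, falling = predict_phase_at(est, p.horizon_s)
            t_onset = end / fs + p.horizon_s
            unlocked = t_onset >= lock_until - 1e-9  # tolerate float jitter at exact expiry
            if falling and unlocked and t_onset + p.stim_duration_s <= p.imagery_s:
                out.append(
                    StimulationEvent(
                        trial=ti,
                        onset_time=float(t_onset),
                        duration_s=p.stim_duration_s,
                        driving_channel=drive,
                        predicted_phase=pred,
                    )
                )
                lock_until = t_onset + p.lockout_s
    return StimulationLog(events=out, params=p)


@dataclass
class StimulationMetrics:
    falling_coverage_pct: float  # % of falling half-cycles holding a stim onset
    unstimulated_pct: float  # % of falling half-cycles inside inter-stim intervals
    targeting_accuracy_pct: float | None  # % of onsets with true phase in (0, pi)
    circular_mean: float | None
    circular_sd: float | None
    n_events: int
    n_half_cycles: int


def _falling_half_cycles(phase_track: np.ndarray, fs: float):
    """Start/end times of maximal falling runs (phase in (0, pi)) of a phase
    track sampled at fs with time origin 0."""
    ph = np.mod(phase_track, TWO_PI)
    falling = (ph > 0) & (ph < np.pi)
    edges = np.diff(falling.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if falling[0]:
        starts = np.r_[0, starts]
    if falling[-1]:
        ends = np.r_[ends, len(falling)]
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def stimulation_metrics(
    log: StimulationLog,
    phase_tracks: dict,
    fs: float,
) -> StimulationMetrics:
    """Score a stimulation log against true phase tracks.

    ``phase_tracks`` maps trial index -> instantaneous phase array over the
    imagery span (time origin = stimulus onset, sampled at fs).  Per trial,
    falling half-cycles are counted over the span the loop was active: from
    the half-cycle holding the first stimulation onset to the one holding the
    last.  A half-cycle with no onset inside it lies within an
    inter-stimulation interval.
    """
    by_trial: dict = {}
    for ev in log.events:
        by_trial.setdefault(ev.trial, []).append(ev.onset_time)
    n_half = 0
    n_stimulated = 0
    onset_phases = []
    for ti, track in phase_tracks.items():
        onsets = np.asarray(sorted(by_trial.get(ti, [])))
        if onsets.size == 0:
            continue
        cycles = _falling_half_cycles(np.asarray(track, dtype=float), fs)
        hit = [i for i, (ts, te) in enumerate(cycles)
               if np.any((onsets >= ts) & (onsets < te))]
        for t in onsets:
            idx = min(int(round(t * fs)), len(track) - 1)
            onset_phases.append(np.mod(track[idx], TWO_PI))
        if not hit:
            continue  # no onset landed in any falling run
        active = cycles[hit[0] : hit[-1] + 1]
        n_half += len(active)
        for ts, te in active:
            if np.any((onsets >= ts) & (onsets < te)):
                n_stimulated += 1
    coverage = 100.0 * n_stimulated / n_half if n_half else 0.0
    if onset_phases:
        phases = np.asarray(onset_phases)
        targeting = 100.0 * float(np.mean((phases > 0) & (phases < np.pi)))
        cmean = float(stats.circmean(phases, high=TWO_PI))
        csd = float(stats.circstd(phases, high=TWO_PI))
    else:
        targeting = cmean = csd = None
    return StimulationMetrics(
        falling_coverage_pct=coverage,
        unstimulated_pct=100.0 - coverage if n_half else 0.0,
        targeting_accuracy_pct=targeting,
        circular_mean=cmean,
        circular_sd=csd,
        n_events=len(log.events),
        n_half_cycles=n_half,
    )
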