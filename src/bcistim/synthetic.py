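"""Synthetic sensorimotor EEG subjects.

Generates continuous 19-channel recordings with the statistical structure the
downstream analyses measure: 1/f background noise, alpha (10 Hz) and low-beta
(17 Hz) carriers on every channel, class-dependent contralateral amplitude
attenuation (ERD) at C3/C4 during the imagery window, von-Mises phase coupling
across channels, and optional high-amplitude artifact pulses.

Trial layout (seconds): 1.5 fixation | 4.0 imagery | 1.5 blank.  The stimulus
onset marked in the event table is the start of the imagery span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .io import CHANNELS_1020, EYE_CHANNELS, EventTable, RawRecording

__all__ = [
    "PostEffect",
    "SyntheticConfig",
    "GroundTruth",
    "generate_subject",
    "make_phase_coupled_signals",
    "inject_artifacts",
]


@dataclass
class PostEffect:
    """Additive parameter changes applied in the post session."""

    erd_depth: float = 0.0
    prestim_alpha_amp: float = 0.0
    coupling: float = 0.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    fs: float = 300.0
    channel_labels: tuple = CHANNELS_1020
    n_trials_per_block: int = 40
    n_blocks_offline: int = 2
    n_blocks_online: int = 2
    sessions: tuple = ("pre", "post")
    fixation_s: float = 1.5
    imagery_s: float = 4.0
    blank_s: float = 1.5
    erd_depth: float = 0.6
    erd_window_s: tuple = (0.5, 3.5)  # relative to stimulus onset
    erd_ramp_s: float = 0.1
    prestim_alpha_amp: float = 12.0  # µV
    beta_amp: float = 6.0
    alpha_freq: float = 10.0
    beta_freq: float = 17.0
    coupling: float | tuple = 0.3  # scalar, or one value per channel
    amp_jitter: float = 0.5  # lognormal sigma on per-trial carrier amplitude
    noise_rms: float = 10.0
    noise_exponent: float = 1.0
    artifact_rate: float = 0.0
    artifact_amp: float = 150.0
    post_effect: PostEffect = field(default_factory=PostEffect)

    def __post_init__(self):
        if isinstance(self.post_effect, dict):
            self.post_effect = PostEffect(**self.post_effect)
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("duplicate channel labels")
        for name in ("erd_depth", "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for c in np.atleast_1d(np.asarray(self.coupling, dtype=float)):
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coupling values must lie in [0, 1], got {c}")
        numeric = [
            self.fs, self.erd_depth, self.prestim_alpha_amp, self.beta_amp,
            self.alpha_freq, self.beta_freq, self.noise_rms, self.noise_exponent,
            self.post_effect.erd_depth, self.post_effect.prestim_alpha_amp,
            self.post_effect.coupling,
        ]
        if not np.all(np.isfinite(numeric)):
            raise ValueError("configuration contains non-finite values")
        if self.fs <= 2 * max(self.alpha_freq, self.beta_freq):
            raise ValueError("fs must exceed twice the highest synthesized frequency")
        if self.fs <= 0 or self.n_trials_per_block < 1:
            raise ValueError("invalid fs or trial count")
        if {"C3", "C4"} - set(self.channel_labels):
            raise ValueError("channel set must include C3 and C4")

    @property
    def n_blocks(self) -> int:
        return self.n_blocks_offline + self.n_blocks_online

    @property
    def trial_len(self) -> int:
        return round((self.fixation_s + self.imagery_s + self.blank_s) * self.fs)

    @property
    def trials_per_session(self) -> int:
        return self.n_blocks * self.n_trials_per_block

    def coupling_per_channel(self) -> np.ndarray:
        c = np.asarray(self.coupling, dtype=float)
        if c.ndim == 0:
            return np.full(len(self.channel_labels), float(c))
        if c.shape != (len(self.channel_labels),):
            raise ValueError("per-channel coupling must have one value per channel")
        return c


def _kappa(coupling: np.ndarray) -> np.ndarray:
    """Map a [0,1] coupling dial to a von-Mises concentration."""
    c = np.clip(coupling, 0.0, 1.0)
    return c / (1.0 - c + 1e-9)


def _mean_resultant(kappa: np.ndarray) -> np.ndarray:
    """E|e^{i theta}| of a von-Mises variable: I1(k)/I0(k)."""
    k = np.asarray(kappa, dtype=float)
    out = np.ones_like(k)
    small = k < 650  # i0 overflows beyond ~700; the ratio is 1 to double precision
    out[small] = special.i1(k[small]) / special.i0(k[small])
    return out


@dataclass
class GroundTruth:
    """Per-trial generation record (oracle for recovery tests)."""

    labels: list  # "left" / "right" per trial
    artifact: np.ndarray  # bool per trial
    pair_coupling: np.ndarray  # (n_ch, n_ch) predicted across-trial PLV
    alpha_freq: float
    fs: float
    trial_len: int
    onset_in_trial: int  # sample offset of the stimulus onset within a trial
    alpha_phase0: np.ndarray  # (n_trials, 2) phase at trial start for (C3, C4)

    def phase_track(self, trial: int, channel: str) -> np.ndarray:
        """Instantaneous alpha phase (cosine convention, radians in [0, 2π))
        over the full trial, at C3 or C4."""
        col = {"C3": 0, "C4": 1}[channel]
        t = np.arange(self.trial_len) / self.fs
        return np.mod(2 * np.pi * self.alpha_freq * t + self.alpha_phase0[trial, col], 2 * np.pi)

    def onset_phase_track(self, trial: int, channel: str) -> np.ndarray:
        """Alpha phase over the imagery span, time origin at the stimulus onset."""
        return self.phase_track(trial, channel)[self.onset_in_trial :]

    def to_json(self, path) -> None:
        payload = {
            "labels": list(self.labels),
            "artifact": np.asarray(self.artifact, dtype=bool).tolist(),
            "pair_coupling": np.asarray(self.pair_coupling).tolist(),
            "alpha_freq": self.alpha_freq,
            "fs": self.fs,
            "trial_len": self.trial_len,
            "onset_in_trial": self.onset_in_trial,
            "alpha_phase0": np.asarray(self.alpha_phase0).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            labels=d["labels"],
            artifact=np.asarray(d["artifact"], dtype=bool),
            pair_coupling=np.asarray(d["pair_coupling"]),
            alpha_freq=d["alpha_freq"],
            fs=d["fs"],
            trial_len=d["trial_len"],
            onset_in_trial=d["onset_in_trial"],
            alpha_phase0=np.asarray(d["alpha_phase0"]),
        )


def _powerlaw_noise(rng, n_ch, n_samp, fs, exponent, rms):
    """1/f^exponent Gaussian noise, normalized per channel to the target RMS."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samp, axis=1)
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def _erd_envelope(n, fs, onset, window_s, ramp_s, depth):
    """Multiplicative amplitude envelope: 1 outside, (1-depth) inside the ERD
    window, raised-cosine ramps of ``ramp_s`` at both edges."""
    env = np.ones(n)
    if depth == 0:
        return env
    t = (np.arange(n) - onset) / fs
    lo, hi = window_s
    core = (t >= lo + ramp_s) & (t < hi - ramp_s)
    env[core] = 1.0 - depth
    up = (t >= lo) & (t < lo + ramp_s)
    frac = (t[up] - lo) / ramp_s
    env[up] = 1.0 - depth * 0.5 * (1 - np.cos(np.pi * frac))
    down = (t >= hi - ramp_s) & (t < hi)
    frac = (t[down] - (hi - ramp_s)) / ramp_s
    env[down] = 1.0 - depth * 0.5 * (1 + np.cos(np.pi * frac))
    return env


def generate_subject(config: SyntheticConfig):
    """Generate one subject: continuous recording over all sessions/blocks,
    an event table, and the generation ground truth.

    Deterministic: identical config (including seed) gives bit-identical output.
    """
    cfg = config
    fs = cfg.fs
    rng = np.random.default_rng(cfg.seed)
    n_ch = len(cfg.channel_labels)
    trial_len = cfg.trial_len
    onset_in_trial = round(cfg.fixation_s * fs)
    trials_per_session = cfg.trials_per_session
    n_trials = trials_per_session * len(cfg.sessions)
    n_total = n_trials * trial_len

    samples = _powerlaw_noise(rng, n_ch, n_total, fs, cfg.noise_exponent, cfg.noise_rms)

    c3 = cfg.channel_labels.index("C3")
    c4 = cfg.channel_labels.index("C4")
    contra = {"left": c4, "right": c3}

    rows = []
    labels_all: list = []
    phase0 = np.zeros((n_trials, 2))
    coupling_base = cfg.coupling_per_channel()
    t_rel = np.arange(trial_len) / fs

    trial_idx = 0
    session_couplings = {}
    for session in cfg.sessions:
        erd = cfg.erd_depth
        alpha_amp = cfg.prestim_alpha_amp
        coupling = coupling_base
        if session == "post":
            erd = float(np.clip(erd + cfg.post_effect.erd_depth, 0.0, 1.0))
            alpha_amp = max(0.0, alpha_amp + cfg.post_effect.prestim_alpha_amp)
            coupling = np.clip(coupling + cfg.post_effect.coupling, 0.0, 1.0)
        kappa = _kappa(coupling)
        session_couplings[session] = coupling
        for block in range(1, cfg.n_blocks + 1):
            phase_name = "offline" if block <= cfg.n_blocks_offline else "online"
            # balanced, shuffled class sequence per block
            half = cfg.n_trials_per_block // 2
            block_labels = ["left"] * half + ["right"] * (cfg.n_trials_per_block - half)
            rng.shuffle(block_labels)
            for lab in block_labels:
                start = trial_idx * trial_len
                ref_alpha = rng.uniform(0, 2 * np.pi)
                ref_beta = rng.uniform(0, 2 * np.pi)
                jit_a = np.where(
                    kappa > 1e8, 0.0, rng.vonmises(0.0, np.minimum(kappa, 1e8), n_ch)
                )
                jit_b = np.where(
                    kappa > 1e8, 0.0, rng.vonmises(0.0, np.minimum(kappa, 1e8), n_ch)
                )
                amp_scale = np.exp(cfg.amp_jitter * rng.standard_normal(n_ch))
                ph_a = np.mod(ref_alpha + jit_a, 2 * np.pi)
                ph_b = np.mod(ref_beta + jit_b, 2 * np.pi)
                env = np.ones((n_ch, trial_len))
                env[contra[lab]] = _erd_envelope(
                    trial_len, fs, onset_in_trial, cfg.erd_window_s,
                    cfg.erd_ramp_s, erd,
                )
                carrier = (
                    alpha_amp * np.cos(2 * np.pi * cfg.alpha_freq * t_rel + ph_a[:, None])
                    + cfg.beta_amp * np.cos(2 * np.pi * cfg.beta_freq * t_rel + ph_b[:, None])
                )
                samples[:, start : start + trial_len] += amp_scale[:, None] * env * carrier
                phase0[trial_idx] = (ph_a[c3], ph_a[c4])
                rows.append(
                    dict(
                        onset_sample=start + onset_in_trial,
                        **{"class": lab},
                        block=block,
                        phase=phase_name,
                        session=session,
                    )
                )
                labels_all.append(lab)
                trial_idx += 1

    # predicted across-trial PLV for each pair: product of the channels'
    # von-Mises mean resultant lengths (pre-session coupling)
    r = _mean_resultant(_kappa(session_couplings[cfg.sessions[0]]))
    pair_coupling = np.outer(r, r)
    np.fill_diagonal(pair_coupling, 1.0)

    raw = RawRecording(
        samples=samples,
        fs=fs,
        channel_labels=cfg.channel_labels,
        meta={"subject": f"sim{cfg.seed:04d}", "seed": cfg.seed},
    )
    events = EventTable(pd.DataFrame(rows))
    truth = GroundTruth(
        labels=labels_all,
        artifact=np.zeros(n_trials, dtype=bool),
        pair_coupling=pair_coupling,
        alpha_freq=cfg.alpha_freq,
        fs=fs,
        trial_len=trial_len,
        onset_in_trial=onset_in_trial,
        alpha_phase0=phase0,
    )

    if cfg.artifact_rate > 0:
        raw = inject_artifacts(
            raw, events, cfg.artifact_rate, cfg.artifact_amp,
            seed=cfg.seed + 1, truth=truth,
        )
    return raw, events, truth


def make_phase_coupled_signals(fs, duration, f0, coupling, n_trials=40, seed=0):
    """Two banks of single-frequency trials whose across-trial phase-difference
    dispersion is controlled by ``coupling``.

    coupling=1: constant phase difference (PLV 1).  coupling=0: independent
    uniform phases per trial (PLV ~ sqrt(pi)/(2 sqrt(N))).

    Returns two arrays of shape (n_trials, n_samples).
    """
    if not (0.0 <= coupling <= 1.0):
        raise ValueError(f"coupling must lie in [0, 1], got {coupling}")
    if not (0 < f0 < fs / 2):
        raise ValueError("f0 must lie below Nyquist")
    rng = np.random.default_rng(seed)
    n = round(duration * fs)
    t = np.arange(n) / fs
    kappa = float(_kappa(np.asarray(coupling)))
    ref = rng.uniform(0, 2 * np.pi, n_trials)
    if coupling >= 1.0 - 1e-12:
        ja = jb = np.zeros(n_trials)
    else:
        ja = rng.vonmises(0.0, min(kappa, 1e8), n_trials)
        jb = rng.vonmises(0.0, min(kappa, 1e8), n_trials)
    x = np.cos(2 * np.pi * f0 * t[None, :] + (ref + ja)[:, None])
    y = np.cos(2 * np.pi * f0 * t[None, :] + (ref + jb)[:, None])
    return x, y


def inject_artifacts(
    raw: RawRecording,
    events: EventTable,
    rate: float,
    amplitude_uv: float = 150.0,
    seed: int = 0,
    truth: GroundTruth | None = None,
    scoring_window_ms: tuple = (500.0, 3500.0),
) -> RawRecording:
    """Add a 200 ms biphasic pulse exceeding ±amplitude to a ``rate`` fraction
    of trials, on a random non-eye channel inside the scoring window.

    Updates ``truth.artifact`` in place when provided; returns a new recording.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if amplitude_uv <= 100.0:
        raise ValueError("artifact amplitude must exceed the 100 µV rejection bound")
    rng = np.random.default_rng(seed)
    n_trials = len(events)
    n_hit = round(rate * n_trials)
    hit = rng.choice(n_trials, size=n_hit, replace=False)
    fs = raw.fs
    # 200 ms Hann-windowed 15 Hz burst: biphasic lobes, and its energy sits
    # inside both analysis bands (8-30 and 1-40 Hz) so the amplitude check
    # still sees it after band-pass filtering.
    pulse_len = round(0.2 * fs)
    tp = np.arange(pulse_len) / fs
    pulse = np.hanning(pulse_len) * np.sin(2 * np.pi * 15.0 * tp)
    pulse *= 1.3 * amplitude_uv / np.abs(pulse).max()
    eligible = [i for i, c in enumerate(raw.channel_labels) if c not in EYE_CHANNELS]
    samples = raw.samples.copy()
    lo = round(scoring_window_ms[0] * fs / 1000)
    hi = round(scoring_window_ms[1] * fs / 1000) - pulse_len
    onsets = events.df["onset_sample"].to_numpy()
    for ti in sorted(hit):
        ch = eligible[rng.integers(len(eligible))]
        pos = onsets[ti] + int(rng.integers(lo, hi))
        samples[ch, pos : pos + pulse_len] += pulse
        if truth is not None:
            truth.artifact[ti] = True
    return RawRecording(
        samples=samples, fs=fs, channel_labels=raw.channel_labels, meta=dict(raw.meta)
    )


def save_subject(raw, events, truth, out_dir):
    """Write recording.edf + events.tsv + ground_truth.json."""
    from .io import write_recording

    out = write_recording(raw, events, out_dir)
    truth.to_json(out / "ground_truth.json")
    return out
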