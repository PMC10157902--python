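"""Motor-imagery BCI scoring.

Offline path (canonical for headline numbers): trial covariance matrices on
the 9-channel central region of interest, Riemannian minimum-distance-to-mean
(MDM) classification with affine-invariant geometry, trained on the two
offline blocks and tested on the two online blocks.

Online-protocol emulation: CSP spatial filters + Fisher LDA on log-variance
features, in both hyper-parameter variants (19 channels / first+last two
filters, or 9 channels / first+last filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .io import (
    ROI_9,
    BandDefinition,
    EpochSet,
    EventTable,
    RawRecording,
    extract_epochs,
    filter_signal,
    reject_epochs,
    subject_quality,
)

__all__ = [
    "estimate_covariance",
    "riemannian_distance",
    "geometric_mean",
    "MdmModel",
    "fit_mdm",
    "predict_mdm",
    "CspModel",
    "FldaModel",
    "train_online_classifier",
    "predict_online",
    "PerformanceRecord",
    "evaluate_offline_accuracy",
    "score_subject",
    "chance_threshold",
    "assign_performance_group",
]


# ---------------------------------------------------------------------------
# SPD geometry
# ---------------------------------------------------------------------------

def estimate_covariance(epoch: np.ndarray, shrinkage: float = 1e-6) -> np.ndarray:
    """Mean-removed sample covariance (divisor T-1) with a trace-scaled
    diagonal shrinkage guaranteeing positive definiteness."""
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("epoch must be channels x samples with >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite values")
    x = x - x.mean(axis=1, keepdims=True)
    c = x @ x.T / (x.shape[1] - 1)
    d = c.shape[0]
    lam = shrinkage * max(np.trace(c), np.finfo(float).tiny) / d
    c += lam * np.eye(d)
    return 0.5 * (c + c.T)


def _check_spd(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T, atol=1e-9 * max(1.0, np.abs(a).max())):
        raise ValueError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(a).min() <= 0:
        raise ValueError(f"{name} is not positive definite")
    return 0.5 * (a + a.T)


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant distance ||log(A^{-1/2} B A^{-1/2})||_F, computed via
    the generalized eigenvalues of (B, A)."""
    a = _check_spd(a, "A")
    b = _check_spd(b, "B")
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    w = linalg.eigh(b, a, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def _sqrtm_spd(a: np.ndarray):
    w, v = np.linalg.eigh(a)
    w = np.maximum(w, 0.0)
    s = (v * np.sqrt(w)) @ v.T
    si = (v * (1.0 / np.sqrt(np.maximum(w, np.finfo(float).tiny)))) @ v.T
    return s, si


def _logm_spd(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    return (v * np.log(w)) @ v.T


def _expm_sym(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    return (v * np.exp(w)) @ v.T


def geometric_mean(matrices, tol: float = 1e-7, max_iter: int = 200) -> np.ndarray:
    """Karcher (Fréchet) mean under the affine-invariant metric.

    Fixed-point iteration X <- X^{1/2} exp(mean_i log(X^{-1/2} C_i X^{-1/2}))
    X^{1/2}, initialized at the arithmetic mean.  Converges when the tangent
    gradient norm drops below ``tol`` (or stagnates at the double-precision
    floor just under 1e-6); genuine non-convergence raises.
    """
    mats = [_check_spd(m, f"matrices[{i}]") for i, m in enumerate(matrices)]
    if not mats:
        raise ValueError("need at least one matrix")
    if len({m.shape for m in mats}) != 1:
        raise ValueError("matrices must share a dimension")
    if len(mats) == 1:
        return mats[0].copy()
    x = np.mean(mats, axis=0)
    prev = np.inf
    for _ in range(max_iter):
        s, si = _sqrtm_spd(x)
        grad = np.mean([_logm_spd(si @ c @ si) for c in mats], axis=0)
        grad = 0.5 * (grad + grad.T)
        gnorm = np.linalg.norm(grad, "fro")
        if gnorm < tol or (gnorm < 1e-6 and gnorm >= 0.5 * prev):
            return 0.5 * (x + x.T)
        prev = gnorm
        x = s @ _expm_sym(grad) @ s
    raise RuntimeError(
        f"Karcher mean did not converge within {max_iter} iterations "
        f"(gradient norm {gnorm:.2e})"
    )


# ---------------------------------------------------------------------------
# MDM
# ---------------------------------------------------------------------------

@dataclass
class MdmModel:
    class_means: dict  # label -> SPD matrix
    classes: tuple  # sorted label order (tie-break: first wins)
    channel_labels: tuple = ()


def fit_mdm(train_epochs: np.ndarray, labels, channel_labels=()) -> MdmModel:
    """Fit per-class Riemannian geometric means of trial covariances."""
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least two classes in the training set")
    means = {}
    for cls in classes:
        covs = [estimate_covariance(e) for e in np.asarray(train_epochs)[labels == cls]]
        if len(covs) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 training trials")
        means[cls] = geometric_mean(covs)
    return MdmModel(class_means=means, classes=classes, channel_labels=tuple(channel_labels))


def predict_mdm(model: MdmModel, epoch: np.ndarray):
    """Argmin-distance class for one trial (channels x samples) or a
    pre-computed covariance matrix; ties go to the first class in sorted order."""
    epoch = np.asarray(epoch, dtype=float)
    cov = epoch if epoch.shape[0] == epoch.shape[1] and np.allclose(epoch, epoch.T) \
        else estimate_covariance(epoch)
    dists = np.array([riemannian_distance(cov, model.class_means[c])
                      for c in model.classes])
    # ties (within numerical noise) go to the first class in sorted order
    best = dists.min()
    tied = dists <= best + 1e-9 * (1.0 + best)
    return model.classes[int(np.argmax(tied))]


# ---------------------------------------------------------------------------
# CSP + FLDA (online-protocol emulation)
# ---------------------------------------------------------------------------

@dataclass
class CspModel:
    filters: np.ndarray  # (n_filters, n_channels), rows sorted by eigenvalue desc
    eigenvalues: np.ndarray  # in [0, 1], descending
    selected: np.ndarray  # indices of retained filters (symmetric from the ends)
    channel_labels: tuple = ()


@dataclass
class FldaModel:
    weights: np.ndarray
    bias: float
    classes: tuple  # (negative-side class, positive-side class)


def _class_covariances(epochs, labels, classes):
    covs = {c: [] for c in classes}
    for e, lab in zip(epochs, labels):
        c = estimate_covariance(e)
        covs[lab].append(c / np.trace(c))  # trace-normalized
    return {c: np.mean(v, axis=0) for c, v in covs.items()}


def fit_csp(epochs, labels, n_select: int = 2, channel_labels=()) -> CspModel:
    """Two-class CSP via the generalized eigenproblem Ca v = λ (Ca + Cb) v.

    Eigenvalues lie in (0, 1) and are returned descending; ``selected`` takes
    ``n_select // 2`` filters from each end.
    """
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError("CSP requires exactly two classes")
    cov = _class_covariances(np.asarray(epochs), labels, classes)
    ca, cb = cov[classes[0]], cov[classes[1]]
    comp = ca + cb
    if np.linalg.eigvalsh(comp).min() < 1e-12 * np.trace(comp):
        raise np.linalg.LinAlgError("composite covariance is rank deficient")
    w, v = linalg.eigh(ca, comp)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    half = n_select // 2
    if half < 1 or n_select % 2:
        raise ValueError("n_select must be a positive even number")
    selected = np.r_[np.arange(half), np.arange(len(w) - half, len(w))]
    return CspModel(
        filters=v.T, eigenvalues=w, selected=selected,
        channel_labels=tuple(channel_labels),
    )


def csp_features(model: CspModel, epochs) -> np.ndarray:
    """Log-variance of the selected spatial-filter outputs."""
    w = model.filters[model.selected]
    out = np.einsum("fc,tcs->tfs", w, np.asarray(epochs, dtype=float))
    return np.log(out.var(axis=2, ddof=1))


def fit_flda(features: np.ndarray, labels) -> FldaModel:
    """Fisher LDA: w = Sw^{-1} (m1 - m0), boundary at the midpoint."""
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError("FLDA requires exactly two classes")
    x0 = features[labels == classes[0]]
    x1 = features[labels == classes[1]]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    sw = np.cov(x0.T, ddof=1) * (len(x0) - 1) + np.cov(x1.T, ddof=1) * (len(x1) - 1)
    sw = np.atleast_2d(sw) + 1e-9 * np.trace(np.atleast_2d(sw)) * np.eye(features.shape[1])
    w = np.linalg.solve(sw, m1 - m0)
    if not np.all(np.isfinite(w)):
        raise ValueError("FLDA weights are not finite")
    bias = -float(w @ (m0 + m1) / 2)
    return FldaModel(weights=w, bias=bias, classes=classes)


def predict_flda(model: FldaModel, features: np.ndarray):
    score = np.asarray(features) @ model.weights + model.bias
    return np.where(score > 0, model.classes[1], model.classes[0])


#: Online hyper-parameter variants: (channel subset or None for all, n CSP filters).
ONLINE_VARIANTS = {
    "19ch_2+2": (None, 4),
    "9ch_1+1": (ROI_9, 2),
}


def train_online_classifier(epochs: EpochSet, labels=None, variant: str = "9ch_1+1"):
    """Train the CSP+FLDA online-protocol classifier in one of the two
    hyper-parameter variants used during the study."""
    if variant not in ONLINE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    subset, n_select = ONLINE_VARIANTS[variant]
    if subset is not None:
        epochs = epochs.pick_channels(subset)
    labels = epochs.labels if labels is None else np.asarray(labels)
    csp = fit_csp(epochs.data, labels, n_select=n_select,
                  channel_labels=epochs.channel_labels)
    flda = fit_flda(csp_features(csp, epochs.data), labels)
    return csp, flda


def predict_online(csp: CspModel, flda: FldaModel, epochs: EpochSet):
    data = epochs.pick_channels(csp.channel_labels).data if csp.channel_labels \
        and epochs.channel_labels != csp.channel_labels else epochs.data
    return predict_flda(flda, csp_features(csp, data))


# ---------------------------------------------------------------------------
# Performance records, chance threshold, pipeline
# ---------------------------------------------------------------------------

@dataclass
class PerformanceRecord:
    subject: str
    session: str
    accuracy: float  # percent
    n_test_trials: int
    group: str = "unassigned"
    stimulation_arm: str = "sham"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must lie in [0, 100]")


def evaluate_offline_accuracy(
    epochs: EpochSet,
    blocks: np.ndarray,
    train_blocks=(1, 2),
    test_blocks=(3, 4),
    subject: str = "",
    session: str = "",
) -> PerformanceRecord:
    """MDM accuracy: train on ``train_blocks``, test on ``test_blocks``.

    ``epochs`` must already be filtered / rejected / restricted to the ROI.
    """
    blocks = np.asarray(blocks)
    tr = np.isin(blocks, train_blocks)
    te = np.isin(blocks, test_blocks)
    if not te.any():
        raise ValueError("no surviving test trials")
    model = fit_mdm(epochs.data[tr], epochs.labels[tr], epochs.channel_labels)
    pred = np.array([predict_mdm(model, e) for e in epochs.data[te]])
    acc = 100.0 * float(np.mean(pred == epochs.labels[te]))
    return PerformanceRecord(
        subject=subject, session=session, accuracy=acc, n_test_trials=int(te.sum())
    )


def score_subject(
    raw: RawRecording,
    events: EventTable,
    session: str,
    subject: str = "",
    roi=ROI_9,
    window_ms=(500.0, 3500.0),
) -> PerformanceRecord:
    """Full offline scoring pipeline for one session of one subject:
    8-30 Hz band-pass, 58-62 Hz band-stop, epoch, ±100 µV rejection (eye
    channels exempt), ROI restriction, MDM train offline / test online."""
    x = filter_signal(raw.samples, raw.fs, "bandpass", BandDefinition("bp", 8, 30))
    if raw.fs / 2 > 62:
        x = filter_signal(x, raw.fs, "bandstop", BandDefinition("notch", 58, 62))
    filtered = RawRecording(x, raw.fs, raw.channel_labels, dict(raw.meta))
    epochs = extract_epochs(filtered, events, window_ms, session=session)
    kept, mask = reject_epochs(epochs)
    quality = subject_quality(mask)
    blocks = kept.events["block"].to_numpy()
    rec = evaluate_offline_accuracy(
        kept.pick_channels(roi), blocks, subject=subject, session=session
    )
    rec.meta.update(quality=quality, n_rejected=int(mask.sum()), n_total=len(mask))
    return rec


def chance_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Chance-level accuracy bound (percent) for a p=0.5 binary classifier:
    upper limit of the two-sided (1-alpha) adjusted-Wald (Agresti-Coull)
    confidence interval."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    x = n_trials / 2.0  # chance classifier
    n_adj = n_trials + z**2
    p_adj = (x + z**2 / 2.0) / n_adj
    return 100.0 * (p_adj + z * np.sqrt(p_adj * (1.0 - p_adj) / n_adj))


def assign_performance_group(record: PerformanceRecord, threshold: float) -> str:
    """'low' iff pre-session accuracy is strictly below the threshold."""
    group = "low" if record.accuracy < threshold else "high"
    record.group = group
    return group
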