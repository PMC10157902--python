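"""Independent reference implementations used only by the tests.

These deliberately take different algorithmic routes from the package:
matrix functions via scipy.linalg.sqrtm/logm (Schur-based) instead of eigh,
closed forms where they exist, and brute-force loops instead of vectorized
code.
"""

import numpy as np
from scipy import linalg, signal


def spd_distance_ref(a, b) -> float:
    """Affine-invariant distance via explicit matrix functions."""
    a_isqrt = np.real(linalg.inv(linalg.sqrtm(a)))
    m = a_isqrt @ b @ a_isqrt
    return float(np.linalg.norm(np.real(linalg.logm(m)), "fro"))


def spd_mean_two_ref(a, b) -> np.ndarray:
    """Closed-form geodesic midpoint of two SPD matrices:
    A^{1/2} (A^{-1/2} B A^{-1/2})^{1/2} A^{1/2}."""
    s = np.real(linalg.sqrtm(a))
    si = np.real(linalg.inv(s))
    return s @ np.real(linalg.sqrtm(si @ b @ si)) @ s


def karcher_residual_ref(x, mats) -> float:
    """Norm of the Karcher critical-point condition
    sum_i log(X^{-1/2} C_i X^{-1/2}) = 0, via scipy.linalg.logm."""
    xi = np.real(linalg.inv(linalg.sqrtm(x)))
    acc = np.zeros_like(x)
    for c in mats:
        acc = acc + np.real(linalg.logm(xi @ c @ xi))
    return float(np.linalg.norm(acc / len(mats), "fro"))


def random_spd(rng, d, cond=10.0) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    w = np.exp(rng.uniform(0, np.log(cond), d))
    return (q * w) @ q.T


def plv_bruteforce(phase_a, phase_b) -> np.ndarray:
    """Explicit loop over trials and time points."""
    n_trials, n_t = phase_a.shape
    out = np.zeros(n_t)
    for t in range(n_t):
        acc = 0.0 + 0.0j
        for n in range(n_trials):
            acc += np.exp(1j * (phase_a[n, t] - phase_b[n, t]))
        out[t] = abs(acc) / n_trials
    return out


def hilbert_phase_ref(x) -> np.ndarray:
    """Analytic-signal phase of an unfiltered signal."""
    return np.angle(signal.hilbert(np.asarray(x, dtype=float)))


def exact_binomial_chance_pct(n, alpha=0.05) -> float:
    """Smallest accuracy k/n whose exceedance probability under Binomial(n, 0.5)
    is at most alpha, via direct enumeration, in percent."""
    from math import comb

    pmf = np.array([comb(n, k) for k in range(n + 1)], dtype=float)
    pmf /= pmf.sum()
    surv = 1.0 - np.cumsum(pmf)  # P(X > k) = P(X >= k+1)
    k = int(np.argmax(surv + pmf <= alpha))  # first k with P(X >= k) <= alpha
    return 100.0 * k / n
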