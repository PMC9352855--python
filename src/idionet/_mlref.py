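"""Pure-numpy reference for the ML discrepancy.

Used by the test suite to verify the jitted kernel and, combined with
``scipy.optimize.minimize``, to provide an independent optimizer route
for cross-checking fits and exact-refit modification indices. Not used
on the hot path.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .sample import LaggedSample


def fml_reference(theta: np.ndarray, a_idx: np.ndarray, phi_idx: np.ndarray,
                  sample: LaggedSample) -> float:
    """F_ML of the full 2p block with the predictor block saturated.

    Builds the implied covariance Sigma(theta) of [eta_{t-1}, eta_t]
    explicitly and evaluates ln|Sigma| - ln|S| + tr(S Sigma^-1) - 2p.
    Deliberately does *not* use the conditional factorization, so it is
    an independent check of that reduction.
    """
    Sigma = implied_covariance(theta, a_idx, phi_idx, sample)
    S = sample.cov
    q = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_m <= 0:
        return np.inf
    return float(logdet_m - logdet_s + np.trace(np.linalg.solve(Sigma, S)) - q)


def implied_covariance(theta: np.ndarray, a_idx: np.ndarray, phi_idx: np.ndarray,
                       sample: LaggedSample) -> np.ndarray:
    """Implied (2p, 2p) covariance with Sigma11 fixed at the sample S11."""
    p = sample.p
    A, Phi, psi = unpack(theta, a_idx, phi_idx, p)
    B = np.linalg.inv(np.eye(p) - A)
    G = B @ Phi
    Om = (B * psi) @ B.T
    S11 = sample.s11
    Sigma = np.empty((2 * p, 2 * p))
    Sigma[:p, :p] = S11
    Sigma[p:, :p] = G @ S11
    Sigma[:p, p:] = Sigma[p:, :p].T
    Sigma[p:, p:] = G @ S11 @ G.T + Om
    return Sigma


def fml_conditional_reference(theta: np.ndarray, a_idx: np.ndarray,
                              phi_idx: np.ndarray, sample: LaggedSample) -> float:
    """Conditional-form F (same quantity as the jitted kernel), in numpy."""
    p = sample.p
    A, Phi, psi = unpack(theta, a_idx, phi_idx, p)
    B = np.linalg.inv(np.eye(p) - A)
    G = B @ Phi
    Om = (B * psi) @ B.T
    c, low = cho_factor(Om, lower=True)
    logdet_om = 2.0 * np.log(np.diag(c)).sum()
    Oinv = cho_solve((c, low), np.eye(p))
    D = G - sample.ghat
    M = sample.s22_1 + D @ sample.s11 @ D.T
    return float(logdet_om - sample.logdet_s22_1 - p + np.sum(Oinv * M))


def unpack(theta: np.ndarray, a_idx: np.ndarray, phi_idx: np.ndarray,
           p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parameter vector -> (A, Phi, psi) matrices."""
    na = len(a_idx)
    nphi = len(phi_idx)
    A = np.zeros((p, p))
    Phi = np.zeros((p, p))
    if na:
        A[a_idx[:, 0], a_idx[:, 1]] = theta[:na]
    if nphi:
        Phi[phi_idx[:, 0], phi_idx[:, 1]] = theta[na:na + nphi]
    psi = np.exp(theta[na + nphi:])
    return A, Phi, psi
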