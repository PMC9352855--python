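"""Jitted maximum-likelihood kernel for the unified SEM.

The model for a p-variate series is

    eta_t = A eta_t + Phi eta_{t-1} + zeta_t,   zeta_t ~ N(0, Psi diag)

estimated on the covariance of the lagged sample [eta_{t-1}, eta_t]
with the predictor block saturated. Because the predictor block is
saturated and the conditional parameters (A, Phi, Psi) do not
constrain it, the Gaussian likelihood factors and the ML discrepancy
reduces to the conditional form

    F(A, Phi, Psi) = ln|Omega| - ln|S22.1| + tr(Omega^-1 M) - p
    Omega = B Psi B',  G = B Phi,  B = (I - A)^-1
    M = S22.1 + (G - Ghat) S11 (G - Ghat)'

whose minimum equals the full 2p-block F_ML with the saturated block
at its sample value. Model chi-square is (N - 1) * F at the minimum.

Everything here is numba-jitted: the model search performs thousands
of warm-started one-path refits per dataset and a Python/scipy
objective is an order of magnitude too slow. The Cholesky and
Gauss-Jordan helpers are written out longhand because trial points in
the line search can make Omega non-PD or (I - A) singular, and
np.linalg raising inside nopython code cannot be caught — the helpers
return a failure flag and the line search backtracks instead.
Correctness of both the kernel and the optimizer is pinned in the test
suite against numpy/scipy re-implementations.

The parameter vector is [a_free, phi_free, log psi] where a_free /
phi_free are the freed entries of A and Phi at index arrays (row =
target, col = source) and psi is log-parameterized for positivity.
"""

import numpy as np
from numba import njit

#: line-search and convergence constants; ftol is relative on F
ARMIJO_C1 = 1e-4
MAX_LINESEARCH = 40
#: an ftol stop only counts as convergence below this gradient sup-norm;
#: stalling in an ill-conditioned valley is reported as non-convergence
FTOL_GMAX = 1e-3
#: inadmissibility barrier on ||(I-A)^-1||_F^2: contemporaneous loops
#: drifting toward a singular (I-A) are rejected by the line search
B_NORM_SQ_MAX = 1e10


@njit(cache=True)
def _chol_inv_logdet(Om):
    """Inverse and log-determinant of a symmetric PD matrix via Cholesky.

    Returns (inv, logdet, ok); ok is False when not positive definite.
    """
    p = Om.shape[0]
    L = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1):
            s = Om[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-300:
                    return L, 0.0, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    logdet = 0.0
    for i in range(p):
        logdet += 2.0 * np.log(L[i, i])
    Linv = np.zeros((p, p))
    for i in range(p):
        Linv[i, i] = 1.0 / L[i, i]
        for j in range(i):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * Linv[k, j]
            Linv[i, j] = s / L[i, i]
    inv = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1):
            s = 0.0
            for k in range(i, p):
                s += Linv[k, i] * Linv[k, j]
            inv[i, j] = s
            inv[j, i] = s
    return inv, logdet, True


@njit(cache=True)
def _inv_ge(E):
    """Gauss-Jordan inverse with partial pivoting; (inv, ok)."""
    p = E.shape[0]
    M = np.zeros((p, 2 * p))
    M[:, :p] = E
    for i in range(p):
        M[i, p + i] = 1.0
    for c in range(p):
        piv = c
        best = abs(M[c, c])
        for r in range(c + 1, p):
            if abs(M[r, c]) > best:
                best = abs(M[r, c])
                piv = r
        if best < 1e-12:
            return np.zeros((p, p)), False
        if piv != c:
            for k in range(2 * p):
                tmp = M[c, k]
                M[c, k] = M[piv, k]
                M[piv, k] = tmp
        pv = M[c, c]
        for k in range(2 * p):
            M[c, k] /= pv
        for r in range(p):
            if r != c and M[r, c] != 0.0:
                f = M[r, c]
                for k in range(2 * p):
                    M[r, k] -= f * M[c, k]
    return np.ascontiguousarray(M[:, p:]), True


@njit(cache=True)
def fml_grad(theta, a_idx, phi_idx, s11, ghat, s22_1, logdet_s22_1):
    """ML discrepancy F and its analytic gradient.

    Returns (F, grad); F is +inf (grad zero) at inadmissible points —
    (I - A) singular or Omega not positive definite.
    """
    p = s11.shape[0]
    na = a_idx.shape[0]
    nphi = phi_idx.shape[0]
    A = np.zeros((p, p))
    Phi = np.zeros((p, p))
    for k in range(na):
        A[a_idx[k, 0], a_idx[k, 1]] = theta[k]
    for k in range(nphi):
        Phi[phi_idx[k, 0], phi_idx[k, 1]] = theta[na + k]
    psi = np.exp(theta[na + nphi:])

    E = -A
    for i in range(p):
        E[i, i] += 1.0
    B, ok = _inv_ge(E)
    g = np.zeros(theta.shape[0])
    if not ok or np.sum(B * B) > B_NORM_SQ_MAX:
        return np.inf, g
    Bt = np.ascontiguousarray(B.T)
    G = B @ Phi
    Om = (B * psi) @ Bt
    Oinv, logdet_om, okc = _chol_inv_logdet(Om)
    if not okc:
        return np.inf, g

    D = G - ghat
    DS = D @ s11
    M = s22_1 + DS @ np.ascontiguousarray(D.T)
    F = logdet_om - logdet_s22_1 - p + np.sum(Oinv * M)

    # W = dF/dOmega (up to symmetry), C collects the mean-structure part
    W = Oinv - Oinv @ M @ Oinv
    C = Oinv @ DS
    gPhi = 2.0 * (Bt @ C)
    WB = W @ B
    Phit = np.ascontiguousarray(Phi.T)
    K = 2.0 * WB * psi + 2.0 * (C @ Phit)
    gA = Bt @ K @ Bt
    for k in range(na):
        g[k] = gA[a_idx[k, 0], a_idx[k, 1]]
    for k in range(nphi):
        g[na + k] = gPhi[phi_idx[k, 0], phi_idx[k, 1]]
    for j in range(p):
        s = 0.0
        for i in range(p):
            s += B[i, j] * WB[i, j]
        g[na + nphi + j] = s * psi[j]  # chain rule through log psi
    return F, g


@njit(cache=True)
def minimize_fml(theta0, a_idx, phi_idx, s11, ghat, s22_1, logdet_s22_1,
                 gtol, ftol, maxiter):
    """Dense BFGS with Armijo backtracking on the ML discrepancy.

    Returns (theta, F, grad, n_iter, converged). Converged means the
    gradient sup-norm fell below ``gtol`` or the relative decrease in F
    fell below ``ftol`` with a finite step accepted.
    """
    n = theta0.shape[0]
    H = np.eye(n)
    th = theta0.copy()
    f, g = fml_grad(th, a_idx, phi_idx, s11, ghat, s22_1, logdet_s22_1)
    if not np.isfinite(f):
        return th, f, g, 0, False
    nit = 0
    converged = False
    for it in range(maxiter):
        gmax = 0.0
        for k in range(n):
            ak = abs(g[k])
            if ak > gmax:
                gmax = ak
        if gmax < gtol:
            converged = True
            break
        d = -(H @ g)
        gd = np.dot(g, d)
        if gd >= 0.0:  # curvature lost; reset to steepest descent
            H = np.eye(n)
            d = -g
            gd = -np.dot(g, g)
        step = 1.0
        accepted = False
        f_new = f
        th_new = th
        g_new = g
        for _ls in range(MAX_LINESEARCH):
            th_try = th + step * d
            f_try, g_try = fml_grad(th_try, a_idx, phi_idx, s11, ghat,
                                    s22_1, logdet_s22_1)
            if f_try <= f + ARMIJO_C1 * step * gd:
                f_new = f_try
                th_new = th_try
                g_new = g_try
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # stale curvature can produce a direction the line search
            # rejects; retry once along steepest descent before giving up
            H = np.eye(n)
            d = -g
            gd = -np.dot(g, g)
            step = 1.0
            for _ls in range(MAX_LINESEARCH + 20):
                th_try = th + step * d
                f_try, g_try = fml_grad(th_try, a_idx, phi_idx, s11, ghat,
                                        s22_1, logdet_s22_1)
                if f_try <= f + ARMIJO_C1 * step * gd:
                    f_new = f_try
                    th_new = th_try
                    g_new = g_try
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            break
        s = th_new - th
        y = g_new - g
        sy = np.dot(s, y)
        if sy > 1e-12:
            Hy = H @ y
            yHy = np.dot(y, Hy)
            rho = 1.0 / sy
            H = (H - rho * np.outer(Hy, s) - rho * np.outer(s, Hy)
                 + (rho * rho * yHy + rho) * np.outer(s, s))
        df = f - f_new
        th = th_new
        g = g_new
        f = f_new
        nit = it + 1
        if df < ftol * (abs(f) + 1.0):
            gmax = 0.0
            for k in range(n):
                ak = abs(g[k])
                if ak > gmax:
                    gmax = ak
            converged = gmax < FTOL_GMAX
            break
    return th, f, g, nit, converged
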