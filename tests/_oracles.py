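"""Independent oracle routes used by the tests.

These deliberately avoid the package's jitted kernel and BFGS loop:
the objective is the pure-numpy reference and the optimizer is
scipy's, with finite-difference gradients, so agreement is evidence
rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from idionet._mlref import fml_conditional_reference, unpack
from idionet.sample import LaggedSample, lagged_pairs
from idionet.usem import _index_arrays, _warm_start


def scipy_fit(sample: LaggedSample, structure, x0=None):
    """ML fit via scipy L-BFGS-B on the numpy objective.

    Returns (theta, fml). Independent of the package optimizer.
    """
    a_idx, phi_idx, _, _ = _index_arrays(structure)
    if x0 is None:
        x0 = _warm_start(sample, a_idx, phi_idx)
    res = minimize(
        fml_conditional_reference, x0, args=(a_idx, phi_idx, sample),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-9, "maxfun": 100000},
    )
    return res.x, float(res.fun)


def scipy_chi2(sample: LaggedSample, structure) -> float:
    _, fml = scipy_fit(sample, structure)
    return (sample.n_eff - 1) * fml


def ols_lagged(ts, phi_mask: np.ndarray):
    """Per-equation OLS of eta_t on eta_{t-1} over pooled lagged pairs.

    The closed-form ML solution when only lagged paths are free and
    the innovation covariance is diagonal.
    """
    Y, _ = lagged_pairs(ts)
    Y = Y - Y.mean(axis=0)
    p = phi_mask.shape[0]
    lagged, current = Y[:, :p], Y[:, p:]
    Phi = np.zeros((p, p))
    resvar = np.zeros(p)
    se = np.zeros((p, p))
    n = Y.shape[0]
    for i in range(p):
        cols = np.where(phi_mask[i])[0]
        if len(cols) == 0:
            resvar[i] = current[:, i].var()
            continue
        X = lagged[:, cols]
        b, *_ = np.linalg.lstsq(X, current[:, i], rcond=None)
        resid = current[:, i] - X @ b
        Phi[i, cols] = b
        resvar[i] = resid @ resid / n
        cov = resid @ resid / (n - len(cols)) * np.linalg.inv(X.T @ X)
        se[i, cols] = np.sqrt(np.diag(cov))
    return Phi, resvar, se


def theta_to_matrices(theta, structure, p):
    a_idx, phi_idx, _, _ = _index_arrays(structure)
    return unpack(np.asarray(theta), a_idx, phi_idx, p)
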