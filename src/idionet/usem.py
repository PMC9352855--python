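"""Unified-SEM estimation, fit indices, and modification indices.

One participant's concatenated ROI series is modeled as

    eta_t = A eta_t + Phi eta_{t-1} + zeta_t,    zeta_t ~ N(0, Psi)

with directed contemporaneous effects in A (zero diagonal), lagged
effects in Phi (the diagonal holding the autoregressive paths),
diagonal innovation covariance Psi, and only the entries freed by a
:class:`~idionet.paths.NetworkStructure` estimated. Estimation is
maximum likelihood on the covariance of the lagged sample
``[eta_{t-1}, eta_t]`` with the predictor block saturated; model
chi-square is ``(N - 1) * F_ML`` at the minimum.

Degrees of freedom follow the moment count of the 2p block:
``p(2p+1)`` unique moments, minus ``p(p+1)/2`` parameters absorbed by
the saturated predictor block, minus ``p`` innovation variances, minus
the number of freed paths — i.e. ``df = p(2p+1) - p(p+1)/2 - p - k``.

Modification indices are *exact refits*: the score for an absent path
is the realized chi-square drop from re-estimating with that one path
freed, warm-started at the restricted solution. This is the
Lagrange-multiplier model-search statistic evaluated without the
quadratic approximation, and each score is referred to chi-square(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._mlcore import fml_grad, minimize_fml
from .errors import DataError, EstimationError, RankDeficiencyError
from .paths import (
    FitIndices,
    NetworkStructure,
    PathEstimate,
    PathSpec,
    PersonNetwork,
)
from .sample import LaggedSample

#: default optimizer tolerances (gradient sup-norm; relative F decrease)
GTOL = 1e-7
FTOL = 1e-11
MAXITER = 800
MAX_RESTARTS = 3


# ---------------------------------------------------------------------------
# internal fit state

@dataclass
class UsemFit:
    """A converged (or best-so-far) ML solution under one structure."""

    sample: LaggedSample
    structure: NetworkStructure
    a_idx: np.ndarray
    phi_idx: np.ndarray
    theta: np.ndarray
    fml: float
    converged: bool
    n_iter: int

    @property
    def chi2(self) -> float:
        return max((self.sample.n_eff - 1) * self.fml, 0.0)

    @property
    def n_free_paths(self) -> int:
        return len(self.structure)

    @property
    def df(self) -> int:
        p = self.sample.p
        return self.sample.n_moments - (p * (p + 1)) // 2 - p - self.n_free_paths

    def beta_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(A, Phi, psi) at the solution."""
        from ._mlref import unpack

        return unpack(self.theta, self.a_idx, self.phi_idx, self.sample.p)


def _index_arrays(structure: NetworkStructure) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Masks as (k, 2) index arrays plus the PathSpecs in matching order."""
    idx = {l: k for k, l in enumerate(structure.rois.labels)}
    a_rows, phi_rows, a_paths, phi_paths = [], [], [], []
    for path in structure.paths:
        pair = (idx[path.target], idx[path.source])
        if path.lag == 0:
            a_rows.append(pair)
            a_paths.append(path)
        else:
            phi_rows.append(pair)
            phi_paths.append(path)
    a_idx = np.array(a_rows, dtype=np.int64).reshape(-1, 2)
    phi_idx = np.array(phi_rows, dtype=np.int64).reshape(-1, 2)
    return a_idx, phi_idx, a_paths, phi_paths


def _warm_start(sample: LaggedSample, a_idx: np.ndarray, phi_idx: np.ndarray) -> np.ndarray:
    """Per-equation least-squares start computed from the moment matrix."""
    p = sample.p
    S = sample.cov
    na = len(a_idx)
    a_vals = np.zeros(na)
    phi_vals = np.zeros(len(phi_idx))
    log_psi = np.zeros(p)
    for i in range(p):
        pred = []  # indices into the 2p moment space
        slots = []  # (which vector, position) to scatter coefficients back
        for k in range(len(phi_idx)):
            if phi_idx[k, 0] == i:
                pred.append(phi_idx[k, 1])
                slots.append((phi_vals, k))
        for k in range(na):
            if a_idx[k, 0] == i:
                pred.append(p + a_idx[k, 1])
                slots.append((a_vals, k))
        yi = p + i
        if pred:
            Spp = S[np.ix_(pred, pred)]
            spy = S[pred, yi]
            try:
                b = np.linalg.solve(Spp, spy)
            except np.linalg.LinAlgError:
                b = np.linalg.lstsq(Spp, spy, rcond=None)[0]
            for (vec, k), bk in zip(slots, b):
                vec[k] = bk
            resvar = S[yi, yi] - float(b @ spy)
        else:
            resvar = S[yi, yi]
        log_psi[i] = math.log(max(resvar, 1e-8))
    return np.concatenate([a_vals, phi_vals, log_psi])


def _minimize(sample: LaggedSample, a_idx: np.ndarray, phi_idx: np.ndarray,
              theta0: np.ndarray, gtol: float, ftol: float,
              maxiter: int, max_restarts: int) -> tuple[np.ndarray, float, bool, int]:
    """BFGS with deterministic restarts on non-convergence.

    Restart sequence: the supplied start, then a fresh least-squares
    start, then jittered perturbations of the best point so far.
    """
    best = None
    th0 = theta0
    for attempt in range(max_restarts + 1):
        th, f, g, nit, conv = minimize_fml(
            th0, a_idx, phi_idx, sample.s11, sample.ghat,
            sample.s22_1, sample.logdet_s22_1, gtol, ftol, maxiter,
        )
        if best is None or (np.isfinite(f) and f < best[1]):
            best = (th, f, conv, nit)
        if conv and np.isfinite(f):
            return th, f, True, nit
        if attempt == 0:
            th0 = _warm_start(sample, a_idx, phi_idx)
        else:
            rng = np.random.default_rng(1_000_003 + attempt)
            th0 = best[0] + rng.normal(0.0, 0.02, size=theta0.shape)
    th, f, conv, nit = best
    return th, f, conv, nit


def fit_structure(sample: LaggedSample, structure: NetworkStructure, *,
                  gtol: float = GTOL, ftol: float = FTOL,
                  maxiter: int = MAXITER, max_restarts: int = MAX_RESTARTS,
                  theta0: np.ndarray | None = None,
                  raise_on_failure: bool = True) -> UsemFit:
    """ML-fit a structure to one participant's lagged sample.

    Low-level entry point returning the raw solution; use
    :func:`fit_usem` for a fully assembled :class:`PersonNetwork`.
    """
    p = sample.p
    n_free = (p * (p + 1)) // 2 + p + len(structure)
    if sample.n_eff <= n_free:
        raise DataError(
            f"{sample.participant_id}: effective N {sample.n_eff} does not "
            f"exceed the number of free parameters {n_free}"
        )
    a_idx, phi_idx, _, _ = _index_arrays(structure)
    if theta0 is None:
        theta0 = _warm_start(sample, a_idx, phi_idx)
    theta, fml, conv, nit = _minimize(
        sample, a_idx, phi_idx, theta0, gtol, ftol, maxiter, max_restarts
    )
    fit = UsemFit(sample=sample, structure=structure, a_idx=a_idx,
                  phi_idx=phi_idx, theta=theta, fml=fml,
                  converged=conv, n_iter=nit)
    if not conv and raise_on_failure:
        raise EstimationError(
            f"{sample.participant_id}: ML estimation did not converge "
            f"after {max_restarts} restarts",
            diagnostics={"fml": fml, "n_iter": nit,
                         "participant_id": sample.participant_id},
        )
    return fit


# ---------------------------------------------------------------------------
# fit indices

def baseline_chi2(sample: LaggedSample) -> tuple[float, int]:
    """Chi-square and df of the no-path baseline model.

    Baseline: A = 0, Phi = 0, free diagonal Psi, saturated predictor
    block. Its ML solution is closed form (psi_i = s22_ii), giving
    F_B = ln|diag(S22)| - ln|S22.1|.
    """
    p = sample.p
    f_b = float(np.sum(np.log(np.diag(sample.s22))) - sample.logdet_s22_1)
    chi2_b = max((sample.n_eff - 1) * f_b, 0.0)
    df_b = sample.n_moments - (p * (p + 1)) // 2 - p
    return chi2_b, df_b


def srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Root mean square standardized residual over unique modeled moments."""
    s_diag = np.sqrt(np.diag(sample_cov))
    denom = np.outer(s_diag, s_diag)
    resid = (sample_cov - implied_cov) / denom
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def fit_indices(chi2_model: float, df_model: float, chi2_baseline: float,
                df_baseline: float, n: int, *,
                srmr_value: float = float("nan")) -> FitIndices:
    """Assemble RMSEA / CFI / NNFI (and a supplied SRMR) from chi-squares.

    ``n`` is the number of observations behind the covariance; RMSEA
    uses ``n - 1``. With df = 0 (saturated model) RMSEA is 0 and NNFI
    is reported as 1 with ``nnfi_undefined`` set.
    """
    if df_baseline < df_model:
        raise DataError("baseline df must be >= model df")
    if n <= 1:
        raise DataError("need n > 1")
    if df_model > 0:
        rmsea = math.sqrt(max(chi2_model - df_model, 0.0) / (df_model * (n - 1)))
        pvalue = float(stats.chi2.sf(chi2_model, df_model))
    else:
        rmsea = 0.0
        pvalue = 1.0

    if df_model == 0:
        cfi = 1.0  # saturated: no noncentrality by construction
    else:
        num = max(chi2_model - df_model, 0.0)
        denom = max(chi2_baseline - df_baseline, num, 0.0)
        cfi = 1.0 - num / denom if denom > 0 else 1.0
        cfi = min(max(cfi, 0.0), 1.0)

    nnfi_undefined = False
    if df_model == 0 or df_baseline == 0:
        nnfi = 1.0
        nnfi_undefined = True
    else:
        ratio_b = chi2_baseline / df_baseline
        ratio_m = chi2_model / df_model
        if abs(ratio_b - 1.0) < 1e-12:
            nnfi = 1.0
            nnfi_undefined = True
        else:
            nnfi = (ratio_b - ratio_m) / (ratio_b - 1.0)

    return FitIndices(chi2=float(chi2_model), df=float(df_model), pvalue=pvalue,
                      rmsea=float(rmsea), srmr=float(srmr_value),
                      cfi=float(cfi), nnfi=float(nnfi),
                      nnfi_undefined=nnfi_undefined)


def indices_for_fit(fit: UsemFit) -> FitIndices:
    """Fit indices for a fitted structure, including SRMR."""
    from ._mlref import implied_covariance

    chi2_b, df_b = baseline_chi2(fit.sample)
    implied = implied_covariance(fit.theta, fit.a_idx, fit.phi_idx, fit.sample)
    srmr_value = srmr(fit.sample.cov, implied)
    return fit_indices(fit.chi2, fit.df, chi2_b, df_b, fit.sample.n_eff,
                       srmr_value=srmr_value)


# ---------------------------------------------------------------------------
# standard errors

def _hessian(fit: UsemFit, step: float = 1e-5) -> np.ndarray:
    """Observed Hessian of F_ML via central differences of the gradient."""
    theta = fit.theta
    n = len(theta)
    H = np.empty((n, n))
    s = fit.sample
    for k in range(n):
        h = step * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        _, gp = fml_grad(tp, fit.a_idx, fit.phi_idx, s.s11, s.ghat,
                         s.s22_1, s.logdet_s22_1)
        _, gm = fml_grad(tm, fit.a_idx, fit.phi_idx, s.s11, s.ghat,
                         s.s22_1, s.logdet_s22_1)
        H[k] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def standard_errors(fit: UsemFit) -> np.ndarray:
    """SEs of the parameter vector from the inverse observed information.

    The log-likelihood is -(N - 1)/2 * F + const, so the observed
    information is (N - 1)/2 * Hessian(F) and the parameter covariance
    its inverse.

    Near-collinear predictors can leave an empirically unidentified
    direction whose information eigenvalue is numerically zero; a
    plain inverse then returns meaningless (even negative) variances.
    Parameters loading on such a dead direction carry no information,
    so their SE is reported as +inf (z = 0) — the search's z-test
    pruning then removes them, which is the statistically appropriate
    outcome. A matrix that is singular or indefinite beyond numerical
    tolerance raises :class:`RankDeficiencyError`.
    """
    H = _hessian(fit)
    info = (fit.sample.n_eff - 1) / 2.0 * H
    w, V = np.linalg.eigh(info)
    w_max = w[-1]
    if not np.isfinite(w_max) or w_max <= 0:
        raise RankDeficiencyError(
            f"{fit.sample.participant_id}: singular information matrix",
            diagnostics={"participant_id": fit.sample.participant_id},
        )
    eps = w_max * 1e-9
    if w[0] < -eps * 1e3:  # genuinely indefinite: not at a minimum
        raise RankDeficiencyError(
            f"{fit.sample.participant_id}: information matrix indefinite "
            "at the solution",
            diagnostics={"participant_id": fit.sample.participant_id,
                         "min_eigenvalue": float(w[0])},
        )
    alive = w > eps
    var = (V[:, alive] ** 2 / w[alive]).sum(axis=1)
    dead_load = np.abs(V[:, ~alive]).max(axis=1) if np.any(~alive) else None
    se = np.sqrt(var)
    if dead_load is not None:
        se[dead_load > 1e-6] = np.inf
    return se


def person_network(fit: UsemFit, *, compute_se: bool = True) -> PersonNetwork:
    """Assemble estimates + fit indices into a :class:`PersonNetwork`."""
    a_idx, phi_idx, a_paths, phi_paths = _index_arrays(fit.structure)
    se = standard_errors(fit) if compute_se else np.full(len(fit.theta), np.nan)
    estimates = []
    na = len(a_paths)
    for k, path in enumerate(a_paths):
        beta = float(fit.theta[k])
        s = float(se[k])
        estimates.append(PathEstimate(path=path, beta=beta, se=s,
                                      z=beta / s if s > 0 else float("nan")))
    for k, path in enumerate(phi_paths):
        beta = float(fit.theta[na + k])
        s = float(se[na + k])
        estimates.append(PathEstimate(path=path, beta=beta, se=s,
                                      z=beta / s if s > 0 else float("nan")))
    return PersonNetwork(
        participant_id=fit.sample.participant_id,
        structure=fit.structure,
        estimates=tuple(estimates),
        fit=indices_for_fit(fit),
    )


def fit_usem(sample: LaggedSample, structure: NetworkStructure, *,
             compute_se: bool = True, **kwargs) -> PersonNetwork:
    """Fit a fixed structure to one participant and return the network.

    Keyword arguments are forwarded to :func:`fit_structure`
    (tolerances, restarts).
    """
    fit = fit_structure(sample, structure, **kwargs)
    return person_network(fit, compute_se=compute_se)


# ---------------------------------------------------------------------------
# modification indices

@dataclass(frozen=True)
class ModificationIndex:
    """Score for freeing one absent path: realized chi-square drop."""

    path: PathSpec
    score: float
    pvalue: float
    converged: bool = True


def modification_indices(sample: LaggedSample, structure: NetworkStructure, *,
                         fitted: UsemFit | None = None,
                         candidates: Sequence[PathSpec] | None = None,
                         gtol: float = GTOL, ftol: float = FTOL,
                         maxiter: int = MAXITER) -> tuple[ModificationIndex, ...]:
    """Exact-refit Lagrange-multiplier scores for all admissible paths.

    For every absent admissible path the model is re-estimated with
    that single path freed (warm-started at the restricted solution);
    the score is the chi-square decrease, with a p-value from
    chi-square(1). Returned sorted by descending score, ties broken by
    (lag, source, target) for determinism.
    """
    if candidates is None:
        candidates = structure.admissible_candidates()
    if not candidates:
        return ()
    if fitted is None:
        fitted = fit_structure(sample, structure, gtol=gtol, ftol=ftol,
                               maxiter=maxiter)
    idx = {l: k for k, l in enumerate(structure.rois.labels)}
    na = len(fitted.a_idx)
    nphi = len(fitted.phi_idx)
    scale = sample.n_eff - 1
    out = []
    for cand in candidates:
        pair = np.array([[idx[cand.target], idx[cand.source]]], dtype=np.int64)
        if cand.lag == 0:
            a_idx = np.vstack([fitted.a_idx, pair])
            phi_idx = fitted.phi_idx
            theta0 = np.concatenate([fitted.theta[:na], [0.0], fitted.theta[na:]])
        else:
            a_idx = fitted.a_idx
            phi_idx = np.vstack([fitted.phi_idx, pair])
            theta0 = np.concatenate([fitted.theta[:na + nphi], [0.0],
                                     fitted.theta[na + nphi:]])
        th, f, g, nit, conv = minimize_fml(
            theta0, a_idx, phi_idx, sample.s11, sample.ghat,
            sample.s22_1, sample.logdet_s22_1, gtol, ftol, maxiter,
        )
        score = max(scale * (fitted.fml - f), 0.0) if np.isfinite(f) else 0.0
        out.append(ModificationIndex(
            path=cand, score=score,
            pvalue=float(stats.chi2.sf(score, 1)) if score > 0 else 1.0,
            converged=bool(conv),
        ))
    out.sort(key=lambda m: (-m.score, m.path.key))
    return tuple(out)
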