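"""Estimation correctness: oracles, invariances, and recovery."""

import numpy as np
import pytest

from idionet import (
    DataError,
    NetworkStructure,
    build_lagged_sample,
    fit_structure,
    fit_usem,
)
from idionet._mlcore import fml_grad
from idionet._mlref import fml_conditional_reference, fml_reference
from idionet.paths import PathSpec
from idionet.usem import _index_arrays, _warm_start, person_network

from _oracles import ols_lagged, scipy_fit, theta_to_matrices
from conftest import saturated_structure, simulate_var, structure_from_matrices


class TestObjectiveKernel:
    """The jitted objective must equal the numpy references exactly."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conditional_equals_full_block_objective(self, rois3, seed):
        # the conditional factorization must reproduce the full 2p-block
        # F_ML with the predictor block at its sample value
        rng = np.random.default_rng(seed)
        ts = simulate_var(rois3, np.zeros((3, 3)), np.diag([0.3, 0.4, 0.5]),
                          1.0, T=300, seed=seed + 10)
        sample = build_lagged_sample(ts)
        structure = NetworkStructure.null(rois3).with_path(
            PathSpec("a", "b", lag=0)
        )
        a_idx, phi_idx, _, _ = _index_arrays(structure)
        theta = np.concatenate([rng.normal(0, 0.2, 4), rng.normal(0, 0.1, 3)])
        f_cond = fml_conditional_reference(theta, a_idx, phi_idx, sample)
        f_full = fml_reference(theta, a_idx, phi_idx, sample)
        f_jit, grad = fml_grad(theta, a_idx, phi_idx, sample.s11, sample.ghat,
                               sample.s22_1, sample.logdet_s22_1)
        assert f_cond == pytest.approx(f_full, abs=1e-10)
        assert f_jit == pytest.approx(f_cond, abs=1e-10)

        # analytic gradient against central differences of the reference
        num = np.empty_like(theta)
        for k in range(len(theta)):
            e = np.zeros_like(theta)
            e[k] = 1e-6
            num[k] = (
                fml_conditional_reference(theta + e, a_idx, phi_idx, sample)
                - fml_conditional_reference(theta - e, a_idx, phi_idx, sample)
            ) / 2e-6
        np.testing.assert_allclose(grad, num, atol=1e-6)


class TestOlsOracle:
    """With only lagged paths free, ML equals per-equation least squares."""

    def test_ar_betas_match_ols_and_truth(self, ar_sample_2roi):
        ts, sample = ar_sample_2roi
        structure = NetworkStructure.null(ts.rois)
        fit = fit_structure(sample, structure)
        _, Phi_hat, psi_hat = fit.beta_matrices()
        Phi_ols, resvar, _ = ols_lagged(ts, np.eye(2, dtype=bool))
        np.testing.assert_allclose(np.diag(Phi_hat), np.diag(Phi_ols),
                                   atol=1e-4)
        np.testing.assert_allclose(psi_hat, resvar, rtol=1e-3)
        # closed-form AR(1): lag-1 autocorrelation equals the AR weight
        np.testing.assert_allclose(np.diag(Phi_hat), 0.5, atol=0.03)

    def test_lagged_cross_paths_match_ols(self, rois3):
        Phi = np.array([[0.4, 0.0, 0.0],
                        [0.3, 0.4, 0.0],
                        [0.0, -0.25, 0.4]])
        ts = simulate_var(rois3, np.zeros((3, 3)), Phi, 1.0, T=10_000, seed=9)
        sample = build_lagged_sample(ts)
        structure = structure_from_matrices(rois3, np.zeros((3, 3)), Phi)
        fit = fit_structure(sample, structure)
        _, Phi_hat, _ = fit.beta_matrices()
        Phi_ols, _, _ = ols_lagged(ts, Phi != 0)
        np.testing.assert_allclose(Phi_hat[Phi != 0], Phi_ols[Phi != 0],
                                   atol=1e-4)
        # planted-weight recovery at T=10000
        np.testing.assert_allclose(Phi_hat[Phi != 0], Phi[Phi != 0], atol=0.05)

    def test_standard_errors_match_ols(self, ar_sample_2roi):
        ts, sample = ar_sample_2roi
        net = fit_usem(sample, NetworkStructure.null(ts.rois))
        _, _, se_ols = ols_lagged(ts, np.eye(2, dtype=bool))
        for est in net.estimates:
            i = ts.rois.index(est.path.target)
            assert est.se == pytest.approx(se_ols[i, i], rel=0.1)


class TestAgainstScipyOptimizer:
    """Package BFGS and scipy L-BFGS-B must find the same minimum."""

    @pytest.mark.parametrize("seed", [1, 5])
    def test_same_minimum(self, rois3, seed):
        A = np.zeros((3, 3))
        A[1, 0] = 0.5
        Phi = np.diag([0.4, 0.3, 0.5])
        Phi[2, 0] = -0.3
        ts = simulate_var(rois3, A, Phi, 1.0, T=500, seed=seed)
        sample = build_lagged_sample(ts)
        structure = structure_from_matrices(rois3, A, Phi)
        fit = fit_structure(sample, structure)
        _, f_scipy = scipy_fit(sample, structure)
        assert fit.fml == pytest.approx(f_scipy, abs=1e-7)


class TestModelProperties:
    def test_saturated_model_is_exact(self, rois3, planted_3roi):
        _, sample, _, _ = planted_3roi
        net = fit_usem(sample, saturated_structure(rois3), compute_se=False)
        assert net.fit.df == 0
        assert net.fit.chi2 == pytest.approx(0.0, abs=1e-4)
        assert net.fit.cfi == 1.0
        assert net.fit.rmsea == 0.0

    def test_omitted_path_is_detected(self, rois3):
        # planted contemporaneous path beta=0.6 left out of the structure:
        # strong global misfit
        A = np.zeros((3, 3))
        A[1, 0] = 0.6
        ts = simulate_var(rois3, A, np.diag([0.4, 0.4, 0.4]), 1.0,
                          T=1000, seed=21)
        sample = build_lagged_sample(ts)
        net = fit_usem(sample, NetworkStructure.null(rois3), compute_se=False)
        assert net.fit.pvalue < 0.001
        assert net.fit.rmsea > 0.10

    def test_df_hand_count_p2(self, rois2):
        # p=2: 10 unique moments - 3 saturated - 2 psi - 2 AR paths = 3
        ts = simulate_var(rois2, np.zeros((2, 2)), np.diag([0.3, 0.3]),
                          1.0, T=200, seed=2)
        fit = fit_structure(build_lagged_sample(ts),
                            NetworkStructure.null(rois2))
        assert fit.df == 3

    def test_nested_chi2_monotone(self, planted_3roi, rois3):
        _, sample, _, _ = planted_3roi
        structure = NetworkStructure.null(rois3)
        chi2_prev = fit_structure(sample, structure).chi2
        for cand in [PathSpec("b", "c", lag=0), PathSpec("a", "b", lag=0),
                     PathSpec("c", "a", lag=1)]:
            structure = structure.with_path(cand)
            chi2 = fit_structure(sample, structure).chi2
            assert chi2 <= chi2_prev + 1e-6
            chi2_prev = chi2

    def test_recovery_with_contemporaneous_loop(self, rois4):
        # planted weights (incl. a reciprocal contemporaneous pair)
        # recovered within +-0.05 at T=10000
        A = np.zeros((4, 4))
        A[1, 0] = 0.5
        A[0, 1] = -0.3
        A[3, 2] = 0.4
        Phi = np.diag([0.4, 0.35, 0.3, 0.45])
        Phi[2, 0] = 0.3
        ts = simulate_var(rois4, A, Phi, 1.0, T=10_000, seed=31)
        sample = build_lagged_sample(ts)
        structure = structure_from_matrices(rois4, A, Phi)
        A_hat, Phi_hat, _ = fit_structure(sample, structure).beta_matrices()
        np.testing.assert_allclose(A_hat[A != 0], A[A != 0], atol=0.05)
        np.testing.assert_allclose(Phi_hat[Phi != 0], Phi[Phi != 0], atol=0.05)

    def test_too_many_parameters_rejected(self, rois3):
        ts = simulate_var(rois3, np.zeros((3, 3)), np.diag([0.3] * 3), 1.0,
                          T=11, seed=4, burn=10)
        with pytest.raises(DataError):
            fit_structure(build_lagged_sample(ts),
                          saturated_structure(rois3))

    def test_estimates_cover_structure(self, planted_3roi, rois3):
        _, sample, A, Phi = planted_3roi
        structure = structure_from_matrices(rois3, A, Phi)
        net = fit_usem(sample, structure)
        assert {e.path.key for e in net.estimates} == {
            p.key for p in structure.paths
        }
        for est in net.estimates:
            if est.se > 0:
                assert est.z == pytest.approx(est.beta / est.se)
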