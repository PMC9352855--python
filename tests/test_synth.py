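"""Synthetic-data generator: determinism, stationarity, moment recovery."""

import numpy as np
import pytest

from idionet import (
    ConfigurationError,
    HormoneBehaviorParams,
    SynthConfig,
    compute_metrics,
    generate_covariates,
    generate_truth,
    simulate_timeseries,
)

PAPER_SCALE = SynthConfig()  # n=11, p=10, two runs of 134


def _ar_only(rois, n=1, ar=(0.5, 0.5), noise=(1.0, 1.0), runs=(10_000,)):
    return SynthConfig(rois=rois, n_participants=n, run_lengths=runs,
                       n_group_paths=0, n_individual_range=(0, 0),
                       ar_weight_range=ar, noise_variance_range=noise)


class TestGenerateTruth:
    def test_seeded_determinism(self):
        t1 = generate_truth(PAPER_SCALE, seed=7)
        t2 = generate_truth(PAPER_SCALE, seed=7)
        assert t1.group_paths == t2.group_paths
        assert t1.individual_paths == t2.individual_paths
        for pid in t1.participant_ids:
            np.testing.assert_array_equal(t1.a_matrices[pid],
                                          t2.a_matrices[pid])
            np.testing.assert_array_equal(t1.phi_matrices[pid],
                                          t2.phi_matrices[pid])
            np.testing.assert_array_equal(t1.noise_variances[pid],
                                          t2.noise_variances[pid])

    def test_different_seeds_differ(self):
        t1 = generate_truth(PAPER_SCALE, seed=1)
        t2 = generate_truth(PAPER_SCALE, seed=2)
        assert t1.group_paths != t2.group_paths

    def test_null_config_gives_ar_only(self, rois4):
        truth = generate_truth(_ar_only(rois4, runs=(60,)), seed=0)
        structure = truth.structure_for(truth.participant_ids[0])
        assert len(structure) == 4
        assert all(p.is_ar for p in structure)

    def test_every_participant_contains_group_paths(self):
        truth = generate_truth(PAPER_SCALE, seed=3)
        group_keys = {p.key for p in truth.group_paths}
        for pid in truth.participant_ids:
            keys = {p.key for p in truth.structure_for(pid).paths}
            assert group_keys <= keys

    def test_all_systems_stationary(self):
        truth = generate_truth(PAPER_SCALE, seed=4)
        for pid in truth.participant_ids:
            assert truth.spectral_radius(pid) < PAPER_SCALE.max_spectral_radius

    def test_complexity_lands_near_study_scale(self):
        # 10 AR + 12 group + 10..15 individual => complexity in [32, 37]
        truth = generate_truth(PAPER_SCALE, seed=5)
        complexities = [
            compute_metrics(truth.structure_for(pid)).complexity
            for pid in truth.participant_ids
        ]
        assert all(32 <= c <= 37 for c in complexities)
        assert 32 <= float(np.mean(complexities)) <= 37

    def test_density_ordering_matches_task_pattern(self):
        # placement weights favor within-MRN; between and within-DMN follow
        truth = generate_truth(PAPER_SCALE, seed=6)
        ms = [compute_metrics(truth.structure_for(pid))
              for pid in truth.participant_ids]
        mrn = float(np.mean([m.density_mrn for m in ms]))
        dmn = float(np.mean([m.density_dmn for m in ms]))
        between = float(np.mean([m.density_between for m in ms]))
        assert mrn > between >= dmn

    def test_infeasible_path_count_rejected(self, rois4):
        with pytest.raises(ConfigurationError):
            SynthConfig(rois=rois4, n_group_paths=100)

    def test_weight_magnitudes_in_range(self):
        truth = generate_truth(PAPER_SCALE, seed=8)
        for pid in truth.participant_ids:
            A = truth.a_matrices[pid]
            nz = np.abs(A[A != 0])
            assert np.all((nz >= 0.3) & (nz <= 0.6))


class TestSimulateTimeseries:
    def test_study_scale_shapes(self):
        truth = generate_truth(PAPER_SCALE, seed=1)
        ts = simulate_timeseries(truth)
        assert len(ts) == 11
        for one in ts:
            assert one.run_lengths == (134, 134)
            assert one.runs[0].shape == (134, 10)

    def test_seeded_determinism(self):
        truth = generate_truth(PAPER_SCALE, seed=1)
        a = simulate_timeseries(truth)
        b = simulate_timeseries(truth)
        np.testing.assert_array_equal(a[3].runs[1], b[3].runs[1])

    def test_runs_are_independent_realizations(self):
        truth = generate_truth(PAPER_SCALE, seed=1)
        ts = simulate_timeseries(truth)
        assert not np.array_equal(ts[0].runs[0], ts[0].runs[1])

    def test_white_noise_moments(self, rois2):
        # all weights zero, unit noise: covariance ~ identity
        cfg = _ar_only(rois2, ar=(0.0, 0.0))
        truth = generate_truth(cfg, seed=2)
        run = simulate_timeseries(truth)[0].runs[0]
        S = np.cov(run.T)
        assert abs(S[0, 0] - 1.0) < 0.05 and abs(S[1, 1] - 1.0) < 0.05
        assert abs(S[0, 1]) < 0.05

    def test_ar_autocorrelation_closed_form(self, rois2):
        # AR(1) with weight 0.5: lag-1 autocorrelation = 0.5
        truth = generate_truth(_ar_only(rois2), seed=3)
        run = simulate_timeseries(truth)[0].runs[0]
        for j in range(2):
            x = run[:, j] - run[:, j].mean()
            rho = (x[1:] @ x[:-1]) / (x @ x)
            assert rho == pytest.approx(0.5, abs=0.03)

    def test_moment_recovery_against_analytic_covariance(self, rois4):
        # empirical lagged moments vs the planted system's stationary
        # solution, within 5% relative error at T=10000
        cfg = SynthConfig(rois=rois4, n_participants=1, run_lengths=(10_000,),
                          n_group_paths=3, n_individual_range=(1, 1))
        truth = generate_truth(cfg, seed=9)
        pid = truth.participant_ids[0]
        run = simulate_timeseries(truth)[0].runs[0]
        V = truth.stationary_covariance(pid)
        C1 = truth.lag1_covariance(pid)
        x = run - run.mean(axis=0)
        V_emp = (x.T @ x) / (len(x) - 1)
        C1_emp = (x[1:].T @ x[:-1]) / (len(x) - 2)
        assert np.linalg.norm(V_emp - V) / np.linalg.norm(V) < 0.05
        assert np.linalg.norm(C1_emp - C1) / np.linalg.norm(C1) < 0.05

    def test_short_runs_rejected(self):
        truth = generate_truth(PAPER_SCALE, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_timeseries(truth, run_lengths=(5,))


class TestCovariates:
    def test_moments_recovered_at_large_n(self, rois2):
        cfg = _ar_only(rois2, n=10_000, runs=(60,))
        truth = generate_truth(cfg, seed=4)
        records = generate_covariates(truth)
        p4 = np.array([r.progesterone for r in records])
        assert abs(p4.mean() - 239.01) / 239.01 < 0.02
        pct = np.array([r.pct_correct for r in records])
        assert np.all((pct >= 0) & (pct <= 100))
        assert np.all(np.array([r.estradiol for r in records]) >= 0)

    def test_zero_sd_gives_exact_means(self, rois4):
        cfg = _ar_only(rois4, n=5, runs=(60,))
        truth = generate_truth(cfg, seed=5)
        params = HormoneBehaviorParams(
            estradiol_sd=0.0, progesterone_sd=0.0, testosterone_sd=0.0,
            pct_correct_sd=0.0,
        )
        for r in generate_covariates(truth, params):
            assert r.progesterone == 239.01
            assert r.pct_correct == 75.0

    def test_zero_coupling_gives_no_correlation(self, rois4):
        cfg = SynthConfig(rois=rois4, n_participants=1000, run_lengths=(60,),
                          n_group_paths=2, n_individual_range=(0, 6))
        truth = generate_truth(cfg, seed=6)
        params = HormoneBehaviorParams(coupling={})
        records = generate_covariates(truth, params)
        counts = np.array([len(truth.individual_paths[pid])
                           for pid in truth.participant_ids], float)
        pct = np.array([r.pct_correct for r in records])
        r = np.corrcoef(counts, pct)[0, 1]
        assert abs(r) < 0.1

    def test_positive_coupling_plants_correlation(self, rois4):
        cfg = SynthConfig(rois=rois4, n_participants=1000, run_lengths=(60,),
                          n_group_paths=2, n_individual_range=(0, 6))
        truth = generate_truth(cfg, seed=7)
        records = generate_covariates(truth)  # default coupling 0.5 on behavior
        counts = np.array([len(truth.individual_paths[pid])
                           for pid in truth.participant_ids], float)
        pct = np.array([r.pct_correct for r in records])
        r = np.corrcoef(counts, pct)[0, 1]
        assert r > 0.3

    def test_seeded_determinism(self, rois4):
        cfg = _ar_only(rois4, n=5, runs=(60,))
        truth = generate_truth(cfg, seed=8)
        assert generate_covariates(truth) == generate_covariates(truth)
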