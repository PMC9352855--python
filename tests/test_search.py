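"""Two-stage search: group criterion, individual additions, determinism."""

import numpy as np
import pytest

from idionet import (
    NetworkStructure,
    SearchConfig,
    SynthConfig,
    build_lagged_sample,
    generate_truth,
    group_search,
    individual_search,
    run_sample_search,
    simulate_timeseries,
)
from idionet.paths import GROUP, INDIVIDUAL, PathSpec

from conftest import simulate_var


def _samples(truth):
    return [build_lagged_sample(ts) for ts in simulate_timeseries(truth)]


def _synth_samples(rois, seed, **kwargs):
    cfg = SynthConfig(rois=rois, **kwargs)
    truth = generate_truth(cfg, seed=seed)
    return truth, _samples(truth)


class TestGroupCriterion:
    @pytest.mark.parametrize("n, threshold, expected",
                             [(11, 0.75, 9), (8, 0.75, 6), (11, 1.0, 11),
                              (10, 0.6, 6)])
    def test_required_count_uses_ceiling(self, n, threshold, expected):
        cfg = SearchConfig(group_threshold=threshold)
        assert cfg.required_count(n) == expected

    @pytest.mark.parametrize("kwargs", [
        {"group_threshold": 0.5}, {"group_threshold": 1.2},
        {"alpha_mi": 0.0}, {"alpha_prune": 1.0}, {"max_iterations": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        from idionet import ConfigurationError

        with pytest.raises(ConfigurationError):
            SearchConfig(**kwargs)


class TestGroupSearch:
    def test_planted_group_paths_recovered_exactly(self, rois4):
        # 3 strong shared paths, no heterogeneity: the group stage must
        # find all of them and nothing else
        truth, samples = _synth_samples(
            rois4, seed=5, n_participants=6, run_lengths=(134, 134),
            n_group_paths=3, n_individual_range=(0, 0),
            weight_range=(0.5, 0.5),
        )
        structure, trace = group_search(samples, SearchConfig())
        want = {p.key for p in truth.group_structure().non_ar_paths}
        got = {p.key for p in structure.non_ar_paths}
        assert got == want
        adds = [s for s in trace.steps if s.action == "add"]
        assert len(adds) == len(want)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_white_noise_yields_ar_only(self, rois4, seed):
        truth, samples = _synth_samples(
            rois4, seed=seed, n_participants=6, run_lengths=(134, 134),
            n_group_paths=0, n_individual_range=(0, 0),
        )
        structure, _ = group_search(samples, SearchConfig())
        assert structure.non_ar_paths == ()

    def test_trace_additions_decrease_chi2(self, rois4):
        _, samples = _synth_samples(
            rois4, seed=5, n_participants=6, run_lengths=(134, 134),
            n_group_paths=3, n_individual_range=(0, 0),
            weight_range=(0.5, 0.5),
        )
        _, trace = group_search(samples, SearchConfig())
        for step in trace.steps:
            if step.action == "add":
                assert step.chi2_after < step.chi2_before

    def test_needs_two_participants(self, rois4):
        from idionet import ConfigurationError

        truth, samples = _synth_samples(
            rois4, seed=5, n_participants=1, n_individual_range=(0, 0),
            n_group_paths=0, run_lengths=(60,),
        )
        with pytest.raises(ConfigurationError):
            group_search(samples[:1], SearchConfig())


class TestIndividualSearch:
    def test_no_heterogeneity_adds_nothing(self, rois4):
        # data generated exactly from the group model with strong weights:
        # the group structure already fits, so no individual paths
        A = np.zeros((4, 4))
        A[1, 0] = 0.6
        A[3, 2] = 0.5
        Phi = np.diag([0.4, 0.4, 0.4, 0.4])
        ts = simulate_var(rois4, A, Phi, 1.0, T=5000, seed=11)
        sample = build_lagged_sample(ts)
        group = NetworkStructure.null(rois4).with_path(
            PathSpec("a", "b", lag=0, level=GROUP)
        ).with_path(PathSpec("c", "d", lag=0, level=GROUP))
        net, trace = individual_search(sample, group, SearchConfig())
        assert net.structure.paths_at_level(INDIVIDUAL) == ()

    def test_planted_unique_path_found(self, rois4):
        A = np.zeros((4, 4))
        A[1, 0] = 0.6   # group path a->b
        A[2, 3] = 0.6   # this person's unique path d->c
        Phi = np.diag([0.4, 0.4, 0.4, 0.4])
        ts = simulate_var(rois4, A, Phi, 1.0, T=1000, seed=13)
        sample = build_lagged_sample(ts)
        group = NetworkStructure.null(rois4).with_path(
            PathSpec("a", "b", lag=0, level=GROUP)
        )
        net, _ = individual_search(sample, group, SearchConfig())
        found = {p.key for p in net.structure.paths_at_level(INDIVIDUAL)}
        assert (0, "d", "c") in found

    def test_satisfied_fit_rule_returns_unchanged(self, rois4):
        ts = simulate_var(rois4, np.zeros((4, 4)), np.diag([0.4] * 4), 1.0,
                          T=300, seed=15)
        sample = build_lagged_sample(ts)
        group = NetworkStructure.null(rois4)
        net, trace = individual_search(
            sample, group, SearchConfig(fit_excellent_required=0)
        )
        assert net.structure == group.with_levels_from(net.structure)
        assert len(net.structure) == len(group)
        assert trace.steps[0].reason == "fit rule satisfied"


class TestSampleSearch:
    @pytest.fixture(scope="class")
    def small_run(self, rois4):
        truth, samples = _synth_samples(
            rois4, seed=23, n_participants=4, run_lengths=(120, 120),
            n_group_paths=2, n_individual_range=(1, 2),
        )
        return truth, samples, run_sample_search(samples, SearchConfig())

    def test_every_network_contains_group_structure(self, small_run):
        _, _, result = small_run
        for net in result.networks:
            assert net.structure.contains_structure(result.group_structure)

    def test_group_edges_shared_weights_individualized(self, small_run):
        _, _, result = small_run
        group_keys = {p.key for p in result.group_structure.non_ar_paths}
        if not group_keys:
            pytest.skip("no group paths found in this benchmark draw")
        for key in group_keys:
            betas = []
            for net in result.networks:
                levels = {p.key: p.level for p in net.structure.paths}
                assert levels[key] == GROUP
                path = next(p for p in net.structure.paths if p.key == key)
                betas.append(net.estimate_for(path).beta)
            assert len(set(betas)) == len(betas)  # fit uniquely per person

    def test_deterministic_given_data_and_config(self, small_run, rois4):
        truth, samples, result = small_run
        rerun = run_sample_search(samples, SearchConfig())
        assert rerun.group_structure == result.group_structure
        assert [n.structure for n in rerun.networks] == [
            n.structure for n in result.networks
        ]
        assert [s.to_dict() for s in rerun.group_trace.steps] == [
            s.to_dict() for s in result.group_trace.steps
        ]

    def test_trace_replay_reproduces_structures(self, small_run, rois4):
        _, _, result = small_run
        replayed_group = result.group_trace.replay(rois4)
        assert {p.key for p in replayed_group.paths} == {
            p.key for p in result.group_structure.paths
        }
        for net in result.networks:
            tr = result.individual_traces[net.participant_id]
            replayed = tr.replay(rois4, base=result.group_structure)
            assert {p.key for p in replayed.paths} == {
                p.key for p in net.structure.paths
            }
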