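"""Complexity and subnetwork-density counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idionet import (
    DEFAULT_ROI_SET,
    NetworkStructure,
    RoiSet,
    compute_metrics,
    summarize_sample,
)
from idionet.metrics import NetworkMetrics
from idionet.paths import PathSpec


def _structure_with_counts(rois, n_mrn, n_dmn, n_between):
    """AR paths plus the requested number of each edge category."""
    mrn = rois.mrn_labels
    dmn = rois.dmn_labels
    pairs = {"mrn": [], "dmn": [], "between": []}
    for lag in (0, 1):
        for src in mrn:
            for tgt in mrn:
                if src != tgt:
                    pairs["mrn"].append((lag, src, tgt))
        for src in dmn:
            for tgt in dmn:
                if src != tgt:
                    pairs["dmn"].append((lag, src, tgt))
        for src in mrn:
            for tgt in dmn:
                pairs["between"].append((lag, src, tgt))
    structure = NetworkStructure.null(rois)
    for cat, n in (("mrn", n_mrn), ("dmn", n_dmn), ("between", n_between)):
        for lag, src, tgt in pairs[cat][:n]:
            structure = structure.with_path(PathSpec(src, tgt, lag=lag))
    return structure


class TestCounting:
    def test_thirty_five_connection_network(self):
        # 10 AR + 12 within-MRN + 6 within-DMN + 7 between: the density
        # profile lands on the within-MRN > between >= within-DMN pattern
        structure = _structure_with_counts(DEFAULT_ROI_SET, 12, 6, 7)
        m = compute_metrics(structure)
        assert m.complexity == 35
        assert m.density_mrn == pytest.approx(12 / 35)
        assert m.density_dmn == pytest.approx(6 / 35)
        assert m.density_between == pytest.approx(7 / 35)
        assert m.density_mrn > m.density_between >= m.density_dmn

    def test_ar_only_network(self):
        m = compute_metrics(NetworkStructure.null(DEFAULT_ROI_SET))
        assert m.complexity == 10
        assert m.density_mrn == m.density_dmn == m.density_between == 0.0

    def test_counting_conservation(self):
        structure = _structure_with_counts(DEFAULT_ROI_SET, 5, 3, 4)
        m = compute_metrics(structure)
        assert m.n_within_mrn + m.n_within_dmn + m.n_between + m.n_ar == \
            m.complexity

    def test_densities_sum_below_one(self):
        m = compute_metrics(_structure_with_counts(DEFAULT_ROI_SET, 12, 6, 7))
        assert m.density_mrn + m.density_dmn + m.density_between <= 1.0

    @pytest.mark.parametrize(
        "rule, complexity, mrn_count",
        [("complexity", 15, 2), ("densities", 15, 8), ("neither", 5, 2)],
    )
    def test_ar_counting_rules(self, rule, complexity, mrn_count):
        structure = _structure_with_counts(DEFAULT_ROI_SET, 2, 1, 2)
        m = compute_metrics(structure, count_ar_in=rule)
        assert m.complexity == complexity
        assert m.n_within_mrn == mrn_count

    def test_degenerate_empty_network(self, rois3):
        structure = NetworkStructure.null(rois3, include_ar=False)
        m = compute_metrics(structure, count_ar_in="neither")
        assert m.degenerate
        assert m.complexity == 0
        assert m.density_mrn == 0.0

    def test_label_permutation_invariance(self):
        structure = _structure_with_counts(DEFAULT_ROI_SET, 4, 2, 3)
        m0 = compute_metrics(structure)
        renames = {l: f"node_{k}" for k, l in enumerate(DEFAULT_ROI_SET.labels)}
        rois2 = RoiSet(
            labels=tuple(renames[l] for l in DEFAULT_ROI_SET.labels),
            membership={renames[l]: n
                        for l, n in DEFAULT_ROI_SET.membership.items()},
        )
        renamed = NetworkStructure(
            rois=rois2,
            paths=tuple(
                PathSpec(renames[p.source], renames[p.target], lag=p.lag,
                         level=p.level)
                for p in structure.paths
            ),
        )
        m1 = compute_metrics(renamed)
        for f in ("complexity", "n_within_mrn", "n_within_dmn", "n_between",
                  "density_mrn", "density_dmn", "density_between"):
            assert getattr(m0, f) == getattr(m1, f)

    def test_lag0_and_lag1_both_counted(self, rois3):
        structure = (NetworkStructure.null(rois3)
                     .with_path(PathSpec("a", "b", lag=0))
                     .with_path(PathSpec("a", "b", lag=1)))
        m = compute_metrics(structure)
        assert m.n_within_mrn == 2


def _metric(pid, complexity):
    denom = complexity if complexity else 1
    return NetworkMetrics(participant_id=pid, complexity=complexity,
                          n_within_mrn=0, n_within_dmn=0, n_between=0,
                          n_ar=complexity, density_mrn=0.0, density_dmn=0.0,
                          density_between=0.0)


class TestSummary:
    def test_mean_and_sd(self):
        out = summarize_sample([_metric("a", 33), _metric("b", 35),
                                _metric("c", 37)])
        assert out.loc["complexity", "mean"] == 35
        assert out.loc["complexity", "sd"] == pytest.approx(2.0)

    def test_repeated_value_has_zero_sd(self):
        out = summarize_sample([_metric("a", 35), _metric("b", 35)])
        assert out.loc["complexity", "sd"] == 0.0

    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=2,
                    max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mean_bounded_by_extremes(self, values):
        ms = [_metric(f"p{k}", v) for k, v in enumerate(values)]
        mean = summarize_sample(ms).loc["complexity", "mean"]
        assert min(values) <= mean <= max(values)
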