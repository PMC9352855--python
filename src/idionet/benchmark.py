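"""Truth-aware benchmarks: specificity under the null and edge recovery.

These drive the package's validation studies: simulate from a known
truth at study scale (n=11, p=10, two runs of 134), run the two-stage
search, and score the recovered structures against the planted ones.
AR paths are present in every truth and every fitted structure by
construction, so they are excluded from recovery scoring — including
them would only inflate the agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .paths import NetworkStructure, PersonNetwork
from .sample import build_lagged_sample
from .search import SearchConfig, group_search, run_sample_search
from .synth import SynthConfig, SyntheticTruth, generate_truth, simulate_timeseries

#: AR-only truth at study scale: no shared or person-unique paths
NULL_CONFIG = SynthConfig(n_group_paths=0, n_individual_range=(0, 0))

#: study-scale recovery benchmark: 12 shared paths, 10-15 unique each
BENCHMARK_CONFIG = SynthConfig()


def group_recovery_scores(truth: SyntheticTruth,
                          structure: NetworkStructure) -> tuple[float, float]:
    """(recall, precision) of the recovered group paths (non-AR)."""
    want = {p.key for p in truth.group_structure().non_ar_paths}
    got = {p.key for p in structure.non_ar_paths}
    tp = len(want & got)
    recall = tp / len(want) if want else 1.0
    precision = tp / len(got) if got else 1.0
    return recall, precision


def edge_recovery_scores(truth: SyntheticTruth,
                         networks: tuple[PersonNetwork, ...],
                         ) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1) over all non-AR edges."""
    tp = fp = fn = 0
    for net in networks:
        want = {p.key for p in
                truth.structure_for(net.participant_id).non_ar_paths}
        got = {p.key for p in net.structure.non_ar_paths}
        tp += len(want & got)
        fp += len(got - want)
        fn += len(want - got)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


@dataclass
class NullSpecificityResult:
    """Group-stage false positives under an AR-only truth."""

    n_seeds: int
    spurious_counts: list[int]

    @property
    def frac_ar_only(self) -> float:
        return float(np.mean([c == 0 for c in self.spurious_counts]))

    @property
    def mean_spurious(self) -> float:
        return float(np.mean(self.spurious_counts))


def null_specificity(n_seeds: int = 20, seed: int = 0,
                     synth: SynthConfig = NULL_CONFIG,
                     search: SearchConfig | None = None,
                     ) -> NullSpecificityResult:
    """Run the group stage on AR-only data across seeds.

    A well-calibrated group criterion (a path must be significant for
    >= 75% of the sample) should almost never admit a spurious shared
    path at alpha = .05.
    """
    search = search or SearchConfig()
    counts = []
    for k in range(n_seeds):
        truth = generate_truth(synth, seed=seed + k)
        samples = [build_lagged_sample(ts) for ts in simulate_timeseries(truth)]
        structure, _ = group_search(samples, search)
        counts.append(len(structure.non_ar_paths))
    return NullSpecificityResult(n_seeds=n_seeds, spurious_counts=counts)


@dataclass
class RecoveryResult:
    """Per-seed and averaged recovery scores on the study-scale benchmark."""

    group_recall: list[float]
    group_precision: list[float]
    edge_precision: list[float]
    edge_recall: list[float]
    edge_f1: list[float]

    def mean(self, field: str) -> float:
        return float(np.mean(getattr(self, field)))


def recovery_benchmark(n_seeds: int = 10, seed: int = 0,
                       synth: SynthConfig = BENCHMARK_CONFIG,
                       search: SearchConfig | None = None,
                       ) -> RecoveryResult:
    """Full two-stage search against planted truths across seeds."""
    search = search or SearchConfig()
    out = RecoveryResult([], [], [], [], [])
    for k in range(n_seeds):
        truth = generate_truth(synth, seed=seed + k)
        samples = [build_lagged_sample(ts) for ts in simulate_timeseries(truth)]
        result = run_sample_search(samples, search)
        g_rec, g_prec = group_recovery_scores(truth, result.group_structure)
        e_prec, e_rec, e_f1 = edge_recovery_scores(truth, result.networks)
        out.group_recall.append(g_rec)
        out.group_precision.append(g_prec)
        out.edge_precision.append(e_prec)
        out.edge_recall.append(e_rec)
        out.edge_f1.append(e_f1)
    return out
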