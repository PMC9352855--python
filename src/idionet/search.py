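"""Two-stage group -> individual model search.

Stage 1 starts every participant at the null structure (AR paths only)
and iteratively frees the candidate path whose exact-refit
modification index is significant for the largest number of
participants, provided that number reaches the group criterion — at
least a fraction ``group_threshold`` of the sample (ceiling-rounded,
e.g. 9 of 11 at 0.75). Added paths enter *every* participant's
structure at group level. The stage ends when no candidate reaches
the criterion, after which group paths whose estimates are significant
for too few participants are pruned (AR paths never).

Stage 2 runs per participant: free that person's best significant
candidate until the model "fits well" — at least
``fit_excellent_required`` of the four index cutoffs (RMSEA <= .05,
SRMR <= .05, CFI >= .95, NNFI >= .95) — or no significant candidate
remains; then prune nonsignificant individual-level paths. All paths,
group and individual, are estimated uniquely per person throughout.

Every addition and pruning is logged in a replayable trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, EstimationError
from .paths import GROUP, INDIVIDUAL, NetworkStructure, PathSpec, PersonNetwork
from .sample import LaggedSample
from .usem import (
    UsemFit,
    _index_arrays,
    fit_structure,
    indices_for_fit,
    modification_indices,
    person_network,
)


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the two-stage search; defaults follow standard use."""

    group_threshold: float = 0.75
    alpha_mi: float = 0.05
    alpha_prune: float = 0.05
    fit_excellent_required: int = 2
    rmsea_cut: float = 0.05
    srmr_cut: float = 0.05
    cfi_cut: float = 0.95
    nnfi_cut: float = 0.95
    max_iterations: int = 60
    prune_group: bool = True
    prune_individual: bool = True
    #: after the individual stage, re-test every group path in the
    #: complete person-specific models and demote those significant for
    #: fewer than the group criterion. Group-stage pruning happens under
    #: group-only models, where a participant's *missing* individual
    #: paths bias the estimates of marginal group paths; the re-check
    #: removes that contamination. Demoted paths stay at individual
    #: level for participants whose estimate is significant.
    confirmatory_group_prune: bool = True
    bonferroni: bool = False
    max_nonconverged_frac: float = 0.25
    include_ar: bool = True

    def __post_init__(self):
        if not (0.5 < self.group_threshold <= 1.0):
            raise ConfigurationError("group_threshold must be in (0.5, 1]")
        for name in ("alpha_mi", "alpha_prune"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if not (0 <= self.fit_excellent_required <= 4):
            raise ConfigurationError("fit_excellent_required must be 0..4")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")

    def required_count(self, n: int) -> int:
        """Participants required for a group path: ceil(threshold * n)."""
        return math.ceil(self.group_threshold * n)

    def fit_rule_satisfied(self, fit_indices) -> bool:
        return fit_indices.n_excellent(
            self.rmsea_cut, self.srmr_cut, self.cfi_cut, self.nnfi_cut
        ) >= self.fit_excellent_required


@dataclass(frozen=True)
class TraceStep:
    """One audited search event (addition, pruning, or stop)."""

    stage: str            # "group" | "individual"
    iteration: int
    action: str           # "add" | "prune" | "stop" | "rollback"
    path: tuple | None = None   # (lag, source, target)
    level: str | None = None
    participant_id: str | None = None
    n_significant: int | None = None
    n_eligible: int | None = None
    score_sum: float | None = None
    chi2_before: float | None = None
    chi2_after: float | None = None
    reason: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class SearchTrace:
    """Ordered log of search events; replaying it rebuilds the structure."""

    steps: list[TraceStep] = field(default_factory=list)

    def log(self, **kwargs) -> None:
        self.steps.append(TraceStep(**kwargs))

    def replay(self, rois, include_ar: bool = True,
               base: NetworkStructure | None = None) -> NetworkStructure:
        """Apply the logged additions/prunings to the starting structure."""
        structure = base if base is not None else NetworkStructure.null(
            rois, include_ar=include_ar
        )
        for step in self.steps:
            if step.path is None:
                continue
            lag, src, tgt = step.path
            path = PathSpec(src, tgt, lag=lag, level=step.level or GROUP)
            if step.action == "add":
                structure = structure.with_path(path)
            elif step.action == "prune":
                structure = structure.without_path(path)
        return structure

    def to_records(self) -> list[dict]:
        return [s.to_dict() for s in self.steps]


def _warm_theta(new_structure: NetworkStructure, old_fit: UsemFit) -> np.ndarray:
    """Start vector for a modified structure: old values, new paths at 0."""
    _, _, old_a, old_phi = _index_arrays(old_fit.structure)
    na = len(old_a)
    lookup = {p.key: float(old_fit.theta[k]) for k, p in enumerate(old_a)}
    lookup.update(
        {p.key: float(old_fit.theta[na + k]) for k, p in enumerate(old_phi)}
    )
    _, _, new_a, new_phi = _index_arrays(new_structure)
    vals = [lookup.get(p.key, 0.0) for p in new_a]
    vals += [lookup.get(p.key, 0.0) for p in new_phi]
    log_psi = old_fit.theta[len(old_a) + len(old_phi):]
    return np.concatenate([np.asarray(vals, dtype=float), log_psi])


def _refit_all(samples: Sequence[LaggedSample], structure: NetworkStructure,
               states: dict[str, UsemFit | None]) -> dict[str, UsemFit | None]:
    """Refit every participant under a new structure, warm-started."""
    new_states: dict[str, UsemFit | None] = {}
    for s in samples:
        old = states.get(s.participant_id)
        theta0 = _warm_theta(structure, old) if old is not None else None
        try:
            new_states[s.participant_id] = fit_structure(
                s, structure, theta0=theta0, raise_on_failure=True
            )
        except EstimationError:
            new_states[s.participant_id] = None
    return new_states


def _check_convergence(states: dict, config: SearchConfig, stage: str) -> list[str]:
    """IDs of converged participants; abort if too many failed."""
    ok = [pid for pid, st in states.items() if st is not None]
    n = len(states)
    failed = n - len(ok)
    if n and failed / n > config.max_nonconverged_frac:
        raise EstimationError(
            f"{stage} search aborted: {failed}/{n} participants failed to "
            "converge",
            diagnostics={"failed": [pid for pid, st in states.items() if st is None]},
        )
    return ok


def group_search(samples: Sequence[LaggedSample], config: SearchConfig,
                 ) -> tuple[NetworkStructure, SearchTrace]:
    """Stage 1: find the directed paths shared by the sample."""
    if len(samples) < 2:
        raise ConfigurationError("group search needs at least 2 participants")
    rois = samples[0].rois
    for s in samples:
        if s.rois.labels != rois.labels:
            raise ConfigurationError("all participants must share the ROI set")
    n = len(samples)
    required = config.required_count(n)
    crit = stats.chi2.ppf(1.0 - config.alpha_mi, 1)
    trace = SearchTrace()

    structure = NetworkStructure.null(rois, include_ar=config.include_ar)
    states = _refit_all(samples, structure, {})

    for iteration in range(config.max_iterations):
        ok_ids = _check_convergence(states, config, "group")
        candidates = structure.admissible_candidates()
        if not candidates:
            break
        alpha_crit = crit
        if config.bonferroni:
            alpha_crit = stats.chi2.ppf(
                1.0 - config.alpha_mi / len(candidates), 1
            )
        counts: dict[tuple, int] = {c.key: 0 for c in candidates}
        sums: dict[tuple, float] = {c.key: 0.0 for c in candidates}
        by_key = {c.key: c for c in candidates}
        for s in samples:
            st = states[s.participant_id]
            if st is None:
                continue
            for mi in modification_indices(s, structure, fitted=st,
                                           candidates=candidates):
                sums[mi.path.key] += mi.score
                if mi.converged and mi.score >= alpha_crit:
                    counts[mi.path.key] += 1
        # best candidate: participant count, then summed score, then lex key
        best_key = min(counts, key=lambda k: (-counts[k], -sums[k], k))
        if counts[best_key] < required:
            trace.log(stage="group", iteration=iteration, action="stop",
                      reason="no candidate reaches the group criterion",
                      n_significant=counts[best_key], n_eligible=len(ok_ids))
            break
        path = replace(by_key[best_key], level=GROUP)
        chi2_before = sum(states[i].chi2 for i in ok_ids)
        structure = structure.with_path(path)
        states = _refit_all(samples, structure, states)
        ok_after = [pid for pid in ok_ids if states.get(pid) is not None]
        chi2_after = sum(states[i].chi2 for i in ok_after)
        trace.log(stage="group", iteration=iteration, action="add",
                  path=path.key, level=GROUP,
                  n_significant=counts[best_key], n_eligible=len(ok_ids),
                  score_sum=sums[best_key],
                  chi2_before=chi2_before, chi2_after=chi2_after)
    else:
        trace.log(stage="group", iteration=config.max_iterations,
                  action="stop", reason="max_iterations reached")

    if config.prune_group:
        structure, states = _prune_group(samples, structure, states,
                                         config, trace)
    return structure, trace


def _prune_group(samples, structure, states, config: SearchConfig,
                 trace: SearchTrace):
    """Drop group paths significant for too few participants (never AR)."""
    n = len(samples)
    required = config.required_count(n)
    zcrit = stats.norm.ppf(1.0 - config.alpha_prune / 2.0)
    iteration = 0
    while True:
        prunable = structure.paths_at_level(GROUP)
        if not prunable:
            break
        ok_ids = _check_convergence(states, config, "group-prune")
        networks = {}
        for s in samples:
            st = states[s.participant_id]
            if st is None:
                continue
            networks[s.participant_id] = person_network(st, compute_se=True)
        counts = {}
        for path in prunable:
            c = 0
            for pid in ok_ids:
                est = networks[pid].estimate_for(path)
                if np.isfinite(est.z) and abs(est.z) >= zcrit:
                    c += 1
            counts[path.key] = c
        failing = {k: c for k, c in counts.items() if c < required}
        if not failing:
            break
        # remove the least-supported path, then re-examine after refit
        worst = min(failing, key=lambda k: (failing[k], k))
        path = next(p for p in prunable if p.key == worst)
        structure = structure.without_path(path)
        states = _refit_all(samples, structure, states)
        trace.log(stage="group", iteration=iteration, action="prune",
                  path=path.key, level=GROUP, n_significant=failing[worst],
                  n_eligible=len(ok_ids))
        iteration += 1
    return structure, states


def individual_search(sample: LaggedSample, group_structure: NetworkStructure,
                      config: SearchConfig,
                      ) -> tuple[PersonNetwork, SearchTrace]:
    """Stage 2: person-unique paths until the model fits well."""
    crit = stats.chi2.ppf(1.0 - config.alpha_mi, 1)
    trace = SearchTrace()
    structure = group_structure
    fit = fit_structure(sample, structure)

    for iteration in range(config.max_iterations):
        indices = indices_for_fit(fit)
        if config.fit_rule_satisfied(indices):
            trace.log(stage="individual", iteration=iteration, action="stop",
                      participant_id=sample.participant_id,
                      reason="fit rule satisfied")
            break
        mis = modification_indices(sample, structure, fitted=fit)
        alpha_crit = crit
        if config.bonferroni and mis:
            alpha_crit = stats.chi2.ppf(1.0 - config.alpha_mi / len(mis), 1)
        significant = [m for m in mis if m.converged and m.score >= alpha_crit]
        if not significant:
            trace.log(stage="individual", iteration=iteration, action="stop",
                      participant_id=sample.participant_id,
                      reason="no significant candidate remains")
            break
        best = significant[0]  # already sorted by (-score, key)
        path = replace(best.path, level=INDIVIDUAL)
        new_structure = structure.with_path(path)
        try:
            new_fit = fit_structure(sample, new_structure,
                                    theta0=_warm_theta(new_structure, fit))
        except EstimationError:
            trace.log(stage="individual", iteration=iteration,
                      action="rollback", path=path.key, level=INDIVIDUAL,
                      participant_id=sample.participant_id,
                      reason="refit failed to converge; addition rolled back")
            break
        trace.log(stage="individual", iteration=iteration, action="add",
                  path=path.key, level=INDIVIDUAL,
                  participant_id=sample.participant_id,
                  score_sum=best.score,
                  chi2_before=fit.chi2, chi2_after=new_fit.chi2)
        structure, fit = new_structure, new_fit
    else:
        trace.log(stage="individual", iteration=config.max_iterations,
                  action="stop", participant_id=sample.participant_id,
                  reason="max_iterations reached")

    if config.prune_individual:
        structure, fit = _prune_individual(sample, structure, fit, config, trace)
    return person_network(fit, compute_se=True), trace


def _prune_individual(sample, structure, fit, config: SearchConfig,
                      trace: SearchTrace):
    """Drop nonsignificant individual-level paths (never group or AR)."""
    zcrit = stats.norm.ppf(1.0 - config.alpha_prune / 2.0)
    iteration = 0
    while True:
        prunable = structure.paths_at_level(INDIVIDUAL)
        if not prunable:
            break
        network = person_network(fit, compute_se=True)
        zs = {p.key: abs(network.estimate_for(p).z) for p in prunable}
        failing = {k: z for k, z in zs.items()
                   if not np.isfinite(z) or z < zcrit}
        if not failing:
            break
        worst = min(failing, key=lambda k: (failing[k], k))
        path = next(p for p in prunable if p.key == worst)
        structure = structure.without_path(path)
        fit = fit_structure(sample, structure,
                            theta0=_warm_theta(structure, fit))
        trace.log(stage="individual", iteration=iteration, action="prune",
                  path=path.key, level=INDIVIDUAL,
                  participant_id=sample.participant_id)
        iteration += 1
    return structure, fit


@dataclass
class SearchResult:
    """Full output of the two-stage search over a sample."""

    group_structure: NetworkStructure
    group_trace: SearchTrace
    networks: tuple[PersonNetwork, ...]
    individual_traces: dict[str, SearchTrace]


def _confirmatory_group_prune(samples, group_structure, networks,
                              config: SearchConfig, group_trace: SearchTrace,
                              individual_traces: dict[str, SearchTrace]):
    """Re-test group paths in the complete person-specific models.

    A group path significant for fewer than the group criterion once
    every participant's individual paths are in place is demoted: kept
    at individual level where its estimate is significant, removed
    elsewhere. Repeats to a fixed point, one path at a time.
    """
    n = len(samples)
    required = config.required_count(n)
    zcrit = stats.norm.ppf(1.0 - config.alpha_prune / 2.0)
    by_pid = {s.participant_id: s for s in samples}
    nets = {net.participant_id: net for net in networks}

    def _zcount(path):
        c = 0
        for net in nets.values():
            z = net.estimate_for(path).z
            if np.isfinite(z) and abs(z) >= zcrit:
                c += 1
        return c

    iteration = 0
    while True:
        prunable = group_structure.paths_at_level(GROUP)
        if not prunable:
            break
        counts = {p.key: _zcount(p) for p in prunable}
        failing = {k: c for k, c in counts.items() if c < required}
        if not failing:
            break
        worst = min(failing, key=lambda k: (failing[k], k))
        path = next(p for p in prunable if p.key == worst)
        group_structure = group_structure.without_path(path)
        group_trace.log(stage="group", iteration=iteration, action="prune",
                        path=path.key, level=GROUP,
                        n_significant=failing[worst], n_eligible=n,
                        reason="confirmatory re-check in full models")
        for pid, net in list(nets.items()):
            z = net.estimate_for(path).z
            keep = np.isfinite(z) and abs(z) >= zcrit
            old_structure = net.structure
            if keep:
                demoted = replace(path, level=INDIVIDUAL)
                new_structure = (old_structure.without_path(path)
                                 .with_path(demoted))
                individual_traces[pid].log(
                    stage="individual", iteration=iteration, action="add",
                    path=path.key, level=INDIVIDUAL, participant_id=pid,
                    reason="group path retained at individual level",
                )
            else:
                new_structure = old_structure.without_path(path)
            fit = fit_structure(by_pid[pid], new_structure)
            nets[pid] = person_network(fit, compute_se=True)
        iteration += 1
    ordered = tuple(nets[s.participant_id] for s in samples)
    return group_structure, ordered


def run_sample_search(samples: Sequence[LaggedSample],
                      config: SearchConfig | None = None) -> SearchResult:
    """Group search, then an individual search per participant.

    Deterministic given the samples and config; every final network's
    structure contains every group path.
    """
    config = config or SearchConfig()
    group_structure, group_trace = group_search(samples, config)
    networks = []
    individual_traces = {}
    for s in samples:
        net, tr = individual_search(s, group_structure, config)
        networks.append(net)
        individual_traces[s.participant_id] = tr
    networks = tuple(networks)
    if config.confirmatory_group_prune:
        group_structure, networks = _confirmatory_group_prune(
            samples, group_structure, networks, config, group_trace,
            individual_traces,
        )
    return SearchResult(
        group_structure=group_structure,
        group_trace=group_trace,
        networks=networks,
        individual_traces=individual_traces,
    )
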