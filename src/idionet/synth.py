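"""Synthetic study datasets from a known directed-network truth.

The generator emulates the study conditions this package targets: 11
participants, ten ROIs (6 MRN + 4 DMN), two runs of 134 volumes each,
a shared group-level directed network plus person-unique connections
with individualized weights, and hormone/behavior covariates with
realistic means and SDs. Data are drawn from the same model class the
estimator assumes,

    eta_t = (I - A_i)^-1 (Phi_i eta_{t-1} + zeta_t),

with Gaussian diagonal-covariance innovations, so planted structures
are exactly recoverable in principle and every downstream stage can be
validated against a known truth.

Group paths are shared by all participants; every participant
additionally receives their own individual paths, and *all* weights —
group and individual — are drawn per person. Path placement favors
within-MRN connections so that default-scale truths land near a
complexity of ~35 with the within-MRN > between >= within-DMN density
ordering typical of rotation-task data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError
from .multimodal import MultimodalRecord
from .paths import GROUP, INDIVIDUAL, NetworkStructure, PathSpec, ar_paths
from .rois import DEFAULT_ROI_SET, MRN, RoiSet
from .sample import ParticipantTimeSeries

_CATEGORIES = ("within_mrn", "within_dmn", "between")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the study-scale conditions."""

    rois: RoiSet = DEFAULT_ROI_SET
    n_participants: int = 11
    run_lengths: tuple[int, ...] = (134, 134)
    n_group_paths: int = 12
    n_individual_range: tuple[int, int] = (10, 15)
    weight_range: tuple[float, float] = (0.3, 0.6)
    ar_weight_range: tuple[float, float] = (0.3, 0.6)
    p_contemporaneous: float = 0.5
    #: sampling weight of (within-MRN, within-DMN, between) placements
    category_probs: tuple[float, float, float] = (0.48, 0.24, 0.28)
    noise_variance_range: tuple[float, float] = (0.8, 1.2)
    max_spectral_radius: float = 0.9
    max_tries: int = 500
    burn_in: int = 100
    #: plant contemporaneous paths consistent with one (hidden) causal
    #: ordering per draw, so every participant's A matrix is recursive.
    #: Reciprocal or cyclic contemporaneous truths are nearly
    #: observationally equivalent to their flips at fMRI-length series,
    #: which makes directed recovery ill-posed rather than hard.
    acyclic_contemporaneous: bool = True

    def __post_init__(self):
        if len(self.rois) < 2:
            raise ConfigurationError("need at least 2 ROIs")
        if self.n_participants < 1:
            raise ConfigurationError("need at least 1 participant")
        for name in ("weight_range", "ar_weight_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi < 1.0):
                raise ConfigurationError(
                    f"{name} magnitudes must lie in [0, 1), got ({lo}, {hi})"
                )
        lo, hi = self.n_individual_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("invalid n_individual_range")
        if not (0.0 <= self.p_contemporaneous <= 1.0):
            raise ConfigurationError("p_contemporaneous must be in [0, 1]")
        if any(c < 0 for c in self.category_probs) or sum(self.category_probs) <= 0:
            raise ConfigurationError("category_probs must be nonnegative, not all 0")
        if self.burn_in < 50:
            raise ConfigurationError("burn_in must be >= 50")
        n_slots = len(self._slots())
        if self.n_group_paths + hi > n_slots:
            raise ConfigurationError(
                f"requested up to {self.n_group_paths + hi} non-AR paths but "
                f"only {n_slots} directed slots exist"
            )

    def _slots(self) -> list[tuple[int, str, str, str]]:
        """All admissible non-AR (lag, source, target, category) slots."""
        slots = []
        for lag in (0, 1):
            for src in self.rois.labels:
                for tgt in self.rois.labels:
                    if src == tgt:
                        continue
                    s_net = self.rois.network_of(src)
                    t_net = self.rois.network_of(tgt)
                    if s_net != t_net:
                        cat = "between"
                    elif s_net == MRN:
                        cat = "within_mrn"
                    else:
                        cat = "within_dmn"
                    slots.append((lag, src, tgt, cat))
        return slots


@dataclass(frozen=True)
class HormoneBehaviorParams:
    """Means/SDs of the covariates and their coupling to the network.

    ``coupling`` gives, per variable, the correlation-scale weight
    linking it to a participant's (standardized) number of true
    individual paths; 0 decouples the variable. Defaults plant the
    positive behavior-complexity and progesterone/testosterone
    relations at moderate strength and leave estradiol uncoupled.
    """

    estradiol_mean: float = 1.33
    estradiol_sd: float = 0.71
    progesterone_mean: float = 239.01
    progesterone_sd: float = 124.99
    testosterone_mean: float = 132.82
    testosterone_sd: float = 64.88
    pct_correct_mean: float = 75.00
    pct_correct_sd: float = 8.39
    coupling: Mapping[str, float] = field(
        default_factory=lambda: {
            "pct_correct": 0.5,
            "progesterone": 0.4,
            "testosterone": 0.4,
            "estradiol": 0.0,
        }
    )

    def __post_init__(self):
        for name in ("estradiol", "progesterone", "testosterone", "pct_correct"):
            sd = getattr(self, f"{name}_sd")
            if sd < 0:
                raise ConfigurationError(f"{name}_sd must be >= 0")
        if not (0.0 < self.pct_correct_mean <= 100.0):
            raise ConfigurationError("pct_correct_mean must be in (0, 100]")
        for var, rho in self.coupling.items():
            if abs(rho) > 1:
                raise ConfigurationError(f"coupling[{var!r}] must be in [-1, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """A complete data-generating system for one synthetic sample."""

    config: SynthConfig
    seed: int
    participant_ids: tuple[str, ...]
    group_paths: tuple[PathSpec, ...]        # includes the AR paths
    individual_paths: Mapping[str, tuple[PathSpec, ...]]
    a_matrices: Mapping[str, np.ndarray]
    phi_matrices: Mapping[str, np.ndarray]
    noise_variances: Mapping[str, np.ndarray]

    def structure_for(self, participant_id: str) -> NetworkStructure:
        return NetworkStructure(
            rois=self.config.rois,
            paths=self.group_paths + self.individual_paths[participant_id],
        )

    def group_structure(self) -> NetworkStructure:
        return NetworkStructure(rois=self.config.rois, paths=self.group_paths)

    def spectral_radius(self, participant_id: str) -> float:
        A = self.a_matrices[participant_id]
        Phi = self.phi_matrices[participant_id]
        p = A.shape[0]
        B = np.linalg.inv(np.eye(p) - A)
        return float(np.max(np.abs(np.linalg.eigvals(B @ Phi))))

    def weight_of(self, participant_id: str, path: PathSpec) -> float:
        i = self.config.rois.index(path.target)
        j = self.config.rois.index(path.source)
        mat = self.a_matrices if path.lag == 0 else self.phi_matrices
        return float(mat[participant_id][i, j])

    def stationary_covariance(self, participant_id: str) -> np.ndarray:
        """Analytic stationary covariance of the planted lag-1 system."""
        A = self.a_matrices[participant_id]
        Phi = self.phi_matrices[participant_id]
        psi = self.noise_variances[participant_id]
        p = A.shape[0]
        B = np.linalg.inv(np.eye(p) - A)
        T = B @ Phi
        Q = (B * psi) @ B.T
        # solve V = T V T' + Q by vectorization
        M = np.eye(p * p) - np.kron(T, T)
        v = np.linalg.solve(M, Q.reshape(-1))
        return v.reshape(p, p)

    def lag1_covariance(self, participant_id: str) -> np.ndarray:
        """Analytic cov(eta_t, eta_{t-1}) of the planted system."""
        A = self.a_matrices[participant_id]
        Phi = self.phi_matrices[participant_id]
        p = A.shape[0]
        B = np.linalg.inv(np.eye(p) - A)
        return B @ Phi @ self.stationary_covariance(participant_id)


def _participant_ids(n: int) -> tuple[str, ...]:
    return tuple(f"sub-{k + 1:02d}" for k in range(n))


def _sample_slots(rng: np.random.Generator, available: list, probs_by_cat: dict,
                  p_con: float, k: int) -> list:
    """Sample k (lag, src, tgt, cat) slots without replacement.

    Each slot's weight is its category's sampling weight times the lag
    share (p_con for contemporaneous, 1 - p_con for lagged).
    """
    if k == 0:
        return []
    if k > len(available):
        raise ConfigurationError("infeasible path count: not enough free slots")
    # normalize by available slots per category so category *totals* (not
    # per-slot rates) follow probs_by_cat; between-network pairs are far
    # more numerous than within-DMN pairs and would otherwise dominate
    cat_counts: dict[str, int] = {}
    for s in available:
        cat_counts[s[3]] = cat_counts.get(s[3], 0) + 1
    weights = np.array(
        [probs_by_cat[s[3]] / cat_counts[s[3]]
         * (p_con if s[0] == 0 else 1.0 - p_con)
         for s in available],
        dtype=float,
    )
    if weights.sum() <= 0:
        weights = np.ones(len(available))
    nonzero = int(np.count_nonzero(weights))
    if nonzero < k:  # weighted slots exhausted; let zero-weight slots back in
        weights = weights + 1e-12
    weights = weights / weights.sum()
    chosen = rng.choice(len(available), size=k, replace=False, p=weights)
    return [available[int(i)] for i in sorted(chosen)]


def generate_truth(config: SynthConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Draw a group + individual path layout and stationary weights.

    Weights are rejection-resampled per participant until the implied
    lag-1 system is stationary (spectral radius of (I-A)^-1 Phi below
    the configured ceiling) and (I - A) is well-conditioned; a
    :class:`GenerationError` is raised if the cap on retries is hit.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    rois = config.rois
    p = len(rois)
    ids = _participant_ids(config.n_participants)
    probs_by_cat = dict(zip(_CATEGORIES, config.category_probs))

    slots = config._slots()
    if config.acyclic_contemporaneous:
        order = {l: int(k) for l, k in
                 zip(rois.labels, rng.permutation(p))}
        slots = [s for s in slots
                 if s[0] == 1 or order[s[1]] < order[s[2]]]
    group_slots = _sample_slots(rng, slots, probs_by_cat,
                                config.p_contemporaneous, config.n_group_paths)
    group_keys = {(lag, s, t) for lag, s, t, _ in group_slots}
    group = tuple(ar_paths(rois)) + tuple(
        PathSpec(s, t, lag=lag, level=GROUP) for lag, s, t, _ in group_slots
    )

    individual: dict[str, tuple[PathSpec, ...]] = {}
    lo, hi = config.n_individual_range
    free = [s for s in slots if (s[0], s[1], s[2]) not in group_keys]
    for pid in ids:
        k = int(rng.integers(lo, hi + 1))
        picked = _sample_slots(rng, free, probs_by_cat,
                               config.p_contemporaneous, k)
        individual[pid] = tuple(sorted(
            (PathSpec(s, t, lag=lag, level=INDIVIDUAL)
             for lag, s, t, _ in picked),
            key=lambda q: q.key,
        ))

    a_mats, phi_mats, noise = {}, {}, {}
    idx = {l: k for k, l in enumerate(rois.labels)}
    for pid in ids:
        all_paths = group + individual[pid]
        for attempt in range(config.max_tries):
            A = np.zeros((p, p))
            Phi = np.zeros((p, p))
            for path in all_paths:
                i, j = idx[path.target], idx[path.source]
                if path.is_ar:
                    w = rng.uniform(*config.ar_weight_range)
                else:
                    w = rng.uniform(*config.weight_range) * rng.choice((-1.0, 1.0))
                if path.lag == 0:
                    A[i, j] = w
                else:
                    Phi[i, j] = w
            E = np.eye(p) - A
            if np.linalg.cond(E) > 1e6:
                continue
            B = np.linalg.inv(E)
            if np.max(np.abs(np.linalg.eigvals(B @ Phi))) < config.max_spectral_radius:
                break
        else:
            raise GenerationError(
                f"{pid}: no stationary weight draw within {config.max_tries} tries"
            )
        a_mats[pid] = A
        phi_mats[pid] = Phi
        noise[pid] = rng.uniform(*config.noise_variance_range, size=p)

    return SyntheticTruth(
        config=config,
        seed=seed,
        participant_ids=ids,
        group_paths=tuple(sorted(group, key=lambda q: q.key)),
        individual_paths=individual,
        a_matrices=a_mats,
        phi_matrices=phi_mats,
        noise_variances=noise,
    )


def simulate_timeseries(truth: SyntheticTruth,
                        run_lengths: Sequence[int] | None = None,
                        seed: int | None = None,
                        ) -> tuple[ParticipantTimeSeries, ...]:
    """Simulate each participant's runs from the planted system.

    Runs are independent realizations: each starts from its own
    burn-in (>= 50 steps, discarded), mirroring separately acquired
    runs that are only concatenated afterwards.
    """
    config = truth.config
    lengths = tuple(run_lengths) if run_lengths is not None else config.run_lengths
    if any(t < 10 for t in lengths):
        raise ConfigurationError("every run length must be >= 10")
    root = np.random.SeedSequence(
        [truth.seed if seed is None else seed, 0x7135]
    )
    p = len(config.rois)
    out = []
    for pid, child in zip(truth.participant_ids,
                          root.spawn(len(truth.participant_ids))):
        A = truth.a_matrices[pid]
        Phi = truth.phi_matrices[pid]
        sd = np.sqrt(truth.noise_variances[pid])
        E = np.eye(p) - A
        try:
            B = np.linalg.inv(E)
        except np.linalg.LinAlgError:
            raise GenerationError(f"{pid}: (I - A) is singular") from None
        runs = []
        for run_len, run_seed in zip(lengths, child.spawn(len(lengths))):
            rng = np.random.default_rng(run_seed)
            total = config.burn_in + run_len
            zeta = rng.normal(0.0, 1.0, size=(total, p)) * sd
            eta = np.zeros(p)
            rows = np.empty((total, p))
            for t in range(total):
                eta = B @ (Phi @ eta + zeta[t])
                rows[t] = eta
            runs.append(rows[config.burn_in:])
        out.append(ParticipantTimeSeries(participant_id=pid, rois=config.rois,
                                         runs=tuple(runs)))
    return tuple(out)


def generate_covariates(truth: SyntheticTruth,
                        params: HormoneBehaviorParams | None = None,
                        seed: int | None = None,
                        ) -> tuple[MultimodalRecord, ...]:
    """Draw hormone/behavior covariates, optionally network-coupled.

    Each variable is mean + sd * (rho * z + sqrt(1 - rho^2) * noise)
    where z is the participant's standardized true individual-path
    count; draws are clipped at zero (hormones cannot be negative) and
    % correct additionally at 100.
    """
    params = params or HormoneBehaviorParams()
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 0xC0DA])
    )
    ids = truth.participant_ids
    counts = np.array([len(truth.individual_paths[pid]) for pid in ids], float)
    std = counts.std()
    z = (counts - counts.mean()) / std if std > 0 else np.zeros_like(counts)

    values: dict[str, np.ndarray] = {}
    for var in ("estradiol", "progesterone", "testosterone", "pct_correct"):
        mean = getattr(params, f"{var}_mean")
        sd = getattr(params, f"{var}_sd")
        rho = float(params.coupling.get(var, 0.0))
        eps = rng.normal(0.0, 1.0, size=len(ids))
        v = mean + sd * (rho * z + math.sqrt(max(1.0 - rho**2, 0.0)) * eps)
        v = np.clip(v, 0.0, 100.0 if var == "pct_correct" else None)
        values[var] = v

    return tuple(
        MultimodalRecord(
            participant_id=pid,
            estradiol=float(values["estradiol"][k]),
            progesterone=float(values["progesterone"][k]),
            testosterone=float(values["testosterone"][k]),
            pct_correct=float(values["pct_correct"][k]),
        )
        for k, pid in enumerate(ids)
    )
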