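"""Shared fixtures: small ROI sets and simulated participants.

Everything is generated programmatically and seeded; no fixture files.
"""

from __future__ import annotations

import numpy as np
import pytest

from idionet import (
    DEFAULT_ROI_SET,
    NetworkStructure,
    ParticipantTimeSeries,
    RoiSet,
    build_lagged_sample,
)


@pytest.fixture(scope="session")
def rois3() -> RoiSet:
    return RoiSet(labels=("a", "b", "c"),
                  membership={"a": "MRN", "b": "MRN", "c": "DMN"})


@pytest.fixture(scope="session")
def rois2() -> RoiSet:
    return RoiSet(labels=("x", "y"), membership={"x": "MRN", "y": "DMN"})


@pytest.fixture(scope="session")
def rois4() -> RoiSet:
    return RoiSet(
        labels=("a", "b", "c", "d"),
        membership={"a": "MRN", "b": "MRN", "c": "DMN", "d": "DMN"},
    )


@pytest.fixture(scope="session")
def default_rois() -> RoiSet:
    return DEFAULT_ROI_SET


def simulate_var(rois: RoiSet, A: np.ndarray, Phi: np.ndarray,
                 psi: np.ndarray | float, T: int, seed: int,
                 n_runs: int = 1, burn: int = 100,
                 participant_id: str = "sub-01") -> ParticipantTimeSeries:
    """Direct simulator for tests: independent of the synth module.

    Draws eta_t = (I - A)^-1 (Phi eta_{t-1} + zeta_t) with diagonal
    Gaussian innovations; each run independently initialized.
    """
    p = len(rois)
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (p,))
    sd = np.sqrt(psi)
    B = np.linalg.inv(np.eye(p) - A)
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        eta = np.zeros(p)
        rows = np.empty((burn + T, p))
        for t in range(burn + T):
            eta = B @ (Phi @ eta + rng.normal(0.0, 1.0, p) * sd)
            rows[t] = eta
        runs.append(rows[burn:])
    return ParticipantTimeSeries(participant_id=participant_id, rois=rois,
                                 runs=tuple(runs))


@pytest.fixture(scope="session")
def ar_sample_2roi(rois2):
    """T=10000 sample from a 2-ROI system with only AR weights 0.5."""
    p = 2
    Phi = np.diag([0.5, 0.5])
    ts = simulate_var(rois2, np.zeros((p, p)), Phi, 1.0, T=10_000, seed=42)
    return ts, build_lagged_sample(ts)


@pytest.fixture(scope="session")
def planted_3roi(rois3):
    """3-ROI system with AR 0.4 plus one contemporaneous path b->c (0.6)."""
    p = 3
    A = np.zeros((p, p))
    A[2, 1] = 0.6  # target c, source b
    Phi = np.diag([0.4, 0.4, 0.4])
    ts = simulate_var(rois3, A, Phi, 1.0, T=2000, seed=7)
    return ts, build_lagged_sample(ts), A, Phi


def structure_from_matrices(rois: RoiSet, A: np.ndarray, Phi: np.ndarray,
                            include_ar: bool = True) -> NetworkStructure:
    """Structure freeing exactly the nonzero entries of (A, Phi)."""
    structure = NetworkStructure.null(rois, include_ar=include_ar)
    from idionet.paths import PathSpec

    for i, tgt in enumerate(rois.labels):
        for j, src in enumerate(rois.labels):
            if A[i, j] != 0:
                structure = structure.with_path(PathSpec(src, tgt, lag=0))
            if Phi[i, j] != 0 and not (i == j and include_ar):
                structure = structure.with_path(PathSpec(src, tgt, lag=1))
    return structure


def saturated_structure(rois: RoiSet) -> NetworkStructure:
    """A just-identified saturated model: df = 0 and exact fit.

    Frees a recursive (lower-triangular) contemporaneous ordering plus
    every lagged path: p(p-1)/2 + p^2 paths, exactly the number of
    conditional moments, so the implied covariance reproduces any
    sample covariance. Freeing *both* directions of every
    contemporaneous pair instead would exceed the moment count and
    lose identification.
    """
    from idionet.paths import PathSpec

    paths = []
    for i, tgt in enumerate(rois.labels):
        for j, src in enumerate(rois.labels):
            if i > j:
                paths.append(PathSpec(src, tgt, lag=0))
            paths.append(PathSpec(src, tgt, lag=1))
    return NetworkStructure(rois=rois, paths=tuple(paths))


def full_candidate_free_structure(rois: RoiSet) -> NetworkStructure:
    """Every admissible path present (no candidate left to free)."""
    from idionet.paths import PathSpec

    paths = []
    for src in rois.labels:
        for tgt in rois.labels:
            if src != tgt:
                paths.append(PathSpec(src, tgt, lag=0))
            paths.append(PathSpec(src, tgt, lag=1))
    return NetworkStructure(rois=rois, paths=tuple(paths))
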