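"""Lagged samples: turning multi-run ROI time series into moment matrices.

Estimation operates on the covariance of the 2p-dimensional *lagged
sample*: each row pairs a time point with its predecessor,
``[eta_{t-1}, eta_t]``. Pairs never span a run boundary — runs were
acquired separately and concatenated afterwards, so the last volume of
one run is not the predecessor of the first volume of the next. With
runs of length T_r the effective sample size is sum(T_r - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .rois import RoiSet


@dataclass(frozen=True)
class ParticipantTimeSeries:
    """One participant's ROI time series, one matrix per run.

    Each run is a (T_r, p) float array with columns in ``rois`` order.
    """

    participant_id: str
    rois: RoiSet
    runs: tuple[np.ndarray, ...]

    def __post_init__(self):
        if not self.runs:
            raise DataError(f"{self.participant_id}: no runs")
        p = len(self.rois)
        runs = []
        for k, run in enumerate(self.runs):
            arr = np.asarray(run, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != p:
                raise DataError(
                    f"{self.participant_id} run {k}: expected {p} columns, "
                    f"got shape {arr.shape}"
                )
            if arr.shape[0] < 2:
                raise DataError(
                    f"{self.participant_id} run {k}: needs at least 2 rows "
                    f"to form a lagged pair, got {arr.shape[0]}"
                )
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{self.participant_id} run {k}: non-finite values")
            runs.append(arr)
        object.__setattr__(self, "runs", tuple(runs))

    @property
    def run_lengths(self) -> tuple[int, ...]:
        return tuple(r.shape[0] for r in self.runs)

    def concatenated(self) -> np.ndarray:
        return np.vstack(self.runs)


@dataclass(frozen=True)
class LaggedSample:
    """Moment matrices of the pooled lagged sample for one participant.

    ``cov`` is the (2p, 2p) covariance (denominator n_eff - 1) of the
    mean-centered rows ``[eta_{t-1}, eta_t]`` pooled over runs. The
    conditional-moment blocks consumed by the estimator are cached:
    ``ghat`` is the least-squares predictor matrix S21 @ S11^-1 and
    ``s22_1`` the conditional covariance of eta_t given eta_{t-1}.
    """

    participant_id: str
    rois: RoiSet
    cov: np.ndarray
    n_eff: int
    s11: np.ndarray = field(repr=False)
    s22: np.ndarray = field(repr=False)
    ghat: np.ndarray = field(repr=False)
    s22_1: np.ndarray = field(repr=False)
    logdet_s22_1: float = field(repr=False)

    @property
    def p(self) -> int:
        return len(self.rois)

    @property
    def n_moments(self) -> int:
        """Unique moments of the 2p block: p(2p + 1)."""
        return self.p * (2 * self.p + 1)


def lagged_pairs(ts: ParticipantTimeSeries) -> tuple[np.ndarray, int]:
    """Pooled (n_eff, 2p) matrix of within-run ``[eta_{t-1}, eta_t]`` rows.

    A run of length T contributes T - 1 rows; no pair spans a run
    boundary. Not yet centered.
    """
    pairs = [np.hstack([run[:-1], run[1:]]) for run in ts.runs]
    Y = np.vstack(pairs)
    return Y, Y.shape[0]


def build_lagged_sample(ts: ParticipantTimeSeries) -> LaggedSample:
    """Pool within-run lagged pairs and compute their covariance.

    Columns of the pooled (n_eff, 2p) matrix are mean-centered over the
    concatenated sample before the covariance is taken, so means are
    not modeled. Run order does not affect the result beyond
    floating-point noise (the pairs are pooled, not ordered).
    """
    Y, n_eff = lagged_pairs(ts)
    if n_eff < 2:
        raise DataError(f"{ts.participant_id}: fewer than 2 lagged pairs")
    Y = Y - Y.mean(axis=0)
    S = (Y.T @ Y) / (n_eff - 1)
    p = len(ts.rois)
    # contiguous copies: these blocks feed the jitted kernel directly
    s11 = np.ascontiguousarray(S[:p, :p])
    s21 = np.ascontiguousarray(S[p:, :p])
    s22 = np.ascontiguousarray(S[p:, p:])
    try:
        ghat = np.ascontiguousarray(np.linalg.solve(s11, s21.T).T)
    except np.linalg.LinAlgError:
        raise DataError(
            f"{ts.participant_id}: singular predictor covariance "
            "(constant or collinear ROI series)"
        ) from None
    s22_1 = np.ascontiguousarray(s22 - ghat @ s21.T)
    sign, logdet = np.linalg.slogdet(s22_1)
    if sign <= 0:
        raise DataError(
            f"{ts.participant_id}: conditional covariance not positive definite"
        )
    return LaggedSample(
        participant_id=ts.participant_id,
        rois=ts.rois,
        cov=S,
        n_eff=n_eff,
        s11=s11,
        s22=s22,
        ghat=ghat,
        s22_1=s22_1,
        logdet_s22_1=float(logdet),
    )
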