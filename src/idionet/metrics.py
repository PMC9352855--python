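"""Network complexity and subnetwork-density metrics.

*Complexity* is the total number of estimated connections in a
person's network. Each non-AR connection is classified by its
endpoints' subnetworks — within-MRN, within-DMN, or between — and each
*density* is that count divided by complexity. Contemporaneous and
lagged connections count identically, and the two lags of the same
ROI pair are two connections (they are separate estimated parameters).

AR self-loops count toward complexity but toward none of the three
densities under the default rule, so the three densities sum to less
than one; the ``count_ar_in`` flag changes this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .paths import NetworkStructure, PersonNetwork
from .rois import MRN, RoiSet

#: where AR self-loops are counted
COUNT_AR_CHOICES = ("complexity", "densities", "neither")


@dataclass(frozen=True)
class NetworkMetrics:
    """Per-participant complexity, raw counts, and densities."""

    participant_id: str
    complexity: int
    n_within_mrn: int
    n_within_dmn: int
    n_between: int
    n_ar: int
    density_mrn: float
    density_dmn: float
    density_between: float
    degenerate: bool = False  # complexity 0; densities reported as 0


def compute_metrics(network: PersonNetwork | NetworkStructure, rois: RoiSet | None = None,
                    *, count_ar_in: str = "complexity") -> NetworkMetrics:
    """Reduce a fitted network (or bare structure) to its metrics.

    ``count_ar_in`` places AR self-loops in the complexity denominator
    only (default), in both the denominator and their own subnetwork's
    count (``"densities"``), or nowhere (``"neither"``).
    """
    if count_ar_in not in COUNT_AR_CHOICES:
        raise ConfigurationError(
            f"count_ar_in must be one of {COUNT_AR_CHOICES}, got {count_ar_in!r}"
        )
    if isinstance(network, PersonNetwork):
        structure = network.structure
        pid = network.participant_id
    else:
        structure = network
        pid = ""
    rois = rois or structure.rois
    for path in structure.paths:
        if path.source not in rois.labels or path.target not in rois.labels:
            raise DataError(f"unknown ROI label in path: {path}")

    n_mrn = n_dmn = n_between = n_ar = 0
    for path in structure.paths:
        if path.is_ar:
            n_ar += 1
            if count_ar_in != "densities":
                continue
        src_net = rois.network_of(path.source)
        tgt_net = rois.network_of(path.target)
        if src_net != tgt_net:
            n_between += 1
        elif src_net == MRN:
            n_mrn += 1
        else:
            n_dmn += 1

    complexity = n_mrn + n_dmn + n_between
    if count_ar_in == "complexity":
        complexity += n_ar
    degenerate = complexity == 0
    denom = complexity if complexity else 1
    return NetworkMetrics(
        participant_id=pid,
        complexity=complexity,
        n_within_mrn=n_mrn,
        n_within_dmn=n_dmn,
        n_between=n_between,
        n_ar=n_ar,
        density_mrn=n_mrn / denom,
        density_dmn=n_dmn / denom,
        density_between=n_between / denom,
        degenerate=degenerate,
    )


_METRIC_COLUMNS = (
    "complexity",
    "density_mrn",
    "density_dmn",
    "density_between",
)


def metrics_frame(metrics: Iterable[NetworkMetrics]) -> pd.DataFrame:
    """One row per participant, indexed by participant id."""
    rows = [m.__dict__ for m in metrics]
    df = pd.DataFrame(rows).set_index("participant_id")
    return df


def summarize_sample(metrics: Sequence[NetworkMetrics]) -> pd.DataFrame:
    """Sample mean and SD (n-1 denominator) of each metric."""
    if len(metrics) < 2:
        raise DataError("need at least 2 participants to summarize")
    df = metrics_frame(metrics)[list(_METRIC_COLUMNS)]
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    out.index.name = "metric"
    return out
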