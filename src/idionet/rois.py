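"""Region-of-interest sets and subnetwork membership.

The node set for every network in this package is a fixed, ordered
collection of ROI labels, each assigned to one of two subnetworks: a
putative mental rotations network (MRN) or the default mode network
(DMN). The default set has ten regions — six MRN (bilateral inferior
frontal gyrus, parietal, and superior parietal) and four DMN (medial
prefrontal cortex, posterior cingulate cortex, bilateral lateral
parietal). Coordinates are optional metadata; nothing in the modeling
uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError, DataError

MRN = "MRN"
DMN = "DMN"
_NETWORKS = (MRN, DMN)


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of ROI labels with MRN/DMN membership.

    Parameters
    ----------
    labels
        Unique ROI names; their order fixes the column order of every
        time-series matrix and coefficient matrix in the package.
    membership
        Map from label to ``"MRN"`` or ``"DMN"``.
    coordinates
        Optional map from label to an (x, y, z) triple in mm.
    """

    labels: tuple[str, ...]
    membership: Mapping[str, str]
    coordinates: Mapping[str, tuple[float, float, float]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("ROI labels must be unique")
        if len(self.labels) < 2:
            raise ConfigurationError("an RoiSet needs at least 2 ROIs")
        missing = [l for l in self.labels if l not in self.membership]
        if missing:
            raise ConfigurationError(f"ROIs without subnetwork membership: {missing}")
        bad = {l: n for l, n in self.membership.items() if n not in _NETWORKS}
        if bad:
            raise ConfigurationError(f"unknown subnetwork names: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise DataError(f"unknown ROI label: {label!r}") from None

    def network_of(self, label: str) -> str:
        try:
            return self.membership[label]
        except KeyError:
            raise DataError(f"unknown ROI label: {label!r}") from None

    @property
    def mrn_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.membership[l] == MRN)

    @property
    def dmn_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.membership[l] == DMN)

    @classmethod
    def from_table(cls, rows: Sequence[tuple[str, str]]) -> "RoiSet":
        """Build from (label, network) rows, e.g. a parsed membership CSV."""
        labels = tuple(r[0] for r in rows)
        membership = {r[0]: r[1] for r in rows}
        return cls(labels=labels, membership=membership)


#: Ten-ROI default node set: 6 MRN + 4 DMN, labels per standard
#: abbreviations (R/L = right/left hemisphere; IFG = inferior frontal
#: gyrus; Par = parietal; sPar = superior parietal; MPFC = medial
#: prefrontal cortex; PCC = posterior cingulate; LP = lateral parietal).
DEFAULT_ROI_SET = RoiSet(
    labels=(
        "R_IFG",
        "L_IFG",
        "R_Par",
        "L_Par",
        "R_sPar",
        "L_sPar",
        "MPFC",
        "PCC",
        "R_LP",
        "L_LP",
    ),
    membership={
        "R_IFG": MRN,
        "L_IFG": MRN,
        "R_Par": MRN,
        "L_Par": MRN,
        "R_sPar": MRN,
        "L_sPar": MRN,
        "MPFC": DMN,
        "PCC": DMN,
        "R_LP": DMN,
        "L_LP": DMN,
    },
)
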