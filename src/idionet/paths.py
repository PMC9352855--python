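"""Directed paths, network structures, and per-person estimates.

A *path* is a directed effect between two ROIs, either contemporaneous
(lag 0, within the same volume) or lagged (lag 1, from one volume to
the next). A lag-1 self-path is an autoregressive (AR) path. A
*network structure* is the set of paths whose coefficients a model
frees; everything else is fixed at zero. Structures carry no weights —
weights are estimated per person.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .errors import ConfigurationError
from .rois import RoiSet

GROUP = "group"
INDIVIDUAL = "individual"
_LEVELS = (GROUP, INDIVIDUAL)


@dataclass(frozen=True, order=True)
class PathSpec:
    """One directed path: ``source -> target`` at lag 0 or 1.

    ``level`` records whether the path was shared by the sample
    ("group") or unique to one person ("individual"); it does not enter
    path identity (a structure cannot contain the same edge twice at
    different levels).
    """

    source: str
    target: str
    lag: int
    level: str = GROUP

    def __post_init__(self):
        if self.lag not in (0, 1):
            raise ConfigurationError(f"lag must be 0 or 1, got {self.lag}")
        if self.level not in _LEVELS:
            raise ConfigurationError(f"level must be one of {_LEVELS}")
        if self.lag == 0 and self.source == self.target:
            raise ConfigurationError(
                f"contemporaneous self-path forbidden: {self.source}"
            )

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity of the edge, ignoring level: (lag, source, target)."""
        return (self.lag, self.source, self.target)

    @property
    def is_ar(self) -> bool:
        """True for a lag-1 self-path (autoregressive)."""
        return self.lag == 1 and self.source == self.target


def ar_paths(rois: RoiSet) -> tuple[PathSpec, ...]:
    """The p autoregressive paths (lag-1 self-paths) of a node set."""
    return tuple(PathSpec(l, l, lag=1, level=GROUP) for l in rois.labels)


@dataclass(frozen=True)
class NetworkStructure:
    """A set of freed directed paths over a fixed ROI set.

    With ``include_ar`` (the default) all p AR paths are present; they
    are part of the null model and are never subject to pruning.
    """

    rois: RoiSet
    paths: tuple[PathSpec, ...]
    include_ar: bool = True

    def __post_init__(self):
        keys = [p.key for p in self.paths]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ConfigurationError(f"duplicate paths: {dupes}")
        labels = set(self.rois.labels)
        for p in self.paths:
            if p.source not in labels or p.target not in labels:
                raise ConfigurationError(f"path references unknown ROI: {p}")
        if self.include_ar:
            have = {p.key for p in self.paths}
            missing = [l for l in self.rois.labels if (1, l, l) not in have]
            if missing:
                raise ConfigurationError(f"AR paths missing for: {missing}")
        # canonical order makes structures comparable and output stable
        object.__setattr__(self, "paths", tuple(sorted(self.paths, key=lambda p: p.key)))

    @classmethod
    def null(cls, rois: RoiSet, include_ar: bool = True) -> "NetworkStructure":
        """The null structure: AR paths only (or empty if not include_ar)."""
        return cls(rois=rois, paths=ar_paths(rois) if include_ar else (), include_ar=include_ar)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self) -> Iterator[PathSpec]:
        return iter(self.paths)

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, PathSpec) else tuple(item)
        return any(p.key == key for p in self.paths)

    def with_path(self, path: PathSpec) -> "NetworkStructure":
        if path in self:
            raise ConfigurationError(f"path already present: {path}")
        return replace(self, paths=self.paths + (path,))

    def without_path(self, path: PathSpec) -> "NetworkStructure":
        kept = tuple(p for p in self.paths if p.key != path.key)
        if len(kept) == len(self.paths):
            raise ConfigurationError(f"path not present: {path}")
        return replace(self, paths=kept)

    def with_levels_from(self, other: "NetworkStructure") -> "NetworkStructure":
        """Relabel paths also present in `other` with `other`'s levels."""
        levels = {p.key: p.level for p in other.paths}
        return replace(
            self,
            paths=tuple(
                replace(p, level=levels.get(p.key, p.level)) for p in self.paths
            ),
        )

    @property
    def non_ar_paths(self) -> tuple[PathSpec, ...]:
        return tuple(p for p in self.paths if not p.is_ar)

    def paths_at_level(self, level: str) -> tuple[PathSpec, ...]:
        return tuple(p for p in self.paths if p.level == level and not p.is_ar)

    def contains_structure(self, other: "NetworkStructure") -> bool:
        have = {p.key for p in self.paths}
        return all(p.key in have for p in other.paths)

    def to_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (p, p) masks (contemporaneous A, lagged Phi).

        Entry [i, j] frees the effect of ROI j on ROI i: row = target,
        column = source.
        """
        p = len(self.rois)
        a_mask = np.zeros((p, p), dtype=bool)
        phi_mask = np.zeros((p, p), dtype=bool)
        idx = {l: k for k, l in enumerate(self.rois.labels)}
        for path in self.paths:
            i, j = idx[path.target], idx[path.source]
            if path.lag == 0:
                a_mask[i, j] = True
            else:
                phi_mask[i, j] = True
        return a_mask, phi_mask

    def admissible_candidates(self) -> tuple[PathSpec, ...]:
        """All absent paths that could be freed.

        Excludes contemporaneous self-paths (inadmissible) and paths
        already present; includes lagged cross-paths and, when AR paths
        are excluded from the structure, lagged self-paths. Both
        directions of a pair are distinct candidates.
        """
        have = {p.key for p in self.paths}
        out = []
        for lag in (0, 1):
            for src in self.rois.labels:
                for tgt in self.rois.labels:
                    if lag == 0 and src == tgt:
                        continue
                    if (lag, src, tgt) in have:
                        continue
                    out.append(PathSpec(src, tgt, lag=lag, level=INDIVIDUAL))
        return tuple(out)


@dataclass(frozen=True)
class PathEstimate:
    """A fitted path: weight ``beta``, standard error, and z = beta/se."""

    path: PathSpec
    beta: float
    se: float
    z: float


@dataclass(frozen=True)
class FitIndices:
    """Chi-square and the standard descriptive fit indices.

    ``nnfi_undefined`` flags the df=0 case where the NNFI denominator
    collapses and the index is reported as 1 by convention. CFI is
    clamped to [0, 1]; NNFI is not clamped.
    """

    chi2: float
    df: float
    pvalue: float
    rmsea: float
    srmr: float
    cfi: float
    nnfi: float
    nnfi_undefined: bool = False

    def n_excellent(
        self,
        rmsea_cut: float = 0.05,
        srmr_cut: float = 0.05,
        cfi_cut: float = 0.95,
        nnfi_cut: float = 0.95,
    ) -> int:
        """How many of the four indices meet their 'excellent' cutoff."""
        return (
            int(self.rmsea <= rmsea_cut)
            + int(self.srmr <= srmr_cut)
            + int(self.cfi >= cfi_cut)
            + int(self.nnfi >= nnfi_cut)
        )


@dataclass(frozen=True)
class PersonNetwork:
    """One participant's fitted network: structure, estimates, fit."""

    participant_id: str
    structure: NetworkStructure
    estimates: tuple[PathEstimate, ...]
    fit: FitIndices

    def __post_init__(self):
        est_keys = sorted(e.path.key for e in self.estimates)
        struct_keys = sorted(p.key for p in self.structure.paths)
        if est_keys != struct_keys:
            raise ConfigurationError(
                "estimates must cover exactly the paths in the structure"
            )

    def estimate_for(self, path: PathSpec) -> PathEstimate:
        for e in self.estimates:
            if e.path.key == path.key:
                return e
        raise KeyError(path)

    @property
    def complexity(self) -> int:
        """Total number of estimated connections (AR included)."""
        return len(self.structure)
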