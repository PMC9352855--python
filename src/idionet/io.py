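"""Plain-text readers and writers for every artifact the pipeline touches.

All formats are delimited text so outputs diff cleanly and reruns can
be compared byte-for-byte:

- time series: one CSV per run, ``<participant>_run-<k>.csv``, header
  row of ROI labels, rows = volumes;
- ROI membership: ``rois.csv`` with columns label, network;
- truth: edge list ``truth_edges.csv`` (participant, source, target,
  lag, level, weight) plus a JSON sidecar with seed and settings;
- fitted networks: edge list with beta/se/z; fit indices one row per
  participant; metrics, summaries, and correlation matrices as CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .metrics import NetworkMetrics, metrics_frame
from .multimodal import CorrelationMatrix, MultimodalRecord
from .paths import NetworkStructure, PathSpec, PersonNetwork
from .rois import RoiSet
from .sample import ParticipantTimeSeries
from .synth import SyntheticTruth

_FLOAT_FMT = "%.17g"  # exact binary round-trip through text


# ---------------------------------------------------------------------------
# ROI sets

def write_roiset(rois: RoiSet, path: Path | str) -> None:
    rows = {"label": list(rois.labels),
            "network": [rois.membership[l] for l in rois.labels]}
    if rois.coordinates:
        for k, axis in enumerate(("x", "y", "z")):
            rows[axis] = [rois.coordinates.get(l, (np.nan,) * 3)[k]
                          for l in rois.labels]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_roiset(path: Path | str) -> RoiSet:
    df = pd.read_csv(path)
    for col in ("label", "network"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = {r.label: (r.x, r.y, r.z) for r in df.itertuples()}
    return RoiSet(labels=tuple(df["label"]),
                  membership=dict(zip(df["label"], df["network"])),
                  coordinates=coords)


# ---------------------------------------------------------------------------
# time series

def write_timeseries(ts: Iterable[ParticipantTimeSeries], outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for one in ts:
        for k, run in enumerate(one.runs):
            df = pd.DataFrame(run, columns=list(one.rois.labels))
            df.to_csv(outdir / f"{one.participant_id}_run-{k + 1:02d}.csv",
                      index=False, float_format=_FLOAT_FMT)


def read_timeseries_dir(indir: Path | str, rois: RoiSet,
                        ) -> tuple[ParticipantTimeSeries, ...]:
    """Load every ``*_run-*.csv`` under ``indir``, grouped by participant.

    Headers must match the ROI set exactly (same labels, any order is
    rejected to avoid silent column permutation); ragged or non-numeric
    rows produce an error naming the file and line.
    """
    indir = Path(indir)
    files = sorted(indir.glob("*_run-*.csv"))
    if not files:
        raise DataError(f"no time-series files found under {indir}")
    by_pid: dict[str, list[tuple[int, np.ndarray]]] = {}
    for f in files:
        stem = f.stem
        pid, _, run_part = stem.rpartition("_run-")
        if not pid:
            raise DataError(f"{f}: cannot parse participant/run from name")
        arr = _read_numeric_csv(f, rois)
        by_pid.setdefault(pid, []).append((int(run_part), arr))
    out = []
    for pid in sorted(by_pid):
        runs = tuple(arr for _, arr in sorted(by_pid[pid], key=lambda x: x[0]))
        out.append(ParticipantTimeSeries(participant_id=pid, rois=rois, runs=runs))
    return tuple(out)


def _read_numeric_csv(path: Path, rois: RoiSet) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        unknown = [c for c in header if c not in rois.labels]
        if unknown:
            raise DataError(f"{path}: unknown ROI column(s) {unknown}")
        if tuple(header) != rois.labels:
            raise DataError(
                f"{path}: header {header} does not match the ROI set order "
                f"{list(rois.labels)}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(rois.labels):
                raise DataError(
                    f"{path}: line {lineno}: expected {len(rois.labels)} "
                    f"cells, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# truth

def write_truth(truth: SyntheticTruth, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in truth.participant_ids:
        struct = truth.structure_for(pid)
        for path in struct.paths:
            rows.append({
                "participant": pid,
                "source": path.source,
                "target": path.target,
                "lag": path.lag,
                "level": "ar" if path.is_ar else path.level,
                "weight": truth.weight_of(pid, path),
            })
    pd.DataFrame(rows).to_csv(outdir / "truth_edges.csv", index=False,
                              float_format=_FLOAT_FMT)
    config = dataclasses.asdict(truth.config)
    config["rois"] = {"labels": list(truth.config.rois.labels),
                      "membership": dict(truth.config.rois.membership)}
    sidecar = {"seed": truth.seed, "config": config,
               "participant_ids": list(truth.participant_ids)}
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2,
                                                  default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# covariates

def write_covariates(records: Sequence[MultimodalRecord], path: Path | str) -> None:
    rows = [{"participant": r.participant_id, "estradiol": r.estradiol,
             "progesterone": r.progesterone, "testosterone": r.testosterone,
             "pct_correct": r.pct_correct} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_covariates(path: Path | str) -> tuple[MultimodalRecord, ...]:
    df = pd.read_csv(path)
    needed = {"participant", "estradiol", "progesterone", "testosterone",
              "pct_correct"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return tuple(
        MultimodalRecord(participant_id=str(r.participant),
                         estradiol=r.estradiol, progesterone=r.progesterone,
                         testosterone=r.testosterone, pct_correct=r.pct_correct)
        for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# fitted networks

def networks_to_edge_frame(networks: Sequence[PersonNetwork]) -> pd.DataFrame:
    rows = []
    for net in networks:
        for est in sorted(net.estimates, key=lambda e: e.path.key):
            path = est.path
            rows.append({
                "participant": net.participant_id,
                "source": path.source,
                "target": path.target,
                "lag": path.lag,
                "level": "ar" if path.is_ar else path.level,
                "beta": est.beta,
                "se": est.se,
                "z": est.z,
            })
    return pd.DataFrame(rows)


def write_networks(networks: Sequence[PersonNetwork], path: Path | str) -> None:
    networks_to_edge_frame(networks).to_csv(path, index=False,
                                            float_format=_FLOAT_FMT)


def write_group_structure(structure: NetworkStructure, path: Path | str) -> None:
    rows = [{"source": p.source, "target": p.target, "lag": p.lag,
             "level": "ar" if p.is_ar else p.level}
            for p in structure.paths]
    pd.DataFrame(rows).to_csv(path, index=False)


def fit_indices_frame(networks: Sequence[PersonNetwork]) -> pd.DataFrame:
    rows = [{"participant": n.participant_id, "chi2": n.fit.chi2,
             "df": n.fit.df, "pvalue": n.fit.pvalue, "rmsea": n.fit.rmsea,
             "srmr": n.fit.srmr, "cfi": n.fit.cfi, "nnfi": n.fit.nnfi}
            for n in networks]
    return pd.DataFrame(rows)


def write_fit_indices(networks: Sequence[PersonNetwork], path: Path | str) -> None:
    fit_indices_frame(networks).to_csv(path, index=False,
                                       float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# metrics and correlations

def write_metrics(metrics: Sequence[NetworkMetrics], path: Path | str) -> None:
    metrics_frame(metrics).to_csv(path, float_format=_FLOAT_FMT)


def write_summary(summary: pd.DataFrame, path: Path | str) -> None:
    summary.to_csv(path, float_format=_FLOAT_FMT)


def write_correlations(matrix: CorrelationMatrix, r_path: Path | str,
                       n_path: Path | str | None = None) -> None:
    matrix.r.to_csv(r_path, float_format=_FLOAT_FMT)
    if n_path is not None:
        matrix.n.to_csv(n_path)
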