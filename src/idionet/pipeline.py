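"""End-to-end orchestration: simulate/load -> search -> metrics -> correlate.

A single validated :class:`PipelineConfig` drives every stage; one
master seed propagates to all stochastic stages, and a manifest
(config hash, seed, package versions, per-stage timings) is written
next to the outputs so deterministic stages can be reproduced
bit-identically from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io as _io
from .errors import ConfigurationError, DataError
from .metrics import COUNT_AR_CHOICES, compute_metrics, summarize_sample
from .multimodal import (
    MultimodalRecord,
    correlate_multimodal,
    describe_sample,
    plot_correlation_heatmap,
)
from .paths import PersonNetwork
from .rois import DEFAULT_ROI_SET, RoiSet
from .sample import ParticipantTimeSeries, build_lagged_sample
from .search import SearchConfig, SearchResult, run_sample_search
from .synth import (
    HormoneBehaviorParams,
    SynthConfig,
    SyntheticTruth,
    generate_covariates,
    generate_truth,
    simulate_timeseries,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; validated before any computation."""

    seed: int = 0
    outdir: str = "results/pipeline"
    source: str = "simulate"             # "simulate" | "load"
    input_dir: str | None = None         # for source="load"
    synth: SynthConfig = field(default_factory=SynthConfig)
    hormones: HormoneBehaviorParams = field(default_factory=HormoneBehaviorParams)
    search: SearchConfig = field(default_factory=SearchConfig)
    count_ar_in: str = "complexity"
    correlation_method: str = "pearson"
    write_heatmap: bool = False

    def __post_init__(self):
        if self.source not in ("simulate", "load"):
            raise ConfigurationError("source must be 'simulate' or 'load'")
        if self.source == "load" and not self.input_dir:
            raise ConfigurationError("source='load' requires input_dir")
        if self.count_ar_in not in COUNT_AR_CHOICES:
            raise ConfigurationError(f"count_ar_in must be one of {COUNT_AR_CHOICES}")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigurationError("correlation_method must be pearson|spearman")
        if not (0 <= self.seed < 2**31):
            raise ConfigurationError("seed must be in [0, 2^31)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw["synth"] = _synth_from_dict(raw["synth"])
        if "hormones" in raw and isinstance(raw["hormones"], dict):
            raw["hormones"] = _build(HormoneBehaviorParams, raw["hormones"])
        if "search" in raw and isinstance(raw["search"], dict):
            raw["search"] = _build(SearchConfig, raw["search"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d["synth"]["rois"] = {
            "labels": list(self.synth.rois.labels),
            "membership": dict(self.synth.rois.membership),
        }
        return json.dumps(d, sort_keys=True, default=_io._jsonable)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


def _build(cls, raw: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def _synth_from_dict(raw: dict) -> SynthConfig:
    raw = dict(raw)
    rois = raw.pop("rois", None)
    if isinstance(rois, dict):
        raw["rois"] = RoiSet(labels=tuple(rois["labels"]),
                             membership=dict(rois["membership"]))
    elif rois is not None:
        raw["rois"] = rois
    return _build(SynthConfig, raw)


@dataclass
class Dataset:
    """Loaded or simulated study data, ready for the search."""

    rois: RoiSet
    timeseries: tuple[ParticipantTimeSeries, ...]
    covariates: tuple[MultimodalRecord, ...] | None = None
    truth: SyntheticTruth | None = None

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(ts.participant_id for ts in self.timeseries)


def simulate_dataset(config: PipelineConfig) -> Dataset:
    truth = generate_truth(config.synth, seed=config.seed)
    ts = simulate_timeseries(truth)
    cov = generate_covariates(truth, config.hormones)
    return Dataset(rois=config.synth.rois, timeseries=ts, covariates=cov,
                   truth=truth)


def load_dataset(config: PipelineConfig) -> Dataset:
    """Load (or simulate) the dataset named by the config.

    For ``source="load"``: reads the ROI table, all time-series runs,
    and covariates if present. Participants missing covariates are
    flagged with a warning but never dropped.
    """
    if config.source == "simulate":
        return simulate_dataset(config)
    indir = Path(config.input_dir)
    if not indir.exists():
        raise DataError(f"input_dir does not exist: {indir}")
    rois = _io.read_roiset(indir / "rois.csv")
    ts = _io.read_timeseries_dir(indir / "timeseries", rois)
    cov = None
    cov_path = indir / "covariates.csv"
    if cov_path.exists():
        cov = _io.read_covariates(cov_path)
        have = {c.participant_id for c in cov}
        missing = [t.participant_id for t in ts if t.participant_id not in have]
        if missing:
            warnings.warn(
                f"participants missing covariates (kept in network stages): "
                f"{missing}",
                RuntimeWarning, stacklevel=2,
            )
    return Dataset(rois=rois, timeseries=ts, covariates=cov)


def write_dataset(dataset: Dataset, outdir: Path | str) -> None:
    """Write a dataset in exactly the layout ``load_dataset`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_roiset(dataset.rois, outdir / "rois.csv")
    _io.write_timeseries(dataset.timeseries, outdir / "timeseries")
    if dataset.covariates is not None:
        _io.write_covariates(dataset.covariates, outdir / "covariates.csv")
    if dataset.truth is not None:
        _io.write_truth(dataset.truth, outdir)


@dataclass
class PipelineResult:
    """Outputs of one full run (also written to disk under outdir)."""

    dataset: Dataset
    search: SearchResult
    metrics: list
    summary: object
    descriptives: object | None
    correlations: object | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/load -> search -> metrics -> correlate and write it all."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    dataset = load_dataset(config)
    if config.source == "simulate":
        write_dataset(dataset, outdir / "dataset")
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    samples = [build_lagged_sample(ts) for ts in dataset.timeseries]
    result = run_sample_search(samples, config.search)
    timings["search"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics = [compute_metrics(net, dataset.rois, count_ar_in=config.count_ar_in)
               for net in result.networks]
    summary = summarize_sample(metrics)
    timings["metrics"] = time.perf_counter() - t0

    descriptives = None
    correlations = None
    t0 = time.perf_counter()
    if dataset.covariates:
        descriptives = describe_sample(dataset.covariates)
        have = {c.participant_id for c in dataset.covariates}
        joint_metrics = [m for m in metrics if m.participant_id in have]
        if len(joint_metrics) >= 3:
            correlations = correlate_multimodal(
                dataset.covariates, joint_metrics,
                method=config.correlation_method,
            )
    timings["correlate"] = time.perf_counter() - t0

    _io.write_group_structure(result.group_structure, outdir / "group_structure.csv")
    _io.write_networks(result.networks, outdir / "person_networks.csv")
    _io.write_fit_indices(result.networks, outdir / "fit_indices.csv")
    _io.write_metrics(metrics, outdir / "metrics.csv")
    _io.write_summary(summary, outdir / "metrics_summary.csv")
    trace = {
        "group": result.group_trace.to_records(),
        "individual": {pid: tr.to_records()
                       for pid, tr in result.individual_traces.items()},
    }
    (outdir / "search_trace.json").write_text(json.dumps(trace, indent=2) + "\n")
    if descriptives is not None:
        _io.write_summary(descriptives, outdir / "covariate_descriptives.csv")
    if correlations is not None:
        _io.write_correlations(correlations, outdir / "correlations.csv",
                               outdir / "correlation_n.csv")
        if config.write_heatmap:
            plot_correlation_heatmap(correlations, outdir / "correlations.png")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_participants": len(dataset.timeseries),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(dataset=dataset, search=result, metrics=metrics,
                          summary=summary, descriptives=descriptives,
                          correlations=correlations, manifest=manifest)


def _versions() -> dict[str, str]:
    import numba
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "idionet": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "numba": numba.__version__,
    }
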