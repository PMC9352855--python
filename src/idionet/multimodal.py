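"""Joining network metrics with hormone and behavior measures.

Hormone levels (estradiol, progesterone, testosterone, in pg/mL) and
in-scanner task performance (% correct) are joined to each
participant's network metrics, summarized as means/SDs, and related by
a pairwise Pearson correlation matrix. With samples of ~11 the matrix
is descriptive; p-values are optional and exploratory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .metrics import NetworkMetrics, metrics_frame

HORMONE_VARS = ("estradiol", "progesterone", "testosterone")
BEHAVIOR_VARS = ("pct_correct",)
NETWORK_VARS = ("complexity", "density_mrn", "density_dmn", "density_between")
ALL_VARS = BEHAVIOR_VARS + HORMONE_VARS + NETWORK_VARS


@dataclass(frozen=True)
class MultimodalRecord:
    """One participant's hormone levels (pg/mL) and task performance."""

    participant_id: str
    estradiol: float
    progesterone: float
    testosterone: float
    pct_correct: float

    def __post_init__(self):
        for name in HORMONE_VARS:
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise DataError(f"{name} must be nonnegative, got {v}")
        v = self.pct_correct
        if np.isfinite(v) and not (0.0 <= v <= 100.0):
            raise DataError(f"pct_correct must be in [0, 100], got {v}")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise correlations with the per-cell number of complete pairs."""

    r: pd.DataFrame
    n: pd.DataFrame

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.r.columns)


def records_frame(records: Sequence[MultimodalRecord]) -> pd.DataFrame:
    rows = [r.__dict__ for r in records]
    return pd.DataFrame(rows).set_index("participant_id")


def describe_sample(records: Sequence[MultimodalRecord]) -> pd.DataFrame:
    """Mean and sample SD (n-1) of each hormone/behavior variable."""
    if len(records) < 2:
        raise DataError("need at least 2 records to describe")
    df = records_frame(records)
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    out.index.name = "variable"
    return out


def correlate_multimodal(records: Sequence[MultimodalRecord],
                         metrics: Sequence[NetworkMetrics], *,
                         method: str = "pearson") -> CorrelationMatrix:
    """Correlate behavior, hormones, and network metrics pairwise.

    The join on participant id must be total. Missing values are
    handled pairwise-complete, with the per-cell n recorded. A
    zero-variance variable yields missing coefficients and a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError("method must be 'pearson' or 'spearman'")
    rec_df = records_frame(records)
    met_df = metrics_frame(metrics)[list(NETWORK_VARS)]
    missing = set(rec_df.index).symmetric_difference(met_df.index)
    if missing:
        raise DataError(
            f"records and metrics must cover the same participants; "
            f"unmatched: {sorted(missing)}"
        )
    joined = rec_df.join(met_df, how="inner")[list(ALL_VARS)]
    if len(joined) < 3:
        raise DataError("need at least 3 joined rows to correlate")

    zero_var = [c for c in joined.columns
                if joined[c].notna().sum() > 1 and
                np.nanstd(joined[c].to_numpy(dtype=float)) == 0.0]
    if zero_var:
        warnings.warn(
            f"zero-variance variables, correlations undefined: {zero_var}",
            RuntimeWarning, stacklevel=2,
        )

    r = joined.corr(method=method, min_periods=2)
    for c in zero_var:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
    np.fill_diagonal(r.values, 1.0)

    notna = joined.notna().astype(int)
    n = pd.DataFrame(notna.T.values @ notna.values,
                     index=joined.columns, columns=joined.columns)
    return CorrelationMatrix(r=r, n=n)


def correlation_pvalues(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Exploratory two-sided p-values for each cell (t reference).

    Labeled exploratory deliberately: at n ~ 11 these have little
    inferential value and the matrix is meant descriptively.
    """
    from scipy import stats

    r = matrix.r.to_numpy(dtype=float)
    n = matrix.n.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p[~np.isfinite(t)] = np.nan
    np.fill_diagonal(p, np.nan)
    return pd.DataFrame(p, index=matrix.r.index, columns=matrix.r.columns)


def plot_correlation_heatmap(matrix: CorrelationMatrix, path=None):
    """Red-blue heatmap of the correlation matrix; saves if given a path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.r.to_numpy(dtype=float), vmin=-1, vmax=1,
                   cmap="RdBu")
    ax.set_xticks(range(len(matrix.labels)))
    ax.set_xticklabels(matrix.labels, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.labels)))
    ax.set_yticklabels(matrix.labels)
    fig.colorbar(im, ax=ax, label="r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
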