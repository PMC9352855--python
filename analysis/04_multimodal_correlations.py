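#!/usr/bin/env python
"""Relate network metrics to hormones and task performance.

Joins the metrics from 03_network_metrics.py with the hormone
(estradiol, progesterone, testosterone; pg/mL) and behavior (% correct)
covariates, prints the descriptives and the pairwise Pearson matrix,
and saves a red-blue heatmap. With n = 11 the matrix is descriptive;
no significance testing is attached.
"""

import argparse
from pathlib import Path

import pandas as pd

from idionet import correlate_multimodal, describe_sample
from idionet.io import read_covariates, write_correlations
from idionet.metrics import NetworkMetrics
from idionet.multimodal import plot_correlation_heatmap


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--run", default="results/run")
    ap.add_argument("--dataset", default="results/dataset")
    args = ap.parse_args()

    records = read_covariates(Path(args.dataset) / "covariates.csv")
    mdf = pd.read_csv(Path(args.run) / "metrics.csv")
    metrics = [
        NetworkMetrics(
            participant_id=str(r.participant_id), complexity=int(r.complexity),
            n_within_mrn=int(r.n_within_mrn), n_within_dmn=int(r.n_within_dmn),
            n_between=int(r.n_between), n_ar=int(r.n_ar),
            density_mrn=r.density_mrn, density_dmn=r.density_dmn,
            density_between=r.density_between,
        )
        for r in mdf.itertuples()
    ]

    print("covariate descriptives:")
    with pd.option_context("display.float_format", "{:.2f}".format):
        print(describe_sample(records))

    matrix = correlate_multimodal(records, metrics)
    write_correlations(matrix, Path(args.run) / "correlations.csv",
                       Path(args.run) / "correlation_n.csv")
    plot_correlation_heatmap(matrix, Path(args.run) / "correlations.png")
    print("\npairwise Pearson correlations:")
    with pd.option_context("display.float_format", "{:+.2f}".format):
        print(matrix.r)
    r = matrix.r
    print("\nkey cells: performance-complexity r = "
          f"{r.loc['pct_correct', 'complexity']:+.2f}; "
          "performance-MRN density r = "
          f"{r.loc['pct_correct', 'density_mrn']:+.2f}")


if __name__ == "__main__":
    main()
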