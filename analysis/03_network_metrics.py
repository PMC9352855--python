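#!/usr/bin/env python
"""Reduce the fitted networks to complexity and subnetwork densities.

Reads the person networks written by 02_search_networks.py and prints
the sample summary (mean/SD per metric) in the descriptive-table
layout: total complexity, then the three densities as proportions of
complexity.
"""

import argparse
from pathlib import Path

import pandas as pd

from idionet import compute_metrics, summarize_sample
from idionet.io import read_roiset, write_metrics, write_summary
from idionet.metrics import metrics_frame
from idionet.paths import GROUP, INDIVIDUAL, NetworkStructure, PathSpec


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--run", default="results/run")
    ap.add_argument("--dataset", default="results/dataset")
    args = ap.parse_args()

    rois = read_roiset(Path(args.dataset) / "rois.csv")
    edges = pd.read_csv(Path(args.run) / "person_networks.csv")
    metrics = []
    for pid, grp in edges.groupby("participant", sort=True):
        paths = tuple(
            PathSpec(r.source, r.target, lag=int(r.lag),
                     level=GROUP if r.level in ("group", "ar") else INDIVIDUAL)
            for r in grp.itertuples()
        )
        structure = NetworkStructure(rois=rois, paths=paths)
        m = compute_metrics(structure, rois)
        metrics.append(type(m)(**{**m.__dict__, "participant_id": str(pid)}))

    summary = summarize_sample(metrics)
    write_metrics(metrics, Path(args.run) / "metrics.csv")
    write_summary(summary, Path(args.run) / "metrics_summary.csv")
    print("per-participant metrics -> metrics.csv; summary:")
    with pd.option_context("display.float_format", "{:.3f}".format):
        print(summary)
    df = metrics_frame(metrics)
    print("\ncheck: densities are proportions of complexity; AR loops "
          f"(always {df['n_ar'].iloc[0]}) count toward complexity only")


if __name__ == "__main__":
    main()
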