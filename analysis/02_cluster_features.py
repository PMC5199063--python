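#!/usr/bin/env python
"""Stage 2: redundancy reduction by Spearman/UPGMA hierarchical clustering.

Builds the feature tree from results/features.csv, writes the tree
(newick), the threshold-vs-cluster-count curve and the grouping at the
working threshold (0.35), and prints the cluster counts at the candidate
thresholds 0.15 / 0.35 / 0.65.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from qifagree import build_cluster_tree, cut_tree, read_feature_table, threshold_curve

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path, default=RESULTS / "features.csv")
    parser.add_argument("--threshold", type=float, default=0.35)
    parser.add_argument("--distance-mode", default="signed", choices=["signed", "absolute"])
    parser.add_argument("--outdir", type=Path, default=RESULTS / "clustering")
    args = parser.parse_args()

    table = read_feature_table(args.features)
    tree = build_cluster_tree(table, distance_mode=args.distance_mode)
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "tree.newick").write_text(tree.to_newick() + "\n")

    grid = np.round(np.arange(0.0, min(tree.root_height, 2.0) + 0.025, 0.025), 4)
    curve = threshold_curve(tree, grid)
    pd.DataFrame(curve, columns=["threshold", "n_clusters"]).to_csv(
        args.outdir / "threshold_curve.csv", index=False
    )
    grouping = cut_tree(tree, args.threshold)
    grouping.to_frame().to_csv(args.outdir / "grouping.csv", index=False)

    if tree.dropped_features:
        print(f"dropped constant features: {tree.dropped_features}")
    for t in (0.15, args.threshold, 0.65):
        n = cut_tree(tree, t).n_groups + len(tree.dropped_features)
        print(f"threshold {t:.2f}: {n} non-redundant clusters")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
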