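#!/usr/bin/env python
"""Stage 3: group-averaged concordance across the 15 inter-setting comparisons.

Computes per-feature Lin CCCs over tumors for every pair of settings,
averages them within the non-redundant groups from stage 2, writes the
group x comparison matrix with category annotations plus the summary
tables, and renders a heatmap with rows and columns ordered by descending
average CCC.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from qifagree import read_feature_table
from qifagree.pipeline import run_agreement_analysis

RESULTS = Path(__file__).resolve().parents[1] / "results"

CATEGORY_COLORS = {"a": "#2ca02c", "b": "#ff7f0e", "c": "#1f77b4", "d": "#9467bd"}


def plot_heatmap(analysis, path: Path) -> None:
    df = analysis.group_matrix.df
    col_order = analysis.summaries["per_pair"].index
    row_order = analysis.summaries["per_group"].index
    ordered = df.loc[row_order, col_order]
    cats = analysis.group_matrix.categories

    fig, ax = plt.subplots(figsize=(9, 0.35 * len(ordered) + 2))
    im = ax.imshow(ordered.to_numpy(), vmin=-1, vmax=1, cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(len(col_order)))
    ax.set_xticklabels(
        [c.replace("_vs_", " vs ") for c in col_order], rotation=60, ha="right", fontsize=7
    )
    for tick, col in zip(ax.get_xticklabels(), col_order):
        tick.set_color(CATEGORY_COLORS[cats[col]])
    ax.set_yticks(range(len(row_order)))
    ax.set_yticklabels(row_order, fontsize=7)
    fig.colorbar(im, ax=ax, label="group-averaged CCC")
    ax.set_title("Inter-setting agreement of non-redundant feature groups")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path, default=RESULTS / "features.csv")
    parser.add_argument("--threshold", type=float, default=0.35)
    parser.add_argument("--outdir", type=Path, default=RESULTS / "agreement")
    args = parser.parse_args()

    table = read_feature_table(args.features)
    analysis = run_agreement_analysis(table, threshold=args.threshold)
    analysis.write(args.outdir)
    plot_heatmap(analysis, args.outdir / "heatmap.png")

    cat = analysis.summaries["category_means"]["mean_ccc"]
    order = " > ".join(cat.sort_values(ascending=False).index)
    print(f"{analysis.grouping.n_groups} groups at threshold {args.threshold}")
    print("category mean CCCs:")
    for c in "abcd":
        print(f"  {c}: {cat[c]:+.3f}")
    print(f"category ordering: {order}")
    pp = analysis.summaries["per_pair"]["mean_ccc"]
    print(f"best comparison:  {pp.index[0]} ({pp.iloc[0]:.3f})")
    print(f"worst comparison: {pp.index[-1]} ({pp.iloc[-1]:.3f})")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
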