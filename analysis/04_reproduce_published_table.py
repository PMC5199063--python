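#!/usr/bin/env python
"""Stage 4: run clustering + agreement on the published per-tumor feature table.

The original study deposited the numeric values of its 89 features for the
32 lung tumors at all six settings as a supplementary workbook.  Export
that workbook to long-layout CSV (columns tumor,setting,feature,value) as
data/s1_feature_export.csv and this stage reruns redundancy reduction and
the CCC analysis on the in-vivo values, reporting the cluster counts at
thresholds 0.15 and 0.35 and the per-category agreement summary.

If exact cluster counts disagree with the published 41/23, rerun with
--distance-mode absolute (whether anticorrelated features were merged is
the one undocumented convention this reconstruction is sensitive to).
"""

import argparse
import sys
from pathlib import Path

from qifagree import ingest_s1
from qifagree.pipeline import run_agreement_analysis
from qifagree.redundancy import cut_tree

REPO = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--s1", type=Path, default=REPO / "data" / "s1_feature_export.csv")
    parser.add_argument("--distance-mode", default="signed", choices=["signed", "absolute"])
    parser.add_argument("--outdir", type=Path, default=REPO / "results" / "s1_reproduction")
    args = parser.parse_args()

    if not args.s1.exists():
        print(
            f"published feature export not found at {args.s1}.\n"
            "Export the supplementary per-tumor feature workbook to "
            "long-layout CSV (tumor,setting,feature,value) and place it "
            "there, then rerun this stage.",
            file=sys.stderr,
        )
        return 2

    table = ingest_s1(args.s1)
    analysis = run_agreement_analysis(table, threshold=0.35, distance_mode=args.distance_mode)
    analysis.write(args.outdir)
    for t in (0.15, 0.35):
        n = cut_tree(analysis.tree, t).n_groups + len(analysis.tree.dropped_features)
        print(f"threshold {t:.2f}: {n} clusters")
    cat = analysis.summaries["category_means"]["mean_ccc"]
    print("category mean CCCs:", {c: round(cat[c], 3) for c in "abcd"})
    pg = analysis.summaries["per_group"]["mean_ccc"]
    print(f"poorest group: {pg.index[-1]} ({pg.iloc[-1]:.3f})")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
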