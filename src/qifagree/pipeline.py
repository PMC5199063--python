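"""End-to-end stages: simulate -> extract -> cluster -> agreement.

These functions are the single implementation behind the analysis scripts,
the CLI and the acceptance script, so every route through the package
computes the same numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementMatrix,
    enumerate_comparisons,
    feature_ccc_matrix,
    group_average_ccc,
    summarize,
)
from .phantoms import (
    AcquisitionSetting,
    CohortConfig,
    CohortItem,
    SimulationParams,
    default_settings,
    generate_cohort,
)
from .preprocess import ResampleSpec, resample_isotropic, resample_mask
from .qif import FeatureRegistry, TextureParams, default_registry, extract_all
from .redundancy import (
    ClusterTree,
    FeatureGrouping,
    build_cluster_tree,
    collapse_groups,
    cut_tree,
    threshold_curve,
)
from .volio import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "extract_item_features",
    "extract_cohort_features",
    "cohort_feature_table",
    "AgreementAnalysis",
    "run_agreement_analysis",
    "write_provenance",
]


def extract_item_features(
    item: CohortItem,
    registry: FeatureRegistry | None = None,
    params: TextureParams = TextureParams(),
    resample: ResampleSpec = ResampleSpec(),
) -> dict[str, float]:
    """Resample one rendered lesion to the isotropic grid and extract features."""
    vol = resample_isotropic(item.volume, resample)
    msk = resample_mask(item.mask, resample)
    return extract_all(
        vol, msk, registry=registry, params=params,
        expected_spacing_mm=resample.target_spacing_mm,
    )


def extract_cohort_features(
    cohort: Iterable[CohortItem],
    registry: FeatureRegistry | None = None,
    params: TextureParams = TextureParams(),
    resample: ResampleSpec = ResampleSpec(),
) -> FeatureTable:
    """Feature table over a cohort of rendered (tumor, setting) items."""
    if registry is None:
        registry = default_registry(params)
    records = []
    for item in cohort:
        values = extract_item_features(item, registry, params, resample)
        label = item.setting.label
        for name in registry.names:
            records.append((item.tumor_id, label, name, values[name]))
        logger.info("extracted %s at %s", item.tumor_id, label)
    return FeatureTable.from_records(records)


def cohort_feature_table(
    n_lesions: int = 32,
    seed: int = 0,
    settings: Sequence[AcquisitionSetting] | None = None,
    config: CohortConfig = CohortConfig(),
    sim_params: SimulationParams = SimulationParams(),
    texture_params: TextureParams = TextureParams(),
) -> FeatureTable:
    """Simulate a cohort and extract the default 89-feature table."""
    if settings is None:
        settings = default_settings()
    cohort = generate_cohort(n_lesions, settings, seed=seed, config=config, params=sim_params)
    return extract_cohort_features(cohort, params=texture_params)


@dataclass
class AgreementAnalysis:
    """All outputs of the cluster + agreement stage."""

    tree: ClusterTree
    curve: list[tuple[float, int]]
    grouping: FeatureGrouping
    feature_matrix: AgreementMatrix
    group_matrix: AgreementMatrix
    summaries: dict[str, pd.DataFrame]
    collapsed: FeatureTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.newick").write_text(self.tree.to_newick() + "\n")
        pd.DataFrame(self.curve, columns=["threshold", "n_clusters"]).to_csv(
            outdir / "threshold_curve.csv", index=False
        )
        self.grouping.to_frame().to_csv(outdir / "grouping.csv", index=False)
        self.feature_matrix.df.to_csv(outdir / "feature_ccc.csv")
        gm = self.group_matrix.df.copy()
        gm.loc["__category__"] = [
            self.group_matrix.categories[c] for c in gm.columns
        ]
        gm.to_csv(outdir / "group_ccc.csv")
        for name, df in self.summaries.items():
            df.to_csv(outdir / f"summary_{name}.csv")


def run_agreement_analysis(
    table: FeatureTable,
    threshold: float = 0.35,
    distance_mode: str = "signed",
    settings: Sequence[AcquisitionSetting] | None = None,
    curve_grid: np.ndarray | None = None,
    ddof: int = 0,
) -> AgreementAnalysis:
    """Cluster the features, cut at the threshold, and compute group CCCs."""
    if settings is None:
        settings = [AcquisitionSetting.from_label(s) for s in table.settings]
    tree = build_cluster_tree(table, distance_mode=distance_mode)
    if curve_grid is None:
        curve_grid = np.round(np.arange(0.0, 1.01, 0.05), 3)
    curve = threshold_curve(tree, curve_grid)
    grouping = cut_tree(tree, threshold)
    # constant features dropped from the tree form their own singleton groups
    for f in tree.dropped_features:
        gid = grouping.n_groups
        grouping.assignment[f] = gid
        grouping.labels[gid] = f
    pairs = enumerate_comparisons(settings)
    fmat = feature_ccc_matrix(table, pairs, ddof=ddof)
    gmat = group_average_ccc(fmat, grouping)
    summaries = summarize(gmat)
    collapsed = collapse_groups(table, grouping)
    return AgreementAnalysis(tree, curve, grouping, fmat, gmat, summaries, collapsed)


def write_provenance(outdir: str | Path, config: dict, seed: int | None = None) -> Path:
    """Machine-readable record sufficient to replay a run bit-identically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {
            "qifagree": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
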