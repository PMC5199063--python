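"""Inter-setting agreement via Lin's concordance correlation coefficient.

For two vectors x, y of one feature's values over the same tumors at two
settings,

    CCC = 2 rho sigma_x sigma_y / (sigma_x^2 + sigma_y^2 + (mu_x - mu_y)^2)
        = 2 cov(x, y) / (var_x + var_y + (mu_x - mu_y)^2)

with population (1/n) moments (Lin's original estimator; a ddof switch is
provided).  CCC penalizes both decorrelation and deviation from the 45-degree
identity line, so it is computed on raw feature values — standardizing per
setting would erase exactly the location/scale disagreements it measures.

The six settings give 15 unordered comparisons, categorized as:

- a: same kernel, different slice thickness;
- b: same thickness, different kernel;
- c: smooth kernel on the thinner slice vs sharp kernel on the thicker;
- d: sharp kernel on the thinner slice vs smooth kernel on the thicker.

Undefined CCCs (both vectors constant) are flagged as NaN, excluded from
averages, and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .phantoms import AcquisitionSetting
from .redundancy import FeatureGrouping
from .volio import FeatureTable, FeatureTableError

__all__ = [
    "ComparisonPair",
    "AgreementMatrix",
    "lin_ccc",
    "enumerate_comparisons",
    "feature_ccc_matrix",
    "group_average_ccc",
    "summarize",
]


def lin_ccc(x: Sequence[float], y: Sequence[float], ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient; NaN if both vectors are constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    n = x.size
    if ddof >= n:
        raise ValueError("ddof too large for vector length")
    mx, my = x.mean(), y.mean()
    denom_n = n - ddof
    vx = float(np.sum((x - mx) ** 2) / denom_n)
    vy = float(np.sum((y - my) ** 2) / denom_n)
    if vx == 0 and vy == 0:
        return float("nan")  # flagged: agreement undefined for two constants
    cov = float(np.sum((x - mx) * (y - my)) / denom_n)
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


@dataclass(frozen=True)
class ComparisonPair:
    """An unordered pair of distinct acquisition settings with its category."""

    a: AcquisitionSetting
    b: AcquisitionSetting

    def __post_init__(self) -> None:
        if self.a.label == self.b.label:
            raise ValueError(f"comparison needs two distinct settings, got {self.a.label}")

    @property
    def label(self) -> str:
        return f"{self.a.label}_vs_{self.b.label}"

    @property
    def category(self) -> str:
        a, b = self.a, self.b
        same_kernel = a.kernel == b.kernel
        same_thickness = a.thickness_mm == b.thickness_mm
        if same_kernel and not same_thickness:
            return "a"
        if same_thickness and not same_kernel:
            return "b"
        thinner = a if a.thickness_mm < b.thickness_mm else b
        return "c" if thinner.kernel == "S" else "d"


def enumerate_comparisons(settings: Sequence[AcquisitionSetting]) -> list[ComparisonPair]:
    """All unordered pairs of distinct settings (C(n,2); 15 for the six defaults)."""
    labels = [s.label for s in settings]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate settings in {labels}")
    if len(settings) < 2:
        raise ValueError("need at least 2 settings")
    return [ComparisonPair(a, b) for a, b in combinations(settings, 2)]


@dataclass
class AgreementMatrix:
    """CCC values per (feature-or-group, comparison pair).

    ``df`` rows are features or groups, columns are pair labels; NaN marks
    flagged (undefined) cells.  ``pairs`` carries the category metadata.
    """

    df: pd.DataFrame
    pairs: list[ComparisonPair]

    def __post_init__(self) -> None:
        expected = [p.label for p in self.pairs]
        if list(self.df.columns) != expected:
            raise ValueError("matrix columns must match pair labels in order")
        vals = self.df.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("CCC values must lie in [-1, 1]")

    @property
    def categories(self) -> dict[str, str]:
        return {p.label: p.category for p in self.pairs}


def feature_ccc_matrix(
    table: FeatureTable,
    pairs: Sequence[ComparisonPair],
    ddof: int = 0,
) -> AgreementMatrix:
    """Per-feature CCC over tumors for every comparison, on raw values."""
    tumors = table.tumors
    if len(tumors) < 3:
        raise FeatureTableError("agreement needs at least 3 tumors")
    available = set(table.settings)
    needed = {p.a.label for p in pairs} | {p.b.label for p in pairs}
    missing = needed - available
    if missing:
        raise FeatureTableError(f"settings absent from table: {sorted(missing)}")

    features = table.features
    wide = table.to_wide().set_index(["tumor", "setting"]).sort_index()
    data = np.full((len(features), len(pairs)), np.nan)
    for j, pair in enumerate(pairs):
        xa = wide.xs(pair.a.label, level="setting").loc[tumors]
        xb = wide.xs(pair.b.label, level="setting").loc[tumors]
        for i, f in enumerate(features):
            data[i, j] = lin_ccc(xa[f].to_numpy(), xb[f].to_numpy(), ddof=ddof)
    df = pd.DataFrame(data, index=features, columns=[p.label for p in pairs])
    return AgreementMatrix(df, list(pairs))


def group_average_ccc(matrix: AgreementMatrix, grouping: FeatureGrouping) -> AgreementMatrix:
    """Arithmetic mean of member-feature CCCs per group (NaN cells excluded)."""
    features = set(matrix.df.index)
    missing = features - set(grouping.assignment)
    if missing:
        raise ValueError(f"grouping does not cover matrix features: {sorted(missing)[:5]}")
    rows = {}
    for gid in sorted(grouping.labels):
        members = [m for m in grouping.members(gid) if m in features]
        if not members:
            continue
        sub = matrix.df.loc[members].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            rows[grouping.labels[gid]] = np.nanmean(sub, axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.df.columns)
    return AgreementMatrix(df, matrix.pairs)


def summarize(
    matrix: AgreementMatrix,
    high_threshold: float = 0.8,
    low_threshold: float = 0.7,
) -> dict[str, pd.DataFrame]:
    """Report tables: per-pair and per-row averages (descending), category means,
    and counts of rows strictly above/below the agreement thresholds."""
    df = matrix.df
    per_pair = df.mean(axis=0, skipna=True).sort_values(ascending=False)
    per_pair = per_pair.rename("mean_ccc").to_frame()
    per_pair["category"] = [matrix.categories[p] for p in per_pair.index]

    per_row = df.mean(axis=1, skipna=True).sort_values(ascending=False)
    per_row = per_row.rename("mean_ccc").to_frame()

    cats = pd.Series(matrix.categories)
    pair_means = df.mean(axis=0, skipna=True)
    category_means = (
        pair_means.groupby(cats).mean().rename("mean_ccc").to_frame().sort_index()
    )

    counts = pd.DataFrame(
        {
            "count": [
                int((per_row["mean_ccc"] > high_threshold).sum()),
                int((per_row["mean_ccc"] < low_threshold).sum()),
            ]
        },
        index=[f"rows_above_{high_threshold}", f"rows_below_{low_threshold}"],
    )
    return {
        "per_pair": per_pair,
        "per_group": per_row,
        "category_means": category_means,
        "threshold_counts": counts,
    }
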