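"""Feature redundancy reduction by Spearman-similarity hierarchical clustering.

Each feature's profile is its value vector over all tumor x setting
observations.  Pairwise similarity is Spearman's rank correlation rho
(midranks for ties); the clustering distance is d = 1 - rho (signed, so
anticorrelated features are *not* merged; a ``1 - |rho|`` switch is
provided).  The tree is built by unweighted average linkage (UPGMA) with a
deterministic tie rule: among equal-distance pairs, the pair whose
name-ordered representative is lexicographically smallest merges first.
Cutting the tree at height t groups features whose average Spearman
correlation is at least 1 - t; collapsed group values are means of member
z-scores (z fitted per feature across all observations), which makes the
collapse invariant to each member's original location and scale.

Features with zero variance have undefined ranks; they are dropped from
the tree and reported on the tree object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .volio import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ZScoreParams",
    "ClusterTree",
    "FeatureGrouping",
    "zscore",
    "spearman_similarity",
    "build_cluster_tree",
    "cut_tree",
    "threshold_curve",
    "collapse_groups",
]


@dataclass(frozen=True)
class ZScoreParams:
    """Per-feature standardization parameters (sample SD, ddof=1)."""

    mean: float
    sd: float
    constant: bool = False


def zscore(values: np.ndarray) -> tuple[np.ndarray, ZScoreParams]:
    """Standardize to mean 0, SD 1 (sample SD convention).

    A constant input is flagged and returned as zeros rather than raising:
    callers must treat flagged features separately (they carry no rank
    information).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("z-score needs at least 2 values")
    mu = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        return np.zeros_like(v), ZScoreParams(mu, 0.0, constant=True)
    return (v - mu) / sd, ZScoreParams(mu, sd)


def spearman_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho: Pearson correlation of midranks, in [-1, 1].

    Zero rank variance (a constant vector) makes the coefficient undefined;
    it is treated as 0 and logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        logger.warning("undefined Spearman similarity (constant input); treating as 0")
        return 0.0
    return float(rho)


@dataclass
class ClusterTree:
    """Agglomerative merge history over features.

    Nodes 0..n-1 are leaves (in ``leaves`` order); merge i creates node
    n+i.  Heights are nondecreasing (UPGMA monotonicity, validated).
    ``dropped_features`` lists zero-variance features excluded before
    clustering.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    distance_mode: str = "signed"
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n >= 2 and len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        hs = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(hs, hs[1:])):
            raise ValueError("merge heights must be nondecreasing (UPGMA monotonicity)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for dendrograms / cophenet)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((len(self.merges), 4))
        for i, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + i] = size
            Z[i] = [a, b, h, size]
        return Z

    def leaf_members(self, node: int) -> list[int]:
        n = self.n_leaves
        if node < n:
            return [node]
        a, b, _ = self.merges[node - n]
        return self.leaf_members(a) + self.leaf_members(b)

    def to_newick(self) -> str:
        """Newick text with branch lengths derived from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for i, (_, _, h) in enumerate(self.merges):
            heights[n + i] = h

        def render(node: int) -> str:
            if node < n:
                name = self.leaves[node].replace(" ", "_").replace(",", "_").replace(
                    "(", "_"
                ).replace(")", "_").replace(":", "_").replace(";", "_")
                return name
            a, b, h = self.merges[node - n]
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            return f"({render(a)}:{la:.6g},{render(b)}:{lb:.6g})"

        root = n + len(self.merges) - 1 if self.merges else 0
        return render(root) + ";"


@dataclass
class FeatureGrouping:
    """Partition of features into non-redundant groups at one threshold."""

    assignment: dict[str, int]
    labels: dict[int, str]
    threshold: float

    def __post_init__(self) -> None:
        groups = set(self.assignment.values())
        if groups != set(self.labels):
            raise ValueError("group labels must cover exactly the assigned group ids")
        if not groups and self.assignment:
            raise ValueError("empty grouping")

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def members(self, group_id: int) -> list[str]:
        return sorted(f for f, g in self.assignment.items() if g == group_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "group_id": g, "group_label": self.labels[g]}
            for f, g in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def _spearman_distance_matrix(profiles: pd.DataFrame, mode: str) -> tuple[np.ndarray, list[str], list[str]]:
    """(distance matrix, kept feature names, dropped constant features)."""
    values = profiles.to_numpy(dtype=float)
    names = list(profiles.columns)
    sds = values.std(axis=0)
    kept = [n for n, s in zip(names, sds) if s > 0]
    dropped = [n for n, s in zip(names, sds) if s == 0]
    if dropped:
        logger.warning("dropping %d zero-variance features from clustering: %s",
                       len(dropped), dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 non-constant features to cluster")
    sub = values[:, [names.index(n) for n in kept]]
    rho = stats.spearmanr(sub).statistic
    if np.ndim(rho) == 0:  # spearmanr returns a scalar for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if mode == "signed":
        dist = 1.0 - rho
    elif mode == "absolute":
        dist = 1.0 - np.abs(rho)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    np.fill_diagonal(dist, 0.0)
    return dist, kept, dropped


def upgma(dist: np.ndarray, names: list[str], distance_mode: str = "signed") -> ClusterTree:
    """Average-linkage agglomeration with the lexicographic tie rule.

    Naive O(n^3) with Lance-Williams updates; cost is irrelevant at
    feature-panel sizes and the explicit loop keeps the tie rule exact.
    """
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> size
    rep: dict[int, str] = {i: names[i] for i in range(n)}  # lexicographic representative
    d: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = float(dist[i, j])
    merges: list[tuple[int, int, float]] = []
    next_id = n
    last_h = -np.inf
    while len(active) > 1:
        best_key = None
        best = (np.inf, "", "")
        for key, dd in d.items():
            a, b = sorted(key)
            ra, rb = sorted((rep[a], rep[b]))
            cand = (dd, ra, rb)
            if cand < best:
                best = cand
                best_key = key
        a, b = sorted(best_key)  # type: ignore[arg-type]
        h = best[0]
        h = max(h, last_h)  # guard float jitter; UPGMA is monotone
        last_h = h
        sa, sb = active.pop(a), active.pop(b)
        new = next_id
        next_id += 1
        for c in list(active):
            dac = d.pop(frozenset((a, c)))
            dbc = d.pop(frozenset((b, c)))
            d[frozenset((new, c))] = (sa * dac + sb * dbc) / (sa + sb)
        del d[frozenset((a, b))]
        active[new] = sa + sb
        rep[new] = min(rep[a], rep[b])
        merges.append((a, b, h))
    return ClusterTree(leaves=list(names), merges=merges, distance_mode=distance_mode)


def build_cluster_tree(table: FeatureTable, distance_mode: str = "signed") -> ClusterTree:
    """UPGMA tree of the table's features under d = 1 - rho_spearman."""
    profiles = table.feature_profiles()
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 features")
    dist, kept, dropped = _spearman_distance_matrix(profiles, distance_mode)
    tree = upgma(dist, kept, distance_mode)
    tree.dropped_features = dropped
    return tree


def cut_tree(tree: ClusterTree, threshold: float) -> FeatureGrouping:
    """Groups = connected components after removing merges above the threshold.

    Threshold t keeps merges with height <= t, i.e. groups features whose
    unweighted-average Spearman correlation is >= 1 - t.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, h) in enumerate(tree.merges):
        node = n + i
        if h <= threshold + 1e-12:
            for child in (a, b):
                parent[find(child)] = find(node)

    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    assignment: dict[str, int] = {}
    labels: dict[int, str] = {}
    # deterministic group ids: ordered by lexicographically-first member
    comps = sorted(roots.values(), key=lambda ls: min(tree.leaves[l] for l in ls))
    for gid, leaves in enumerate(comps):
        names = sorted(tree.leaves[l] for l in leaves)
        labels[gid] = names[0] if len(names) == 1 else f"{names[0]}_group"
        for nme in names:
            assignment[nme] = gid
    return FeatureGrouping(assignment, labels, threshold)


def threshold_curve(tree: ClusterTree, grid: np.ndarray) -> list[tuple[float, int]]:
    """(threshold, cluster count) along an ascending grid; counts nonincreasing."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    return [(float(t), cut_tree(tree, t).n_groups) for t in grid]


def collapse_groups(table: FeatureTable, grouping: FeatureGrouping) -> FeatureTable:
    """One value per (tumor, setting, group): mean of member z-scores.

    Z-scores are fitted per feature over all observations.  Constant member
    features carry no information and are excluded (logged); a group whose
    members are all constant collapses to 0 by convention.
    """
    profiles = table.feature_profiles()
    features = set(profiles.columns)
    missing = features - set(grouping.assignment)
    if missing:
        raise ValueError(f"grouping does not cover features: {sorted(missing)[:5]}")

    zcols: dict[str, np.ndarray] = {}
    constants: list[str] = []
    for f in profiles.columns:
        z, p = zscore(profiles[f].to_numpy())
        if p.constant:
            constants.append(f)
        else:
            zcols[f] = z
    if constants:
        logger.warning("constant features excluded from group averaging: %s", constants)

    records = []
    index = profiles.index  # (tumor, setting)
    for gid in sorted(grouping.labels):
        members = [m for m in grouping.members(gid) if m in features]
        informative = [m for m in members if m in zcols]
        if informative:
            vals = np.mean([zcols[m] for m in informative], axis=0)
        else:
            vals = np.zeros(len(profiles))
        label = grouping.labels[gid]
        for (tumor, setting), v in zip(index, vals):
            records.append((tumor, setting, label, float(v)))
    return FeatureTable.from_records(records)
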