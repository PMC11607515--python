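"""Co-abundance metabotyping of serum metabolite features.

Two stages mirror the analysis chain for untargeted metabolomics in a
staged-disease cohort:

1. **Cross-comparison selection.**  Set A keeps a feature if, in at
   least one pairwise group comparison, BOTH the Wilcoxon q-value and
   the (log-intensity) Welch t-test q-value fall below ``q_metabolite``
   AND the fold change is outside (``fc_low``, ``fc_high``) — all three
   conditions within the same comparison.  Set B keeps a feature if the
   Jonckheere-Terpstra trend p or the Kruskal-Wallis p across the
   ordered groups is below ``p_setB``.  The selected set is the union;
   a user-supplied drug-feature exclusion list is removed afterwards.

2. **Co-abundance clustering.**  Signed weighted network on Pearson
   correlations of log-transformed standardized intensities,
   a_ij = ((1 + r_ij)/2)^beta with beta = 14 by default; topological
   overlap (TOM) similarity; average-linkage tree on 1 - TOM; and a
   deterministic dynamic tree cut whose deepSplit level (0-4) maps to an
   increasingly aggressive cut height.  Clusters below
   ``min_cluster_size`` are left unassigned; survivors are labelled
   M01, M02, ... by descending size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .stats import (
    bh_adjust,
    fold_change,
    jonckheere_terpstra,
    kruskal_wallis,
    t_test_welch,
    wilcoxon_rank_sum,
)
from .tables import AbundanceTable, CohortMetadata

logger = logging.getLogger("triomics")

UNASSIGNED = "M00"

#: deepSplit level 0-4 -> core tightness quantile; the minimum merge-height
#: gap required to split a branch is 0.75 * (1 - q) of the dendrogram height
#: window, so higher levels demand smaller gaps and split more aggressively.
DEEP_SPLIT_QUANTILES = (0.64, 0.73, 0.82, 0.91, 0.95)

#: fraction of the maximum merge height at which the static top cut is made
TOP_CUT_FRACTION = 0.99


@dataclass
class CrossComparisonResult:
    feature_id: str
    setA_pass: bool
    setB_pass: bool
    selected: bool
    support: dict = field(default_factory=dict)


def _log_intensity(table: AbundanceTable) -> pd.DataFrame:
    """Log transform; a half-minimum pseudocount is added only when the
    table actually contains zeros."""
    vals = table.values
    if (vals > 0).all():
        return np.log(table.data)
    nz = vals[vals > 0]
    pc = nz.min() / 2.0 if len(nz) else 1e-9
    return np.log(table.data + pc)


def cross_comparison_filter(
    met_table: AbundanceTable,
    meta: CohortMetadata,
    config: PipelineConfig | None = None,
    exclude: list[str] | None = None,
) -> list[CrossComparisonResult]:
    """Set A (pairwise dual-q + fold change) union set B (trend/k-group)."""
    config = config or PipelineConfig()
    groups = list(meta.group_order)
    sample_sets = {g: meta.samples_in_group(g) for g in groups}
    for g, ids in sample_sets.items():
        if len(ids) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    logged = _log_intensity(met_table)
    raw = met_table.data
    features = met_table.feature_ids
    n = len(features)
    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]

    setA = np.zeros(n, dtype=bool)
    support: list[dict] = [{} for _ in range(n)]
    for ref, case in pairs:
        r_ids, c_ids = sample_sets[ref], sample_sets[case]
        wp = np.empty(n)
        tp = np.empty(n)
        fc = np.empty(n)
        for i, fid in enumerate(features):
            x_raw = raw.loc[fid, r_ids].to_numpy()
            y_raw = raw.loc[fid, c_ids].to_numpy()
            wp[i] = wilcoxon_rank_sum(x_raw, y_raw).p_value
            tp[i] = t_test_welch(
                logged.loc[fid, r_ids].to_numpy(), logged.loc[fid, c_ids].to_numpy()
            ).p_value
            fc[i] = fold_change(x_raw, y_raw)
        wq = bh_adjust(wp)  # each test family adjusted separately
        tq = bh_adjust(tp)
        gate = (fc > config.fc_high) | (fc < config.fc_low)
        passed = (wq < config.q_metabolite) & (tq < config.q_metabolite) & gate
        setA |= passed
        for i in range(n):
            support[i][f"{ref}_vs_{case}"] = {
                "wilcoxon_q": float(wq[i]),
                "ttest_q": float(tq[i]),
                "fold_change": float(fc[i]),
            }

    setB = np.zeros(n, dtype=bool)
    grouped_raw = [raw[sample_sets[g]].to_numpy() for g in groups]
    for i in range(n):
        vecs = [g[i] for g in grouped_raw]
        jt_p = jonckheere_terpstra(vecs).p_value
        kw_p = kruskal_wallis(vecs).p_value
        setB[i] = jt_p < config.p_setB or kw_p < config.p_setB
        support[i]["trend"] = {"jt_p": float(jt_p), "kruskal_p": float(kw_p)}

    excluded = set(exclude or [])
    results = []
    for i, fid in enumerate(features):
        sel = bool((setA[i] or setB[i]) and fid not in excluded)
        results.append(
            CrossComparisonResult(fid, bool(setA[i]), bool(setB[i]), sel, support[i])
        )
    return results


def selected_features(results: list[CrossComparisonResult]) -> list[str]:
    return [r.feature_id for r in results if r.selected]


# ---------------------------------------------------------------------------
# Network construction


def adjacency(
    selected_table: AbundanceTable, beta: float = 14.0, signed: bool = True
) -> pd.DataFrame:
    """Soft-threshold adjacency on log-standardized feature correlations.

    Signed: a = ((1 + r)/2)^beta; unsigned: a = |r|^beta.  Zero-variance
    features are dropped with a warning.  Diagonal is 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    logged = _log_intensity(selected_table)
    sd = logged.std(axis=1, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        logger.warning("dropping %d zero-variance features", len(dead))
        logged = logged.drop(index=dead)
    if logged.shape[0] < 3:
        raise ValueError("need >= 3 variable features for a network")
    r = np.corrcoef(logged.to_numpy())
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=logged.index, columns=logged.index)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log-log connectivity-frequency fit (scale-free check)."""
    a = adj.to_numpy()
    k = a.sum(axis=1) - np.diag(a)
    if np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(k[mask].mean())
        ys.append(mask.mean())
    xs, ys = np.array(xs), np.array(ys)
    ok = (xs > 0) & (ys > 0)
    if ok.sum() < 3:
        return float("nan")
    lx, ly = np.log10(xs[ok]), np.log10(ys[ok])
    r = np.corrcoef(lx, ly)[0, 1]
    return float(np.clip(r**2, 0.0, 1.0))


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM similarity; see module docstring for the exact formula."""
    a = adj.to_numpy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0  # connectivity excluding self
    a2 = a @ a
    # shared-neighbour term excludes u in {i, j}: (A^2)_ij - a_ii a_ij - a_ij a_jj
    shared = a2 - 2.0 * a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(den, 1.0)  # diagonal is overwritten below
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class MetabotypeAssignment:
    """Feature -> metabotype label; M00 marks unassigned features."""

    labels: pd.Series  # feature_id -> "M01".. / "M00"
    sizes: dict[str, int]
    eigen_features: pd.DataFrame | None = None  # cluster x sample

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(k for k in self.sizes if k != UNASSIGNED)

    def members(self, cluster: str) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def dynamic_tree_cut(
    dissimilarity: pd.DataFrame,
    deep_split: int = 4,
    min_cluster_size: int = 5,
) -> MetabotypeAssignment:
    """Average-linkage tree plus deterministic adaptive branch decomposition.

    A static top cut at ``TOP_CUT_FRACTION * h_max`` separates the main
    branches; each branch is then recursively split at its top merge
    whenever (i) both sub-branches hold at least ``min_cluster_size``
    features and (ii) the merge height exceeds both sub-branch tops by
    at least ``0.75 * (1 - q) * (cut_height - h_min)``, with q taken
    from ``DEEP_SPLIT_QUANTILES[deep_split]``.  Higher deepSplit levels
    therefore require smaller gaps and can only refine the partition,
    so the number of clusters never decreases with ``deep_split``.
    Branches smaller than ``min_cluster_size`` are unassigned (M00);
    surviving clusters are relabelled M01, M02, ... by descending size.
    """
    if deep_split not in (0, 1, 2, 3, 4):
        raise ValueError("deep_split must be in 0..4")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    d = dissimilarity.to_numpy().copy()
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    np.fill_diagonal(d, 0.0)
    features = list(dissimilarity.index)
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    cut_height = TOP_CUT_FRACTION * h_max
    q = DEEP_SPLIT_QUANTILES[deep_split]
    min_gap = 0.75 * (1.0 - q) * max(cut_height - h_min, 0.0)

    from scipy.cluster.hierarchy import to_tree

    root = to_tree(z)

    def top_branches(node, out):
        """Maximal subtrees whose top merge lies below the static cut."""
        if node.is_leaf() or node.dist <= cut_height:
            out.append(node)
        else:
            top_branches(node.left, out)
            top_branches(node.right, out)

    def split(node, out):
        """Recursive gap-guarded decomposition of one branch."""
        if node.is_leaf():
            out.append(node)
            return
        left, right = node.left, node.right
        gap = node.dist - max(left.dist, right.dist)
        if (
            left.count >= min_cluster_size
            and right.count >= min_cluster_size
            and gap >= min_gap
        ):
            split(left, out)
            split(right, out)
        else:
            out.append(node)

    branches: list = []
    top_branches(root, branches)
    clusters: list = []
    for b in branches:
        split(b, clusters)

    labels = pd.Series(UNASSIGNED, index=features, dtype=object)
    kept = [c for c in clusters if c.count >= min_cluster_size]
    if not kept:
        logger.warning("no branch reached min_cluster_size; all unassigned")
    # deterministic order: size descending, then leftmost leaf id as tie-break
    def leafs(node):
        return node.pre_order(lambda n: n.id)

    kept.sort(key=lambda c: (-c.count, min(leafs(c))))
    for i, c in enumerate(kept):
        for leaf in leafs(c):
            labels.iloc[leaf] = f"M{i + 1:02d}"
    sizes = labels.value_counts().to_dict()
    return MetabotypeAssignment(labels, sizes)


def eigen_feature(
    met_table: AbundanceTable, assignment: MetabotypeAssignment
) -> pd.DataFrame:
    """First principal component per cluster over samples.

    Computed on log-transformed, per-feature standardized intensities;
    sign-oriented so the mean correlation with cluster members is
    positive.  A singleton cluster's eigen-feature is the standardized
    feature itself.
    """
    logged = _log_intensity(met_table)
    std = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=1).replace(0, 1.0)
    std = std.div(sd, axis=0)
    rows = {}
    for cid in assignment.cluster_ids:
        members = [m for m in assignment.members(cid) if m in std.index]
        if not members:
            continue
        x = std.loc[members].to_numpy()  # features x samples
        if x.shape[0] == 1:
            vec = x[0]
        else:
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            vec = vt[0] * s[0] / np.sqrt(x.shape[0])
        corr = np.array([np.corrcoef(vec, row)[0, 1] for row in x])
        if np.nanmean(corr) < 0:
            vec = -vec
        rows[cid] = vec
    frame = pd.DataFrame(rows, index=met_table.sample_ids).T
    frame.index.name = "cluster"
    return frame


def metabotype_chain(
    met_table: AbundanceTable,
    meta: CohortMetadata,
    config: PipelineConfig | None = None,
    exclude: list[str] | None = None,
) -> tuple[list[CrossComparisonResult], MetabotypeAssignment]:
    """Full chain: cross-comparison selection -> network -> TOM -> cut ->
    eigen-features."""
    config = config or PipelineConfig()
    results = cross_comparison_filter(met_table, meta, config, exclude)
    selected = selected_features(results)
    if len(selected) < 3:
        raise ValueError("fewer than 3 selected features; cannot cluster")
    sub = met_table.subset_features(selected)
    adj = adjacency(sub, beta=config.soft_power_beta, signed=True)
    tom = topological_overlap(adj)
    assignment = dynamic_tree_cut(
        1.0 - tom, deep_split=config.deep_split,
        min_cluster_size=config.min_cluster_size,
    )
    assignment.eigen_features = eigen_feature(sub, assignment)
    return results, assignment
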