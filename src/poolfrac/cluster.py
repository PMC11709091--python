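"""Unsupervised hierarchical clustering of protein abundance.

Rows (proteins) are z-scored on the log2 scale, then rows and columns
(pools) are clustered agglomeratively.  Defaults — Pearson-correlation
distance with average linkage — mirror common heatmap-tool settings;
Euclidean distance and complete/ward linkage are available as options.
Output is deterministic: inputs are sorted by identifier before
linkage so that distance ties always break the same way, and
dendrograms can be exported as Newick text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .model import AbundanceTable, ValidationError

DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")

#: Maximal Pearson-correlation distance, assigned to zero-variance rows.
_MAX_CORR_DIST = 2.0


@dataclass
class ClusteringResult:
    zscores: pd.DataFrame           # proteins x pools, z-scored log2
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_clusters: Optional[dict[str, int]]
    col_clusters: Optional[dict[str, int]]

    def row_newick(self) -> str:
        return linkage_to_newick(self.row_linkage, list(self.zscores.index))

    def col_newick(self) -> str:
        return linkage_to_newick(self.col_linkage, list(self.zscores.columns))


def zscore_log2_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score of log2 values; zero-variance rows become all
    zeros."""
    logged = np.log2(values.to_numpy(dtype=float))
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def _distance_matrix(data: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return pdist(data, metric="euclidean")
    # Correlation distance with a defined value for zero-variance rows:
    # such rows get the maximal distance to everything (and 0 to
    # themselves via the diagonal, which pdist ignores).
    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance row(s): correlation "
            f"distance set to the maximum ({_MAX_CORR_DIST})"
        )
        safe = data.copy()
        # Give flat rows an arbitrary non-constant profile so pdist is
        # defined; their distances are overwritten below anyway.
        safe[degenerate] = np.arange(data.shape[1], dtype=float)
        d = squareform(pdist(safe, metric="correlation"), checks=False)
        d[degenerate, :] = _MAX_CORR_DIST
        d[:, degenerate] = _MAX_CORR_DIST
        np.fill_diagonal(d, 0.0)
        return squareform(d, checks=False)
    return pdist(data, metric="correlation")


def cluster_heatmap(
    table: AbundanceTable,
    proteins: Optional[Set[str]] = None,
    distance: str = "correlation",
    linkage: str = "average",
    cut_k: Optional[int] = None,
    cut_k_rows: Optional[int] = None,
) -> ClusteringResult:
    """Cluster a (subset of a) protein x pool matrix.

    ``proteins`` restricts to a protein subset (e.g. an age-dynamic DE
    set).  Proteins with missing values in the selected pools are
    dropped with a warning, since distances are undefined on incomplete
    rows.  ``cut_k`` labels the **column** (pool) dendrogram cut into k
    flat clusters — the grouping used to ask whether age groups
    separate — and ``cut_k_rows`` does the same for protein rows.
    """
    if distance not in DISTANCES:
        raise ValidationError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")

    sub = table if proteins is None else table.select_proteins(proteins)
    if proteins is not None and len(sub.proteins) < len(set(proteins)):
        missing = sorted(set(proteins) - set(sub.proteins))
        raise ValidationError(f"proteins not in table: {', '.join(missing)}")

    complete = sub.values.dropna(axis=0)
    n_dropped = sub.shape[0] - complete.shape[0]
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} protein(s) with missing values")
    if complete.shape[0] < 2 or complete.shape[1] < 2:
        raise ValidationError("need at least 2 complete proteins and 2 pools")

    # Deterministic tie-breaking: sort by identifier before linkage.
    complete = complete.sort_index(axis=0).sort_index(axis=1)
    z = zscore_log2_rows(complete)

    method = linkage
    row_d = _distance_matrix(z.to_numpy(), distance)
    col_d = _distance_matrix(z.to_numpy().T, distance)
    row_link = hierarchy.linkage(row_d, method=method)
    col_link = hierarchy.linkage(col_d, method=method)

    row_leaves = hierarchy.leaves_list(row_link)
    col_leaves = hierarchy.leaves_list(col_link)
    row_order = [z.index[i] for i in row_leaves]
    col_order = [z.columns[i] for i in col_leaves]

    def cut(link: np.ndarray, labels: Sequence[str], k: Optional[int]):
        if k is None:
            return None
        flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(labels, flat)}

    return ClusteringResult(
        zscores=z,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
        row_clusters=cut(row_link, list(z.index), cut_k_rows),
        col_clusters=cut(col_link, list(z.columns), cut_k),
    )


def cluster_purity(
    clusters: Mapping[str, int], labels: Mapping[str, str]
) -> float:
    """Weighted purity of flat clusters against reference labels:
    sum over clusters of its majority-label count, over the total."""
    by_cluster: dict[int, list[str]] = {}
    for item, c in clusters.items():
        by_cluster.setdefault(c, []).append(labels[item])
    total = sum(len(v) for v in by_cluster.values())
    majority = sum(max(v.count(l) for l in set(v)) for v in by_cluster.values())
    return majority / total


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage as Newick text; branch lengths are merge
    -height differences (leaf branches span the full merge height)."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
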