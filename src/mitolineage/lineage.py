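"""Mitochondrial distance matrix and hierarchical lineage clustering.

The mitochondrial distance between two cells (or clones) i and j over
informative mutations x is the mean absolute VAF difference across the
sites where at least one of the pair carries the allele at an appreciable
frequency:

    d_ij = sum_x |AF_xi - AF_xj| * (I[AF_xi > t] or I[AF_xj > t])
           / sum_x (I[AF_xi > t] or I[AF_xj > t]),        t = 0.01.

Sites silent in both members carry no lineage evidence and are excluded
from the average, so d lies in [0, 1].  A pair with no contributing site
at all provides no shared evidence and is assigned distance 1 (maximally
dissimilar), with a warning.

Cells are grouped by agglomerative clustering on the precomputed distance
matrix (average linkage by default); Euclidean and correlation distances
on the VAF columns are provided as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_matrix import VafDataset


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    metric: str
    min_af: float = 0.01

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class LineageResult:
    """Dendrogram (scipy linkage matrix) plus optional flat clusters."""

    labels: list[str]
    linkage: np.ndarray
    linkage_method: str
    clusters: dict[str, int] | None = None

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def mito_distance(ds: VafDataset, min_af: float = 0.01) -> DistanceMatrix:
    """Pairwise mitochondrial distance between cells over the dataset's mutations.

    Missing VAFs (depth 0) count as 0 for the indicator; a site contributes
    to a pair only when at least one member's VAF exceeds ``min_af``.
    """
    if ds.n_mutations == 0:
        raise ValueError("empty mutation set: cannot compute mitochondrial distance")
    af = np.nan_to_num(ds.vaf)  # mutations x cells
    ind = af > min_af
    n = ds.n_cells
    d = np.zeros((n, n))
    n_zero = 0
    for i in range(n):
        ai = af[:, i]
        ii = ind[:, i]
        both = ii[:, None] | ind[:, i + 1:]
        num = (np.abs(ai[:, None] - af[:, i + 1:]) * both).sum(axis=0)
        den = both.sum(axis=0)
        with np.errstate(invalid="ignore"):
            row = np.where(den > 0, num / np.maximum(den, 1), 1.0)
        n_zero += int((den == 0).sum())
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if n_zero:
        warnings.warn(
            f"{n_zero} cell pairs share no site above min_af={min_af}; "
            "their distance is set to 1",
            stacklevel=2,
        )
    return DistanceMatrix(list(ds.cells), d, "mito", min_af)


def alt_distance(ds: VafDataset, metric: str = "euclidean") -> DistanceMatrix:
    """Euclidean or 1 - Pearson correlation distance over VAF columns.

    Missing entries are handled pairwise-complete; a pair with a
    zero-variance column under correlation gets distance 1 (warned).
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    if ds.n_mutations == 0 or (metric == "correlation" and ds.n_mutations < 2):
        raise ValueError(f"too few mutations for {metric} distance")
    v = ds.vaf
    n = ds.n_cells
    d = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(v[:, i]) | np.isnan(v[:, j]))
            a, b = v[ok, i], v[ok, j]
            if metric == "euclidean":
                d[i, j] = d[j, i] = float(np.sqrt(((a - b) ** 2).sum()))
            else:
                if a.size < 2 or a.std() == 0 or b.std() == 0:
                    d[i, j] = d[j, i] = 1.0
                    warned = True
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                    d[i, j] = d[j, i] = 1.0 - r
    if warned:
        warnings.warn("zero-variance columns under correlation set to distance 1", stacklevel=2)
    return DistanceMatrix(list(ds.cells), d, metric)


def cluster_lineage(
    dm: DistanceMatrix, linkage_method: str = "average", k: int | None = None
) -> LineageResult:
    """Agglomerative clustering on a precomputed distance matrix.

    Supported linkages: average (UPGMA, default), complete, single.  Ward
    is rejected for non-Euclidean metrics.  scipy's agglomeration is
    deterministic (lowest-index pair merges first on ties).
    """
    if linkage_method == "ward" and dm.metric == "mito":
        raise ValueError("ward linkage requires Euclidean geometry; use average/complete/single")
    if linkage_method not in ("average", "complete", "single", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    if k is not None and k > len(dm.labels):
        raise ValueError("k exceeds number of observations")
    Z = hierarchy.linkage(dm.condensed(), method=linkage_method)
    result = LineageResult(list(dm.labels), Z, linkage_method)
    if k is not None:
        result.clusters = result.cut(k)
    return result


def leaf_order(result: LineageResult) -> list[str]:
    return [result.labels[i] for i in hierarchy.leaves_list(result.linkage)]


def to_newick(result: LineageResult) -> str:
    """Render the dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return rec(tree, tree.dist) + ";"


def export_heatmap_data(
    ds: VafDataset, dm: DistanceMatrix, result: LineageResult, out_prefix: str
) -> dict[str, str]:
    """Write heatmap-ready artifacts: leaf-ordered VAF matrix, flat clusters
    (if cut), the distance matrix, and the dendrogram in Newick format."""
    import pandas as pd

    order = leaf_order(result)
    col_idx = [ds.cells.index(c) for c in order]
    paths = {}

    vaf = pd.DataFrame(ds.vaf[:, col_idx], index=ds.mutation_names, columns=order)
    paths["vaf"] = f"{out_prefix}_vaf_ordered.csv"
    vaf.to_csv(paths["vaf"], index_label="mutation", float_format="%.12g")

    dmat = pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels)
    paths["distance"] = f"{out_prefix}_distance.csv"
    dmat.to_csv(paths["distance"], index_label="", float_format="%.12g")

    if result.clusters is not None:
        paths["clusters"] = f"{out_prefix}_clusters.csv"
        pd.DataFrame(
            {"cell": list(result.clusters), "cluster": list(result.clusters.values())}
        ).to_csv(paths["clusters"], index=False)

    paths["newick"] = f"{out_prefix}_dendrogram.nwk"
    with open(paths["newick"], "w") as fh:
        fh.write(to_newick(result) + "\n")
    return paths
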