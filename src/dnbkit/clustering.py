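"""Time-evolution clustering: z-score, 1 - r dissimilarity, average linkage.

The linkage is implemented directly (Lance–Williams update for the
unweighted pair-group average) rather than delegated, so that tie-breaking
is fully specified: among equally close pairs the one with the smallest
(first, second) cluster indices wins.  The dendrogram uses the usual
merge-list encoding — row m merges nodes ``a`` and ``b`` (original leaves
are 0..n-1, the merge created at row m is node n+m) at ``height`` into a
cluster of ``size`` leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, SampleMetadata

__all__ = [
    "Dendrogram",
    "zscore_rows",
    "cell_mean_profiles",
    "correlation_dissimilarity",
    "average_linkage",
    "cut_clusters",
]


@dataclass
class Dendrogram:
    """Merge list of an agglomerative clustering.

    ``merges`` is an (n-1, 4) float array with columns
    (child_a, child_b, height, size); ``labels`` are the leaf gene ids.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["child_a", "child_b", "height", "size"]
        ).astype({"child_a": int, "child_b": int, "size": int})


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize every gene row to mean 0 and sample SD 1 (ddof=1)."""
    values = matrix.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        bad = matrix.genes[constant].tolist()
        raise ValueError(f"constant rows cannot be z-scored: {bad[:10]}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=matrix.genes, columns=matrix.samples), scale=matrix.scale
    )


def cell_mean_profiles(
    matrix: ExpressionMatrix, metadata: SampleMetadata
) -> ExpressionMatrix:
    """Per-gene feature vector of (group, week) cell means of log2 values.

    Columns are ordered control weeks ascending then treated weeks
    ascending, named ``<group>_w<week>``.  This is the default feature
    space for time-evolution clustering; pass the full matrix instead to
    cluster on individual samples.
    """
    cols = {}
    for group, week, ids in metadata.cells():
        cols[f"{group}_w{week}"] = matrix.data.loc[:, ids].mean(axis=1)
    profile = pd.DataFrame(cols, index=matrix.genes)
    return ExpressionMatrix(profile, scale=matrix.scale)


def correlation_dissimilarity(matrix: ExpressionMatrix) -> np.ndarray:
    """Pairwise 1 - Pearson(r) grid over gene rows; entries in [0, 2]."""
    values = matrix.data.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = matrix.genes[sd == 0].tolist()
        raise ValueError(f"constant rows have undefined correlation: {bad[:10]}")
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # clip fp noise just outside [0, 2]
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def average_linkage(
    dissimilarity: np.ndarray, labels: list[str] | None = None
) -> Dendrogram:
    """UPGMA-style average linkage on an explicit dissimilarity grid.

    Inter-cluster dissimilarity is the unweighted mean of all cross-pair
    entries; ties are broken toward the smallest cluster indices, making
    the merge order deterministic.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("dissimilarity must be a square grid")
    if n < 2:
        raise ValueError("need at least 2 items")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(n)]

    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # positions into `work`, ordered by node id creation
    node_of = list(range(n))  # node id at each active position
    sizes = {i: 1 for i in range(n)}
    merges = np.empty((n - 1, 4), dtype=float)

    for m in range(n - 1):
        k = len(active)
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)  # first minimum = smallest (row, col) positions
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        height = sub[i, j]
        node_i, node_j = node_of[i], node_of[j]
        a, b = sorted((node_i, node_j))
        new_node = n + m
        size = sizes[node_i] + sizes[node_j]
        merges[m] = (a, b, height, size)

        pi, pj = active[i], active[j]
        # Lance-Williams: average linkage with cluster-size weights
        wi = sizes[node_i] / size
        wj = sizes[node_j] / size
        others = [p for p in active if p not in (pi, pj)]
        if others:
            merged = wi * work[pi, others] + wj * work[pj, others]
            work[pi, others] = merged
            work[others, pi] = merged
        work[pi, pi] = np.inf
        sizes[new_node] = size
        node_of[i] = new_node
        del active[j], node_of[j]

    return Dendrogram(merges=merges, labels=list(labels))


def cut_clusters(dendrogram: Dendrogram, cutoff: float = 0.5) -> pd.DataFrame:
    """Flat clusters from merges with height <= cutoff (inclusive).

    Returns a DataFrame (gene, cluster_id, cluster_size); cluster ids are
    assigned 1, 2, ... by first appearance in leaf order.
    """
    n = dendrogram.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, height, _size) in enumerate(dendrogram.merges):
        if height <= cutoff:
            new = n + m
            parent[find(int(a))] = new
            parent[find(int(b))] = new

    roots: dict[int, int] = {}
    assignment = []
    for leaf in range(n):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots) + 1
        assignment.append(roots[root])
    out = pd.DataFrame({"gene": dendrogram.labels, "cluster_id": assignment})
    counts = out["cluster_id"].value_counts()
    out["cluster_size"] = out["cluster_id"].map(counts)
    return out.set_index("gene", drop=False)
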