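"""Dataset x feature matrices, community distances, clustering and ordination.

Distances are computed on relative-abundance rows by default (heatmaps are
drawn on relative values); an absolute mode is available.  Four metrics are
supported:

* Morisita-Horn: ``1 - 2*sum(x_i*y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y)``
  with ``X = sum(x)``, ``Y = sum(y)``.  Abundance-based, insensitive to
  sample size, range [0, 1]; not a metric (the triangle inequality can fail).
* Bray-Curtis: ``sum|x_i - y_i| / sum(x_i + y_i)``.
* Jaccard on presence/absence supports.
* Euclidean.

Hierarchical clustering is average linkage (UPGMA): at each step the pair of
clusters with the smallest unweighted mean pairwise distance merges, at a
height equal to that mean.  Ties break deterministically on the
lexicographically smallest member labels so outputs are bit-reproducible.
Ordination is classical (Torgerson) multi-dimensional scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

from .abundance import absolute_frequency
from .annotation_store import Dataset
from .hierarchies import OntologyDAG, PathwayMap, TaxonomyTree
from .query_engine import QueryNode, evaluate, parse_query

METRICS = ("morisita-horn", "bray-curtis", "jaccard", "euclidean")


def build_matrix(
    datasets: Sequence[Dataset],
    attribute: str,
    level: str | int | None = None,
    filter_query: str | QueryNode | None = None,
    *,
    tree: TaxonomyTree | None = None,
    ontology: OntologyDAG | None = None,
    pathway_map: PathwayMap | None = None,
    mode: str = "relative",
    weighted: bool = True,
    include_unassigned: bool = True,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Datasets x features abundance matrix over the union of features.

    The filter query is applied per dataset *before* aggregation; relative
    frequencies use each dataset's post-filter total.  A dataset left empty
    by the filter yields a row of zeros and a warning.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    ast = parse_query(filter_query) if isinstance(filter_query, str) else filter_query

    def one_profile(dataset: Dataset):
        filtered = evaluate(ast, dataset, tree) if ast is not None else dataset
        if ast is not None and len(filtered) == 0:
            warnings.warn(
                f"filter left dataset {dataset.library_id!r} empty; row of zeros",
                stacklevel=2,
            )
        profile = absolute_frequency(
            filtered,
            attribute,
            level,
            tree=tree,
            ontology=ontology,
            pathway_map=pathway_map,
            weighted=weighted,
            include_unassigned=include_unassigned,
        )
        return profile.relative() if mode == "relative" else profile

    if n_jobs != 1:
        from joblib import Parallel, delayed

        profiles = Parallel(n_jobs=n_jobs)(delayed(one_profile)(d) for d in datasets)
    else:
        profiles = [one_profile(d) for d in datasets]

    features = sorted(set().union(*(p.values.keys() for p in profiles)) or set())
    data = np.zeros((len(profiles), len(features)))
    for i, profile in enumerate(profiles):
        for j, feature in enumerate(features):
            data[i, j] = profile[feature]
    return pd.DataFrame(data, index=[d.library_id for d in datasets], columns=features)


def _check_vectors(x: np.ndarray, y: np.ndarray, metric: str) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundance profiles must be non-negative")
    if metric in ("morisita-horn", "bray-curtis", "jaccard"):
        if x.sum() == 0 or y.sum() == 0:
            raise ValueError(f"{metric} distance is undefined for an all-zero profile")


def morisita_horn(x: Sequence[float], y: Sequence[float]) -> float:
    """Morisita-Horn distance (1 - similarity) between two abundance profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_vectors(x, y, "morisita-horn")
    X = x.sum()
    Y = y.sum()
    da = (x**2).sum() / X**2
    db = (y**2).sum() / Y**2
    # grouping (X*Y) keeps the expression bitwise symmetric in x and y
    similarity = 2.0 * (x * y).sum() / ((da + db) * (X * Y))
    return float(min(1.0, max(0.0, 1.0 - similarity)))


def distance(x: Sequence[float], y: Sequence[float], metric: str = "morisita-horn") -> float:
    """Distance between two equal-length non-negative abundance vectors."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_vectors(x, y, metric)
    if metric == "morisita-horn":
        return morisita_horn(x, y)
    if metric == "bray-curtis":
        return float(_ssd.braycurtis(x, y))
    if metric == "jaccard":
        return float(_ssd.jaccard(x > 0, y > 0))
    return float(_ssd.euclidean(x, y))


def distance_matrix(matrix: pd.DataFrame, metric: str = "morisita-horn") -> pd.DataFrame:
    """Symmetric pairwise distance matrix between the rows of ``matrix``."""
    ids = list(matrix.index)
    values = matrix.to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = distance(values[i], values[j], metric)
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass(frozen=True)
class DendrogramNode:
    """Binary merge-tree node; leaves have height 0 and no children."""

    height: float
    members: tuple[str, ...]  # sorted leaf labels under this node
    children: tuple["DendrogramNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class Dendrogram:
    root: DendrogramNode

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.members

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf labels in display order."""
        order: list[str] = []

        def walk(node: DendrogramNode) -> None:
            if node.is_leaf:
                order.append(node.label)  # type: ignore[arg-type]
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return order

    def merge_heights(self) -> list[float]:
        heights: list[float] = []

        def walk(node: DendrogramNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                for child in node.children:
                    walk(child)

        walk(self.root)
        return sorted(heights)

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent-child height differences."""

        def render(node: DendrogramNode) -> str:
            if node.is_leaf:
                return _newick_escape(node.label or "")
            parts = [
                f"{render(child)}:{node.height - child.height:.10g}"
                for child in node.children
            ]
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"

    def cut(self, height: float) -> dict[str, int]:
        """Partition leaves by severing every merge whose height exceeds ``height``.

        Returns leaf label -> cluster index; clusters are numbered in leaf
        order.  Cutting at or above the root height yields one cluster;
        cutting below every merge yields all singletons.
        """
        if height < 0:
            raise ValueError("cut height must be non-negative")
        clusters: list[list[str]] = []

        def walk(node: DendrogramNode) -> None:
            if not node.is_leaf and node.height > height:
                for child in node.children:
                    walk(child)
            else:
                clusters.append(list(node.members))

        walk(self.root)
        assignment: dict[str, int] = {}
        for index, members in enumerate(clusters):
            for leaf in members:
                assignment[leaf] = index
        return assignment


def _newick_escape(label: str) -> str:
    if any(c in label for c in " ():,;'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Merge height equals the unweighted mean pairwise distance between the two
    clusters (maintained with the Lance-Williams average update).  Tied
    candidate pairs are broken by the lexicographically smallest member
    labels, so the result is deterministic.
    """
    labels = [str(l) for l in dist.index]
    if len(labels) < 2:
        raise ValueError("average linkage needs at least 2 items")
    values = dist.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    nodes: dict[tuple[str, ...], DendrogramNode] = {
        (label,): DendrogramNode(0.0, (label,), (), label) for label in labels
    }
    sizes: dict[tuple[str, ...], int] = {key: 1 for key in nodes}
    pair_dist: dict[frozenset[tuple[str, ...]], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            pair_dist[frozenset(((a,), (b,)))] = float(values[i, j])

    while len(nodes) > 1:
        best_pair = None
        best_key = None
        for pair, d in pair_dist.items():
            a, b = sorted(pair)  # members tuples sort lexicographically
            key = (d, a[0], b[0])
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        height = pair_dist.pop(frozenset((a, b)))
        node_a, node_b = nodes.pop(a), nodes.pop(b)
        merged_members = tuple(sorted(a + b))
        children = tuple(sorted((node_a, node_b), key=lambda n: n.members[0]))
        merged = DendrogramNode(height, merged_members, children)
        size_a, size_b = sizes.pop(a), sizes.pop(b)
        for other in list(nodes):
            da = pair_dist.pop(frozenset((a, other)))
            db = pair_dist.pop(frozenset((b, other)))
            pair_dist[frozenset((merged_members, other))] = (
                size_a * da + size_b * db
            ) / (size_a + size_b)
        nodes[merged_members] = merged
        sizes[merged_members] = size_a + size_b

    return Dendrogram(next(iter(nodes.values())))


def cut_tree(dendrogram: Dendrogram, height: float) -> dict[str, int]:
    """Functional alias for :meth:`Dendrogram.cut`."""
    return dendrogram.cut(height)


def classical_mds(dist: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix into ``k`` dimensions.

    Eigendecomposition of the double-centred squared-distance matrix;
    negative eigenvalues (possible for non-Euclidean inputs such as
    Morisita-Horn) are truncated at zero with a warning.  Axis signs are
    fixed by making the first nonzero loading of each axis positive.
    """
    n = len(dist)
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n = {n}, got {k}")
    d = dist.to_numpy(dtype=float)
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ (d**2) @ centering
    eigenvalues, eigenvectors = np.linalg.eigh(gram)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order][:k]
    eigenvectors = eigenvectors[:, order][:, :k]
    if (eigenvalues < -1e-9 * max(1.0, float(np.abs(eigenvalues).max()))).any():
        warnings.warn(
            "negative eigenvalues truncated at 0 (non-Euclidean distances)",
            stacklevel=2,
        )
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    coords = eigenvectors * np.sqrt(eigenvalues)
    for j in range(coords.shape[1]):
        column = coords[:, j]
        nonzero = np.nonzero(np.abs(column) > 1e-12)[0]
        if nonzero.size and column[nonzero[0]] < 0:
            coords[:, j] = -column
    return pd.DataFrame(
        coords, index=dist.index, columns=[f"dim{i + 1}" for i in range(k)]
    )


def export_heatmap(
    matrix: pd.DataFrame,
    metric: str = "morisita-horn",
    out_tsv: str | Path | None = None,
    out_image: str | Path | None = None,
) -> tuple[pd.DataFrame, Dendrogram, Dendrogram]:
    """Reorder a matrix by row/column dendrogram leaf orders and export it.

    Rows (datasets) and columns (features) are each clustered with average
    linkage on ``metric``; the reordered matrix is written as TSV when
    ``out_tsv`` is given and drawn to ``out_image`` (PDF/PNG by extension)
    when requested.  Returns the reordered matrix and both dendrograms.
    """
    row_tree = average_linkage(distance_matrix(matrix, metric))
    col_tree = average_linkage(distance_matrix(matrix.T, metric))
    ordered = matrix.loc[row_tree.leaf_order(), col_tree.leaf_order()]
    if out_tsv is not None:
        ordered.to_csv(out_tsv, sep="\t", float_format="%.10g")
    if out_image is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * ordered.shape[1]), max(3, 0.4 * ordered.shape[0]))
        )
        mesh = ax.pcolormesh(ordered.to_numpy(), cmap="Reds_r")
        ax.set_xticks(np.arange(ordered.shape[1]) + 0.5)
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=7)
        ax.set_yticks(np.arange(ordered.shape[0]) + 0.5)
        ax.set_yticklabels(ordered.index, fontsize=7)
        fig.colorbar(mesh, ax=ax, label="relative abundance")
        fig.tight_layout()
        fig.savefig(out_image)
        plt.close(fig)
    return ordered, row_tree, col_tree


def write_distance_matrix(dist: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    dist.to_csv(path, sep="\t", float_format="%.10g")
    return path
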