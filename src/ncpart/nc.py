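"""Nest-centroid clustering.

A discriminant projection is fitted with nest samples as groups (all axes
kept), per-nest centroids are taken in discriminant space, Euclidean
distances between centroids are computed and displayed as an agglomerative
dendrogram exportable to Newick.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._lda import canonical_axes
from .errors import ValidationError
from .io import MorphoTable

__all__ = [
    "LDProjection",
    "NestCentroidSet",
    "DistanceMatrix",
    "Dendrogram",
    "fit_group_lda",
    "nest_centroids",
    "centroid_distances",
    "build_dendrogram",
    "cut_dendrogram",
    "to_newick",
]

LINKAGES = ("ward", "average", "complete", "single")


@dataclass
class LDProjection:
    scores: pd.DataFrame          # specimen x axis (LD1..LDr)
    loadings: pd.DataFrame        # trait x axis
    eigenvalues: np.ndarray
    group_labels: pd.Series       # per-specimen nest id

    @property
    def axis_count(self) -> int:
        return self.scores.shape[1]


@dataclass
class NestCentroidSet:
    centroids: pd.DataFrame       # nest x axis
    n_individuals: pd.Series      # per nest

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray            # square, symmetric, zero diagonal
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.17g")


@dataclass
class Dendrogram:
    """Merge-list representation of an agglomerative tree.

    Nodes 0..n-1 are leaves in ``leaf_ids`` order; merge i creates node
    n + i from the two child node indices at ``heights[i]``.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int]]
    heights: list[float]
    linkage: str = "average"
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def fit_group_lda(table: MorphoTable | pd.DataFrame, groups: pd.Series | None = None,
                  traits: list[str] | None = None, ridge: float = 0.0) -> LDProjection:
    """Discriminant projection with nest samples as groups, all axes kept.

    Accepts either a MorphoTable (groups default to its nest ids) or a plain
    numeric DataFrame plus explicit group labels.
    """
    if isinstance(table, MorphoTable):
        frame = table.traits(traits, dropna=False)
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()].tolist()
            raise ValidationError(
                f"traits with absent values cannot enter the projection: {bad}")
        if groups is None:
            groups = table.nest_ids
    else:
        frame = table.astype(float)
        if groups is None:
            raise ValidationError("groups are required for a plain data frame")
    groups = pd.Series(groups, index=frame.index).astype(str)
    counts = groups.value_counts()
    if (counts == 0).any():  # pragma: no cover - value_counts never yields 0
        raise ValidationError("empty group")
    n, p = frame.shape
    G = counts.size
    if n - G < p and ridge == 0.0:
        raise ValidationError(
            f"within-group scatter not invertible (n-G={n - G} < p={p}); "
            "enable ridge regularization")
    V, evals, uniq, scores = canonical_axes(frame.to_numpy(float),
                                            groups.to_numpy(), ridge)
    axes = [f"LD{i + 1}" for i in range(V.shape[1])]
    return LDProjection(
        scores=pd.DataFrame(scores, index=frame.index, columns=axes),
        loadings=pd.DataFrame(V, index=frame.columns, columns=axes),
        eigenvalues=evals,
        group_labels=groups,
    )


def nest_centroids(proj: LDProjection) -> NestCentroidSet:
    """Arithmetic mean of each nest's specimen scores."""
    grouped = proj.scores.groupby(proj.group_labels)
    cents = grouped.mean().sort_index()
    counts = grouped.size().sort_index()
    return NestCentroidSet(cents, counts)


def centroid_distances(centroids: NestCentroidSet | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances in full discriminant space."""
    frame = centroids.centroids if isinstance(centroids, NestCentroidSet) else centroids
    if len(frame) < 2:
        raise ValidationError("need at least 2 centroids for a distance matrix")
    X = frame.to_numpy(float)
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    D = np.sqrt(np.maximum(d2, 0.0))
    D = (D + D.T) / 2.0
    return DistanceMatrix([str(i) for i in frame.index], D)


def build_dendrogram(D: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering with explicit lexicographic tie-breaking.

    When several pairs attain the minimal inter-cluster distance, the pair
    whose (sorted) smallest-leaf-id representatives are lexicographically
    smallest is merged first.  Ward heights follow the Euclidean (square
    root) convention.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unsupported linkage {linkage!r}; choose from {LINKAGES}")
    n = len(D.ids)
    if n < 2:
        raise ValidationError("need at least 2 leaves")
    squared = linkage == "ward"
    work = D.values.astype(float) ** 2 if squared else D.values.astype(float).copy()
    np.fill_diagonal(work, np.inf)

    active = list(range(n))                       # current node index per slot
    reps = list(D.ids)                            # smallest leaf id per slot
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int]] = []
    heights: list[float] = []

    for step in range(n - 1):
        masked = np.where(alive[:, None] & alive[None, :], work, np.inf)
        m = masked.min()
        cand = np.argwhere(np.isclose(masked, m, rtol=0.0, atol=0.0))
        pairs = [(i, j) for i, j in cand if i < j]
        i, j = min(pairs, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        hi, hj = active[i], active[j]
        height = float(np.sqrt(m)) if squared else float(m)
        merges.append(tuple(sorted((hi, hj))))
        heights.append(height)

        ni, nj = sizes[i], sizes[j]
        others = np.flatnonzero(alive)
        others = others[(others != i) & (others != j)]
        dik, djk = work[i, others], work[j, others]
        if linkage == "single":
            new = np.minimum(dik, djk)
        elif linkage == "complete":
            new = np.maximum(dik, djk)
        elif linkage == "average":
            new = (ni * dik + nj * djk) / (ni + nj)
        else:  # ward, Lance-Williams on squared distances
            nk = sizes[others]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * work[i, j]) / (ni + nj + nk)
        work[i, others] = new
        work[others, i] = new
        alive[j] = False
        sizes[i] = ni + nj
        active[i] = n + step
        reps[i] = min(reps[i], reps[j])

    return Dendrogram(list(D.ids), merges, heights, linkage)


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Leaf labels (1..k, in order of first appearance) from a k-cluster cut."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range for {n} leaves")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = dend.merges[step]
        node = n + step
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return labels


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _quote(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dend: Dendrogram, annotations: dict[str, str] | None = None,
              separator: str = "-") -> str:
    """Newick text with branch lengths from merge heights.

    A leaf's branch length is its parent's height; an internal node's branch
    is the height difference to its parent.  Annotations are prepended to
    leaf ids, joined by ``separator``.
    """
    ann = annotations if annotations is not None else dend.annotations
    n = dend.n_leaves
    height = [0.0] * n + list(dend.heights)

    def label(leaf: int) -> str:
        lid = dend.leaf_ids[leaf]
        return _quote(f"{ann[lid]}{separator}{lid}") if ann and lid in ann else _quote(lid)

    def render(node: int, parent_h: float) -> str:
        if node < n:
            return f"{label(node)}:{parent_h:.10g}"
        a, b = dend.merges[node - n]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{parent_h - h:.10g}"

    root = 2 * n - 2
    a, b = dend.merges[root - n]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"
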