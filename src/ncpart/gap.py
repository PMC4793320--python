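"""Gap statistic and recursive partitioning.

The number of clusters is estimated by comparing the log within-cluster
dispersion of the data with its expectation under uniform reference sets
drawn in the per-feature bounding box (optionally PCA-rotated).  The recursive partitioner re-runs
the estimate inside every cluster large enough to be split, labels
undersized final clusters as outliers, and two partitions can be reconciled
into congruent/wildcard id sets by maximum-agreement label matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .nc import DistanceMatrix, build_dendrogram, cut_dendrogram

__all__ = [
    "OUTLIER",
    "GapProfile",
    "Partition",
    "CongruenceSet",
    "within_dispersion",
    "gap_statistic",
    "part",
    "congruence",
]

OUTLIER = "OUTLIER"
CLUSTERERS = ("hclust", "kmeans")


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster dispersion W.

    W = sum_r D_r / (2 n_r) with D_r the sum over all ordered pairs of
    squared Euclidean distances inside cluster r; identical to the sum of
    squared distances to cluster centroids, which is how it is computed.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] == 0 or labels.shape[0] != X.shape[0]:
        raise ValidationError("labels must match a non-empty row set")
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        if sub.shape[0] == 0:  # pragma: no cover - unique() never yields empty
            raise ValidationError("empty cluster")
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


# -- base clusterers -------------------------------------------------------

def _kmeans_single(X: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int = 100) -> tuple[np.ndarray, float]:
    """One Lloyd run from a k-means++ initialization."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                far = dist[np.arange(n), new_labels].argmax()
                centers[j] = X[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels, within_dispersion(X, labels)


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
            n_init: int = 10) -> np.ndarray:
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    best_labels, best_w = None, np.inf
    for _ in range(n_init):
        labels, w = _kmeans_single(X, k, rng)
        if w < best_w:
            best_labels, best_w = labels, w
    return best_labels


def _row_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"r{i:0{width}d}" for i in range(n)]


def _hclust_tree(X: np.ndarray, linkage: str):
    n = X.shape[0]
    sq = (X ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    D = DistanceMatrix(_row_ids(n), np.sqrt((d2 + d2.T) / 2.0))
    return build_dendrogram(D, linkage)


def _cluster_all_k(X: np.ndarray, ks: list[int], clusterer: str,
                   rng: np.random.Generator, linkage: str) -> dict[int, np.ndarray]:
    """Labels for each requested k; the hclust tree is built only once."""
    if clusterer == "hclust":
        tree = _hclust_tree(X, linkage) if X.shape[0] > 1 else None
        out = {}
        for k in ks:
            if k == 1 or tree is None:
                out[k] = np.zeros(X.shape[0], dtype=int)
            else:
                out[k] = cut_dendrogram(tree, k)
        return out
    if clusterer == "kmeans":
        return {k: _kmeans(X, k, rng) for k in ks}
    raise ValidationError(f"unknown clusterer {clusterer!r}; choose from {CLUSTERERS}")


# -- gap statistic ---------------------------------------------------------

@dataclass
class GapProfile:
    k: list[int]
    log_w: list[float]
    e_log_w: list[float]
    gap: list[float]
    s: list[float]
    khat: int
    B: int
    clusterer: str
    seed_state: str = ""
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "log_w": self.log_w,
            "e_log_w": self.e_log_w,
            "gap": self.gap,
            "s": self.s,
            "khat": self.khat,
            "B": self.B,
            "clusterer": self.clusterer,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _reference_box(X: np.ndarray, method: str):
    """Sampler for uniform reference data (feature-range box by default;
    "pca" rotates into the principal frame first)."""
    mean = X.mean(axis=0)
    Xc = X - mean
    if method == "pca" and X.shape[0] > 1:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        rot = Xc @ Vt.T
        lo, hi = rot.min(axis=0), rot.max(axis=0)

        def draw(rng: np.random.Generator) -> np.ndarray:
            Z = rng.uniform(lo, hi, size=rot.shape)
            return Z @ Vt + mean
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)

        def draw(rng: np.random.Generator) -> np.ndarray:
            return rng.uniform(lo, hi, size=X.shape)

    return draw


_LOG_FLOOR = 1e-300


def gap_statistic(X: np.ndarray, kmax: int, B: int, clusterer: str = "hclust",
                  rng: np.random.Generator | int | None = None,
                  linkage: str = "ward", reference: str = "range",
                  keep_labels: bool = True) -> GapProfile:
    """Gap profile over k = 1..kmax and the one-SE choice of k.

    gap_k = E*[log W_k] - log W_k over B uniform reference sets;
    s_k = sd_k * sqrt(1 + 1/B); khat is the smallest k with
    gap_k >= gap_{k+1} - s_{k+1}, else kmax.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if kmax < 1:
        raise ValidationError("kmax must be >= 1")
    if kmax > n:
        raise ValidationError(f"kmax={kmax} exceeds number of rows {n}")
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(rng)
    ks = list(range(1, kmax + 1))

    labels_by_k = _cluster_all_k(X, ks, clusterer, rng, linkage)
    log_w = [float(np.log(max(within_dispersion(X, labels_by_k[k]), _LOG_FLOOR)))
             for k in ks]

    draw = _reference_box(X, reference)
    ref_log_w = np.empty((B, kmax))
    for b in range(B):
        Z = draw(rng)
        z_labels = _cluster_all_k(Z, ks, clusterer, rng, linkage)
        for i, k in enumerate(ks):
            ref_log_w[b, i] = np.log(max(within_dispersion(Z, z_labels[k]), _LOG_FLOOR))

    e_log_w = ref_log_w.mean(axis=0)
    sd = ref_log_w.std(axis=0, ddof=0)
    s = sd * np.sqrt(1.0 + 1.0 / B)
    gap = e_log_w - np.asarray(log_w)

    khat = kmax
    for i in range(kmax - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            khat = ks[i]
            break

    return GapProfile(ks, list(map(float, log_w)), list(map(float, e_log_w)),
                      list(map(float, gap)), list(map(float, s)), khat, B,
                      clusterer, labels_by_k=labels_by_k if keep_labels else {})


# -- recursive partitioner -------------------------------------------------

@dataclass
class Partition:
    ids: list[str]
    labels: list[object]          # positive int cluster labels or OUTLIER
    method: str
    min_size: int
    trace: list[dict] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.ids, name="cluster")

    @property
    def n_clusters(self) -> int:
        return len({l for l in self.labels if l != OUTLIER})

    def write_csv(self, path: str | Path) -> None:
        self.as_series().rename_axis("id").to_csv(path)


def part(X: np.ndarray, ids: list[str] | None = None, kmax: int = 15,
         min_size: int = 8, B: int = 1000, clusterer: str = "hclust",
         rng: np.random.Generator | int | None = None, linkage: str = "ward",
         reference: str = "range") -> Partition:
    """Recursive Gap-statistic partitioning with outlier labeling.

    The Gap estimate is re-optimized inside every cluster with at least
    2 * min_size rows; final clusters smaller than min_size become OUTLIER.
    Labels are renumbered 1..K in row order of first appearance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if ids is None:
        ids = _row_ids(n)
    if len(ids) != n:
        raise ValidationError("ids length does not match row count")
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    rng = np.random.default_rng(rng)

    final = np.full(n, -1, dtype=int)   # leaf-cluster key per row
    trace: list[dict] = []
    counter = [0]

    def leaf(idx: np.ndarray) -> None:
        counter[0] += 1
        final[idx] = counter[0]

    def recurse(idx: np.ndarray, path: str) -> None:
        n_sub = len(idx)
        if n_sub < 2 * min_size:
            leaf(idx)
            return
        kmax_sub = max(1, min(kmax, n_sub // min_size, n_sub))
        if kmax_sub < 2:
            leaf(idx)
            return
        prof = gap_statistic(X[idx], kmax_sub, B, clusterer, rng, linkage, reference)
        if prof.khat == 1:
            leaf(idx)
            return
        trace.append({"path": path, "size": int(n_sub), "khat": int(prof.khat),
                      "profile": prof.to_dict()})
        sub_labels = prof.labels_by_k[prof.khat]
        for lab in np.unique(sub_labels):
            child = idx[sub_labels == lab]
            if len(child) >= 2 * min_size:
                recurse(child, f"{path}.{int(lab)}" if path else str(int(lab)))
            else:
                leaf(child)

    recurse(np.arange(n), "")

    sizes = pd.Series(final).value_counts()
    labels: list[object] = []
    renum: dict[int, int] = {}
    for key in final:
        if sizes[key] < min_size:
            labels.append(OUTLIER)
        else:
            if key not in renum:
                renum[key] = len(renum) + 1
            labels.append(renum[key])
    return Partition([str(i) for i in ids], labels, f"part-{clusterer}",
                     min_size, trace)


# -- congruence between two partitions ------------------------------------

@dataclass
class CongruenceSet:
    congruent_ids: list[str]
    wildcard_ids: list[str]
    mapping: dict[object, object]   # p2 label -> matched p1 label

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "congruent_ids": self.congruent_ids,
            "wildcard_ids": self.wildcard_ids,
            "label_mapping": {str(k): str(v) for k, v in self.mapping.items()},
        }, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def congruence(p1: Partition, p2: Partition) -> CongruenceSet:
    """Ids classified identically by two partitions after label matching.

    Labels of ``p2`` are matched to ``p1`` by Hungarian assignment on the
    contingency table (maximum agreement).  Ids that are OUTLIER in either
    partition, or whose matched labels disagree, are wildcards.
    """
    if set(p1.ids) != set(p2.ids):
        raise ValidationError("partitions cover different id sets")
    s1 = p1.as_series()
    s2 = p2.as_series().reindex(s1.index)

    l1 = sorted({l for l in s1 if l != OUTLIER})
    l2 = sorted({l for l in s2 if l != OUTLIER})
    cont = np.zeros((len(l2), len(l1)))
    i1 = {l: i for i, l in enumerate(l1)}
    i2 = {l: i for i, l in enumerate(l2)}
    for a, b in zip(s2, s1):
        if a != OUTLIER and b != OUTLIER:
            cont[i2[a], i1[b]] += 1
    mapping: dict[object, object] = {}
    if cont.size:
        rows, cols = linear_sum_assignment(-cont)
        mapping = {l2[r]: l1[c] for r, c in zip(rows, cols)}

    congruent, wildcard = [], []
    for sid in s1.index:
        a, b = s2[sid], s1[sid]
        if a != OUTLIER and b != OUTLIER and mapping.get(a) == b:
            congruent.append(str(sid))
        else:
            wildcard.append(str(sid))
    return CongruenceSet(congruent, wildcard, mapping)
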