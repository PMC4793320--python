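"""Shared linear discriminant machinery.

Two faces of the same model: canonical discriminant axes (used for the
nest-grouped projection) and a pooled-covariance Gaussian classifier (used
for confirmation, wildcards and ratio powers).  Scores from the canonical
axes follow the sphering convention: pooled within-group variance 1 on each
axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import NumericError, ValidationError

__all__ = ["canonical_axes", "GaussianLDA", "pooled_within_cov"]


def _group_stats(X: np.ndarray, groups: np.ndarray):
    uniq, inv = np.unique(groups, return_inverse=True)
    G = len(uniq)
    n, p = X.shape
    counts = np.bincount(inv, minlength=G).astype(float)
    sums = np.zeros((G, p))
    np.add.at(sums, inv, X)
    means = sums / counts[:, None]
    return uniq, inv, counts, means


def pooled_within_cov(X: np.ndarray, groups: np.ndarray, ridge: float = 0.0):
    """Pooled within-group covariance with divisor n - G, plus group stats."""
    uniq, inv, counts, means = _group_stats(X, groups)
    n, p = X.shape
    G = len(uniq)
    resid = X - means[inv]
    df = n - G
    if df <= 0 and ridge == 0.0:
        raise ValidationError(
            f"no within-group degrees of freedom (n={n}, groups={G}); "
            "enable ridge regularization")
    Sw = resid.T @ resid / max(df, 1)
    if ridge > 0.0:
        Sw = Sw + ridge * np.eye(p)
    return Sw, uniq, inv, counts, means


def canonical_axes(X: np.ndarray, groups: np.ndarray, ridge: float = 0.0):
    """All canonical discriminant axes for grouped data.

    Returns (loadings p x r, eigenvalues r, group_ids, scores n x r) with
    r = min(G - 1, p).  Loadings satisfy v' Sw v = 1 (sphering); axis signs
    are fixed so the largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    Sw, uniq, inv, counts, means = pooled_within_cov(X, groups, ridge)
    G = len(uniq)
    if G < 2:
        raise ValidationError("need at least 2 groups for a discriminant analysis")
    grand = X.mean(axis=0)
    dm = means - grand
    Sb = (dm * counts[:, None]).T @ dm

    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise NumericError(
            "within-group scatter is singular; enable ridge regularization "
            f"(ridge > 0): {exc}") from None
    order = np.argsort(evals)[::-1]
    r = min(G - 1, p)
    evals = np.maximum(evals[order][:r], 0.0)
    V = evecs[:, order][:, :r]
    # deterministic sign: largest-|loading| entry positive per axis
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    scores = (X - grand) @ V
    return V, evals, uniq, scores


@dataclass
class GaussianLDA:
    """Pooled-covariance Gaussian classifier (classic LDA).

    Equal class priors by default; ``priors="proportional"`` weighs by class
    size.  ``ridge`` adds a diagonal to the pooled covariance.
    """

    priors: str = "equal"
    ridge: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianLDA":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        Sw, classes, inv, counts, means = pooled_within_cov(X, y, self.ridge)
        try:
            chol = linalg.cho_factor(Sw, lower=True)
        except linalg.LinAlgError:
            raise NumericError(
                "singular pooled within-class covariance; enable ridge "
                "regularization (ridge > 0)") from None
        self.classes_ = classes
        self.means_ = means
        self._chol = chol
        if self.priors == "equal":
            self.log_priors_ = np.full(len(classes), -np.log(len(classes)))
        elif self.priors == "proportional":
            self.log_priors_ = np.log(counts / counts.sum())
        else:
            raise ValidationError(f"unknown priors setting {self.priors!r}")
        return self

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = np.empty((X.shape[0], len(self.classes_)))
        for j, mu in enumerate(self.means_):
            d = X - mu
            z = linalg.cho_solve(self._chol, d.T)
            out[:, j] = -0.5 * np.einsum("ij,ji->i", d, z) + self.log_priors_[j]
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lj = self.log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.log_joint(X), axis=1)]
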