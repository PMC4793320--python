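"""Ratio extraction for identification keys and diagnoses.

Operationalizes "classification power" between two taxa as the LOOCV-LDA
percent correct on one or two trait ratios at the individual level, searches
exhaustively for the best-separating ratio, and fits reduced linear
discriminant functions on raw trait subsets whose score sign splits the two
classes.  This is an operational surrogate for the full multivariate ratio
analysis machinery: it reproduces ratio identities and percent-correct
values without the isometric size axis or allometry correction.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .confirm import loocv_lda
from .errors import ValidationError
from .io import MorphoTable

__all__ = [
    "RatioPower",
    "RatioPairPower",
    "DFunction",
    "D4_PRINTED",
    "ratio_power",
    "ratio_pair_power",
    "best_ratio_search",
    "reduced_discriminant",
    "evaluate_dfunction",
]


def _trait_frame(X) -> pd.DataFrame:
    if isinstance(X, MorphoTable):
        return X.traits()
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    raise ValidationError("expected a MorphoTable or a trait DataFrame")


def _two_classes(labels: pd.Series) -> list[str]:
    classes = sorted(labels.astype(str).unique())
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {classes}")
    return classes


@dataclass
class RatioPower:
    numerator: str
    denominator: str
    classes: list[str]
    class_means: dict[str, float]
    class_ranges: dict[str, tuple[float, float]]
    percent_correct: float
    threshold: float
    separation: float = 0.0      # standardized mean separation, used for ties

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    def key_text(self) -> str:
        """Key-couplet style line per class."""
        lines = []
        for c in self.classes:
            lo, hi = self.class_ranges[c]
            lines.append(f"{c}: {self.name} = {self.class_means[c]:.3f} "
                         f"[{lo:.3f}, {hi:.3f}] ({self.percent_correct:.1f}%)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ratio": self.name,
            "classes": self.classes,
            "class_means": self.class_means,
            "class_ranges": {c: list(r) for c, r in self.class_ranges.items()},
            "percent_correct": self.percent_correct,
            "threshold": self.threshold,
        }


@dataclass
class RatioPairPower:
    ratio1: str
    ratio2: str
    classes: list[str]
    percent_correct: float
    coordinates: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {"ratios": [self.ratio1, self.ratio2], "classes": self.classes,
                "percent_correct": self.percent_correct}


def _ratio_values(frame: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    for code in (numerator, denominator):
        if code not in frame.columns:
            raise ValidationError(f"trait {code!r} not present")
    if numerator == denominator:
        raise ValidationError("numerator and denominator must differ")
    vals = frame[numerator] / frame[denominator]
    if vals.isna().any():
        raise ValidationError(
            f"ratio {numerator}/{denominator} undefined for some specimens")
    return vals


def _fast_loocv_two_class_1d(x: np.ndarray, y: np.ndarray,
                             classes: list[str]) -> float:
    """Vectorized LOOCV percent correct of equal-prior 1-D pooled-variance LDA.

    With a shared variance the rule reduces to nearest leave-one-out class
    mean; identical to the generic LOOCV path, just without the n model fits.
    """
    m = {}
    for c in classes:
        mask = y == c
        s, n = x[mask].sum(), mask.sum()
        mu = np.where(mask, (s - x) / (n - 1), s / n)
        m[c] = mu
    d0 = np.abs(x - m[classes[0]])
    d1 = np.abs(x - m[classes[1]])
    pred = np.where(d0 <= d1, classes[0], classes[1])  # tie -> first class
    return 100.0 * float((pred == y).mean())


def ratio_power(X, labels, numerator: str, denominator: str) -> RatioPower:
    """LOOCV-LDA percent correct of a single trait ratio between two classes."""
    frame = _trait_frame(X)
    labels = pd.Series(labels, index=frame.index).astype(str)
    classes = _two_classes(labels)
    vals = _ratio_values(frame, numerator, denominator)

    result = loocv_lda(vals.to_frame("ratio"), labels)
    means = {c: float(vals[labels == c].mean()) for c in classes}
    ranges = {c: (float(vals[labels == c].min()), float(vals[labels == c].max()))
              for c in classes}
    threshold = (means[classes[0]] + means[classes[1]]) / 2.0
    pooled_sd = _pooled_sd(vals, labels, classes)
    sep = abs(means[classes[0]] - means[classes[1]]) / pooled_sd if pooled_sd > 0 else np.inf
    return RatioPower(numerator, denominator, classes, means, ranges,
                      result.overall_percent, float(threshold), float(sep))


def _pooled_sd(vals: pd.Series, labels: pd.Series, classes: list[str]) -> float:
    ss, df = 0.0, 0
    for c in classes:
        sub = vals[labels == c]
        ss += float(((sub - sub.mean()) ** 2).sum())
        df += len(sub) - 1
    return np.sqrt(ss / df) if df > 0 else 0.0


def ratio_pair_power(X, labels, ratio1: tuple[str, str],
                     ratio2: tuple[str, str]) -> RatioPairPower:
    """LOOCV-LDA percent correct of two ratios jointly.

    Collinear ratios (|correlation| = 1) fall back to the single-ratio power
    with a warning.
    """
    frame = _trait_frame(X)
    labels = pd.Series(labels, index=frame.index).astype(str)
    classes = _two_classes(labels)
    v1 = _ratio_values(frame, *ratio1)
    v2 = _ratio_values(frame, *ratio2)
    name1, name2 = f"{ratio1[0]}/{ratio1[1]}", f"{ratio2[0]}/{ratio2[1]}"

    r = np.corrcoef(v1, v2)[0, 1]
    coords = pd.DataFrame({name1: v1, name2: v2, "class": labels})
    if abs(r) >= 1.0 - 1e-10:
        warnings.warn(f"ratios {name1} and {name2} are collinear; "
                      "falling back to a single-ratio discriminant")
        single = ratio_power(X, labels, *ratio1)
        return RatioPairPower(name1, name2, classes, single.percent_correct, coords)
    result = loocv_lda(coords[[name1, name2]], labels)
    return RatioPairPower(name1, name2, classes, result.overall_percent, coords)


def best_ratio_search(X, labels, candidate_traits: list[str]) -> list[RatioPower]:
    """Exhaustive single-ratio search between two classes, ranked by power.

    One orientation per unordered trait pair: the one whose first-class mean
    exceeds the second-class mean.  Ties in percent correct are broken by the
    larger standardized mean separation, then by ratio name.
    """
    if len(candidate_traits) < 3:
        raise ValidationError("need at least 3 candidate traits")
    frame = _trait_frame(X)
    labels = pd.Series(labels, index=frame.index).astype(str)
    classes = _two_classes(labels)
    y = labels.to_numpy()

    results: list[RatioPower] = []
    for a, b in itertools.combinations(candidate_traits, 2):
        vals = _ratio_values(frame, a, b)
        num, den = a, b
        if vals[labels == classes[0]].mean() < vals[labels == classes[1]].mean():
            num, den = b, a
            vals = 1.0 / vals
        means = {c: float(vals[labels == c].mean()) for c in classes}
        ranges = {c: (float(vals[labels == c].min()), float(vals[labels == c].max()))
                  for c in classes}
        pct = _fast_loocv_two_class_1d(vals.to_numpy(float), y, classes)
        pooled = _pooled_sd(vals, labels, classes)
        sep = abs(means[classes[0]] - means[classes[1]]) / pooled if pooled > 0 else np.inf
        results.append(RatioPower(num, den, classes, means, ranges, pct,
                                  (means[classes[0]] + means[classes[1]]) / 2.0,
                                  float(sep)))
    results.sort(key=lambda r: (-r.percent_correct, -r.separation, r.name))
    return results


@dataclass
class DFunction:
    """Linear discriminant score on raw traits: sum(coef * trait) + intercept."""

    traits: list[str]
    coefficients: list[float]
    intercept: float
    classes: list[str] = field(default_factory=list)
    class_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    percent_correct: float | None = None
    positive_class: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "traits": self.traits,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "classes": self.classes,
            "class_stats": self.class_stats,
            "percent_correct": self.percent_correct,
            "positive_class": self.positive_class,
        }, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


#: Published four-trait reduced discriminant separating the two most similar
#: species (positive scores -> bidentatus); kept frozen for verification.
D4_PRINTED = DFunction(
    traits=["ML", "CW", "SPBA", "SPST"],
    coefficients=[0.062581, -0.052596, -0.095374, -0.042818],
    intercept=6.642672,
    classes=["bidentatus", "fragilis"],
    positive_class="bidentatus",
)


def reduced_discriminant(X, labels, traits: list[str]) -> DFunction:
    """Two-class LDA on a raw-trait subset with the midpoint intercept rule.

    Coefficients are scaled to unit pooled within-class variance of scores;
    the intercept places the two class score means symmetric about 0, with
    the alphabetically first class on the positive side.
    """
    if len(traits) < 1:
        raise ValidationError("trait subset must not be empty")
    frame = _trait_frame(X)[list(traits)]
    labels = pd.Series(labels, index=frame.index).astype(str)
    classes = _two_classes(labels)
    Xa = frame.to_numpy(float)
    y = labels.to_numpy()

    m1 = Xa[y == classes[0]].mean(axis=0)
    m2 = Xa[y == classes[1]].mean(axis=0)
    n1, n2 = (y == classes[0]).sum(), (y == classes[1]).sum()
    resid = np.vstack([Xa[y == classes[0]] - m1, Xa[y == classes[1]] - m2])
    Sw = resid.T @ resid / (n1 + n2 - 2)
    try:
        w = np.linalg.solve(Sw, m1 - m2)
    except np.linalg.LinAlgError:
        raise ValidationError("singular within-class scatter for this trait subset")
    norm = float(np.sqrt(w @ Sw @ w))
    if norm == 0:
        raise ValidationError("degenerate discriminant (identical class means)")
    w = w / norm
    if w @ (m1 - m2) < 0:
        w = -w
    intercept = -float(w @ (m1 + m2) / 2.0)

    scores = Xa @ w + intercept
    stats = {}
    for c in classes:
        sc = scores[y == c]
        stats[c] = {"mean": float(sc.mean()), "min": float(sc.min()),
                    "max": float(sc.max())}
    pct = loocv_lda(frame, labels).overall_percent
    return DFunction(list(traits), [float(v) for v in w], intercept,
                     classes, stats, pct, positive_class=classes[0])


def evaluate_dfunction(df: DFunction, specimens) -> pd.Series:
    """Scores of a linear discriminant function for one or more specimens."""
    if isinstance(specimens, MorphoTable):
        frame = specimens.data
    elif isinstance(specimens, pd.Series):
        frame = specimens.to_frame().T
    elif isinstance(specimens, dict):
        frame = pd.DataFrame([specimens])
    else:
        frame = pd.DataFrame(specimens)
    missing = [t for t in df.traits if t not in frame.columns]
    if missing:
        raise ValidationError(f"missing traits for discriminant score: {missing}")
    block = frame[df.traits].astype(float)
    if block.isna().any().any():
        bad = block.index[block.isna().any(axis=1)].tolist()
        raise ValidationError(f"absent trait values for specimens: {bad}")
    vals = block.to_numpy() @ np.asarray(df.coefficients) + df.intercept
    return pd.Series(vals, index=frame.index, name="score")
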