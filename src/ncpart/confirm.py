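"""Confirmatory leave-one-out cross-validated LDA with wildcard assignment.

Imposed class hypotheses are evaluated specimen by specimen: each labeled
specimen is predicted by a discriminant model trained on all other labeled
specimens (equal priors by default).  Specimens without a hypothesis
("wildcards") are assigned from the full labeled model and reported with
posterior probabilities; they never enter the confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._lda import GaussianLDA
from .errors import ValidationError

__all__ = ["WILDCARD", "ClassificationResult", "loocv_lda", "wildcard_assign"]

WILDCARD = "WILDCARD"


@dataclass
class ClassificationResult:
    classes: list[str]
    confusion: pd.DataFrame            # rows imposed, cols predicted
    per_class_percent: pd.Series
    overall_percent: float
    posteriors: pd.DataFrame           # labeled specimens x classes
    predictions: pd.Series             # labeled specimens
    wildcard_predictions: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    wildcard_posteriors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def confusion_with_percent(self) -> pd.DataFrame:
        """Confusion matrix with a trailing percent.correct column."""
        out = self.confusion.copy()
        out["percent.correct"] = self.per_class_percent.round(1)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": self.classes,
            "confusion": {c: self.confusion.loc[c].to_dict() for c in self.classes},
            "per_class_percent": self.per_class_percent.to_dict(),
            "overall_percent": self.overall_percent,
            "wildcards": {
                str(i): {
                    "predicted": str(self.wildcard_predictions[i]),
                    "posterior": self.wildcard_posteriors.loc[i].to_dict(),
                }
                for i in self.wildcard_predictions.index
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr)


def _assemble(frame: pd.DataFrame, labels: pd.Series, preds: pd.Series,
              post: pd.DataFrame, classes: list[str]) -> ClassificationResult:
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for true, pred in zip(labels, preds):
        confusion.loc[true, pred] += 1
    sizes = confusion.sum(axis=1)
    per_class = 100.0 * pd.Series(np.diag(confusion), index=classes) / sizes
    overall = 100.0 * np.trace(confusion.to_numpy()) / len(labels)
    return ClassificationResult(classes, confusion, per_class, float(overall),
                                post, preds)


def loocv_lda(X, labels, priors: str = "equal", ridge: float = 0.0) -> ClassificationResult:
    """Leave-one-out cross-validated LDA on labeled specimens.

    Every class needs >= 2 specimens (a singleton cannot be left out and
    still trained on).
    """
    frame = _as_frame(X)
    labels = pd.Series(labels, index=frame.index).astype(str)
    if labels.isna().any():
        raise ValidationError("labels must be present for every specimen")
    counts = labels.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        raise ValidationError(f"classes with a single specimen cannot be "
                              f"cross-validated: {small}")
    classes = sorted(counts.index)
    Xa = frame.to_numpy(float)
    ya = labels.to_numpy()
    n = len(frame)

    preds = np.empty(n, dtype=object)
    post = np.zeros((n, len(classes)))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = GaussianLDA(priors=priors, ridge=ridge).fit(Xa[mask], ya[mask])
        pr = model.predict_proba(Xa[i:i + 1])[0]
        # model class order can differ from the global one if a class empties
        for c, p in zip(model.classes_, pr):
            post[i, classes.index(c)] = p
        preds[i] = model.classes_[np.argmax(pr)]
        mask[i] = True

    preds_s = pd.Series(preds, index=frame.index, name="predicted")
    post_df = pd.DataFrame(post, index=frame.index, columns=classes)
    return _assemble(frame, labels, preds_s, post_df, classes)


def wildcard_assign(X, labels_partial, priors: str = "equal",
                    ridge: float = 0.0) -> ClassificationResult:
    """LOOCV on labeled specimens plus posterior assignment of wildcards.

    ``labels_partial`` holds a class per specimen or WILDCARD (None/NaN also
    count as wildcard).  Wildcard posteriors come from the model trained on
    all labeled specimens.
    """
    frame = _as_frame(X)
    labels = pd.Series(labels_partial, index=frame.index, dtype=object)
    is_wild = labels.isna() | (labels == WILDCARD)
    if not is_wild.any():
        raise ValidationError("no wildcard specimens; use loocv_lda instead")
    labeled = frame.loc[~is_wild]
    if labels.loc[~is_wild].astype(str).nunique() < 2:
        raise ValidationError("need at least 2 labeled classes")

    result = loocv_lda(labeled, labels.loc[~is_wild].astype(str), priors, ridge)

    model = GaussianLDA(priors=priors, ridge=ridge).fit(
        labeled.to_numpy(float), labels.loc[~is_wild].astype(str).to_numpy())
    wild = frame.loc[is_wild]
    probs = model.predict_proba(wild.to_numpy(float))
    result.wildcard_posteriors = pd.DataFrame(probs, index=wild.index,
                                              columns=list(model.classes_))
    result.wildcard_predictions = pd.Series(
        model.classes_[np.argmax(probs, axis=1)], index=wild.index,
        name="predicted")
    return result
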