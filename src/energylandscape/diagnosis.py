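"""Diagnosis prediction from dynamics indices.

Univariate rule: cutoff = (min of the TD group + max of the ASD group) / 2
on a single index; the classification direction (which side is called ASD)
is taken from the training group means, not hard-coded.  Bivariate rule: a
linear soft-margin support vector machine on (intermediate-state
frequency, indirect-transition frequency).  Both are trained on one cohort
and evaluated on independent cohorts by sensitivity and specificity with
ASD as the positive class; scoring on the training cohort is refused
unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "Classifier",
    "univariate_cutoff",
    "build_univariate_classifier",
    "bivariate_boundary",
    "evaluate_classifier",
]


@dataclass
class Classifier:
    """Trained diagnostic rule (univariate cutoff or linear boundary).

    For ``kind='univariate'``: ``threshold`` with ``asd_below`` giving the
    direction.  For ``kind='bivariate'``: ``weights``/``bias`` of the
    linear decision function, positive scores classified ASD.
    ``training_ids`` fingerprint the training cohort for train/test
    separation.
    """

    kind: str
    threshold: float | None = None
    asd_below: bool = True
    weights: np.ndarray | None = None
    bias: float | None = None
    training_ids: frozenset = field(default_factory=frozenset)
    metadata: dict = field(default_factory=dict)

    def predict_asd(self, x: np.ndarray) -> np.ndarray:
        """Boolean ASD predictions for feature rows (or scalars)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "univariate":
            vals = x.ravel()
            return vals < self.threshold if self.asd_below else vals > self.threshold
        if self.kind == "bivariate":
            scores = np.atleast_2d(x) @ self.weights + self.bias
            return scores > 0
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "threshold": self.threshold,
                "asd_below": self.asd_below,
                "weights": None if self.weights is None else self.weights.tolist(),
                "bias": self.bias,
                "metadata": self.metadata,
            },
            indent=2,
        )


def univariate_cutoff(td_values: np.ndarray, asd_values: np.ndarray) -> float:
    """Midpoint cutoff ((min of TD) + (max of ASD)) / 2.

    Appropriate for indices that are lower in the ASD group, where the TD
    minimum and ASD maximum bracket the overlap region.
    """
    td_values = np.asarray(td_values, dtype=float)
    asd_values = np.asarray(asd_values, dtype=float)
    if td_values.size == 0 or asd_values.size == 0:
        raise ValueError("both groups must be non-empty")
    return float((td_values.min() + asd_values.max()) / 2.0)


def build_univariate_classifier(
    td_values: np.ndarray,
    asd_values: np.ndarray,
    training_ids=(),
    name: str = "",
) -> Classifier:
    """Univariate midpoint classifier with direction from group means."""
    thr = univariate_cutoff(td_values, asd_values)
    asd_below = bool(np.mean(asd_values) < np.mean(td_values))
    return Classifier(
        kind="univariate",
        threshold=thr,
        asd_below=asd_below,
        training_ids=frozenset(training_ids),
        metadata={"index": name},
    )


def bivariate_boundary(
    features: np.ndarray,
    is_asd: np.ndarray,
    c: float = 1.0,
    training_ids=(),
) -> Classifier:
    """Linear soft-margin SVM boundary on two dynamics indices.

    Deterministic for fixed inputs; the regularization constant C defaults
    to 1 and is configurable.  Positive decision scores are mapped to the
    ASD class regardless of which side the margin fit put them on.
    """
    features = np.asarray(features, dtype=float)
    is_asd = np.asarray(is_asd, dtype=bool)
    if features.ndim != 2 or features.shape[1] != 2:
        raise ValueError("features must be n x 2")
    if is_asd.all() or (~is_asd).all():
        raise ValueError("both classes must be present in training data")
    svm = SVC(kernel="linear", C=c)
    svm.fit(features, is_asd.astype(int))
    w = svm.coef_.ravel().copy()
    b = float(svm.intercept_[0])
    # sklearn's positive decision side is class 1 == ASD already, but keep
    # the orientation explicit in case of label inversion
    if svm.classes_[1] != 1:
        w, b = -w, -b
    if np.allclose(w, 0.0):
        raise ValueError("degenerate SVM fit: zero weight vector")
    return Classifier(
        kind="bivariate",
        weights=w,
        bias=b,
        training_ids=frozenset(training_ids),
        metadata={"C": c},
    )


def evaluate_classifier(
    clf: Classifier,
    features: np.ndarray,
    is_asd: np.ndarray,
    participant_ids=None,
    allow_train_overlap: bool = False,
) -> tuple[float, float]:
    """Sensitivity and specificity on a test cohort (ASD positive).

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP).  If a
    class is absent from the test set the corresponding metric is NaN.
    When ``participant_ids`` overlap the classifier's training cohort the
    call is refused unless ``allow_train_overlap=True`` (the design
    evaluates on independent cohorts).
    """
    if participant_ids is not None and not allow_train_overlap:
        overlap = clf.training_ids & set(participant_ids)
        if overlap:
            raise ValueError(
                f"test cohort overlaps the training cohort ({sorted(overlap)[:5]}...); "
                "pass allow_train_overlap=True to score anyway"
            )
    is_asd = np.asarray(is_asd, dtype=bool)
    pred = clf.predict_asd(features)
    tp = int(np.sum(pred & is_asd))
    fn = int(np.sum(~pred & is_asd))
    tn = int(np.sum(~pred & ~is_asd))
    fp = int(np.sum(pred & ~is_asd))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec
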