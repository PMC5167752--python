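"""Condition classification and repeatability statistics.

A linear support vector machine separates Target from Novel feature
vectors; the signed distance of each observation from the separating
hyperplane is the classification score, summarized by the area under the
ROC curve.  Test-retest repeatability of single features is measured with
the one-way random-effects intraclass correlation coefficient,
ICC = (MSb - MSw) / (MSb + (k - 1) MSw), where each subject is one ANOVA
group and k is the number of visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .errors import (
    ColumnMismatchError,
    MissingCellError,
    SingleClassError,
    SubjectMismatchError,
)
from .scoring import FeatureTable

#: Default SVM regularization constant: a deliberately small C
#: (10 ** -3.5) to avoid overfitting the high-dimensional feature set.
DEFAULT_C = 10.0 ** -3.5

POSITIVE_LABEL = "Target"


@dataclass
class ClassifierModel:
    """Trained linear SVM: one weight per feature column plus a bias.

    Scores are oriented so that positive means the positive class
    (``Target`` by default).
    """

    weights: pd.Series
    bias: float
    C: float
    positive_label: str
    negative_label: str
    metadata: dict = field(default_factory=dict)


def train_svm(
    features: FeatureTable,
    C: float = DEFAULT_C,
    positive_label: str = POSITIVE_LABEL,
    metadata: dict | None = None,
) -> ClassifierModel:
    """Fit a linear max-margin classifier on (scaled) features.

    Deterministic: the dual solver runs to tolerance 1e-6 with no random
    subsampling.  Labels come from the table's condition column.
    """
    labels = features.labels
    present = sorted(labels.unique())
    if len(present) < 2:
        raise SingleClassError(f"need two classes, got {present}")
    if len(present) > 2:
        raise ValueError(f"binary classification only, got {present}")
    if positive_label not in present:
        raise ValueError(f"positive label {positive_label!r} absent")
    negative = next(c for c in present if c != positive_label)
    clf = SVC(kernel="linear", C=C, tol=1e-6)
    X = features.values.to_numpy()
    clf.fit(X, labels.to_numpy())
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # SVC orients the decision function toward classes_[1]
    if clf.classes_[1] != positive_label:
        w, b = -w, -b
    return ClassifierModel(
        weights=pd.Series(w, index=features.values.columns),
        bias=b,
        C=C,
        positive_label=positive_label,
        negative_label=negative,
        metadata=metadata or {},
    )


def decision_scores(model: ClassifierModel, features: FeatureTable) -> pd.Series:
    """Signed distance of each row from the separating hyperplane
    (positive side = positive class)."""
    cols = list(model.weights.index)
    missing = [c for c in cols if c not in features.values.columns]
    if missing:
        raise ColumnMismatchError(f"feature columns missing: {missing[:5]}...")
    X = features.values[cols].to_numpy()
    raw = X @ model.weights.to_numpy() + model.bias
    norm = float(np.linalg.norm(model.weights.to_numpy()))
    if norm > 0:
        raw = raw / norm
    return pd.Series(raw, index=features.values.index)


def roc_auc(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    positive_label: str = POSITIVE_LABEL,
) -> tuple[np.ndarray, float]:
    """ROC operating points and the area under the curve.

    AUC equals the probability that a random positive outranks a random
    negative, with ties counted one half.
    """
    y = np.asarray(labels) == positive_label
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise SingleClassError("both classes required for ROC")
    fpr, tpr, _ = skmetrics.roc_curve(y, s)
    auc = float(skmetrics.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class IccResult:
    value: float
    ms_between: float
    ms_within: float
    k: int
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def icc(values: np.ndarray) -> IccResult:
    """One-way random-effects intraclass correlation of a subject x visit
    matrix.

    Each subject is one ANOVA group; MSb and MSw are the between- and
    within-subject mean squares.  A table with zero variance everywhere is
    degenerate and reported as 0 with a flag.  Negative values are returned
    as computed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (visits >= 2) matrix")
    if np.isnan(x).any():
        raise MissingCellError("missing cells in repeatability table")
    n, k = x.shape
    subj_means = x.mean(axis=1)
    grand = x.mean()
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((x - subj_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0.0:
        return IccResult(value=0.0, ms_between=msb, ms_within=msw, k=k,
                         degenerate=True)
    return IccResult(value=float((msb - msw) / denom),
                     ms_between=float(msb), ms_within=float(msw), k=k)


def repeatability_report(tables: list[FeatureTable]) -> pd.DataFrame:
    """Per-feature ICC across visits.

    Each table holds one visit of the same subjects (same condition, same
    feature columns).  Returns a data frame indexed by feature with columns
    MSb, MSw, k, icc and degenerate.
    """
    if len(tables) < 2:
        raise ValueError("need at least two visits")
    ref = tables[0]

    def keys(t):  # observations align on (subject, condition), not visit
        return t.meta["subject"] + "|" + t.meta["condition"]

    subjects = list(keys(ref))
    cols = list(ref.values.columns)
    if len(set(subjects)) != len(subjects):
        raise SubjectMismatchError("duplicate subject/condition rows")
    mats = []
    for t in tables:
        if list(t.values.columns) != cols:
            raise ColumnMismatchError("feature columns differ across visits")
        if sorted(keys(t)) != sorted(subjects):
            raise SubjectMismatchError("subjects differ across visits")
        v = t.values.copy()
        v.index = keys(t)
        mats.append(v.loc[subjects])
    k = len(tables)
    rows = []
    for c in cols:
        m = np.column_stack([mat[c].to_numpy() for mat in mats])
        r = icc(m)
        rows.append((r.ms_between, r.ms_within, r.k, r.value, r.degenerate))
    return pd.DataFrame(rows, index=cols,
                        columns=["MSb", "MSw", "k", "icc", "degenerate"])
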