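"""Leave-one-out SVM evaluation of the six pipeline variants.

With only a few dozen specimens per study, the classical protocol for this
kind of bone-image work is a linear SVM scored by leave-one-out
cross-validation (LOOCV).  Six feature pipelines are compared:

======  ==========================================================
TNS     plain direction-averaged texture only
TSNS    plain direction-averaged texture + shape
TYS     variation-coefficient weighted texture only
TSYS    weighted texture + shape
TSYLS   Lasso-selected subset of the TSYS features
TSYLC   dispersion-penalized (convex-model) subset of the TSYS features
======  ==========================================================

The positive class is the disease state (OVX), so sensitivity is the
osteoporosis detection rate.  Features are standardized inside each
training fold only; confusion counts are pooled over folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .selection import DispersionLasso

__all__ = [
    "VARIANTS",
    "ClassificationReport",
    "metrics",
    "youden",
    "loocv_svm",
    "run_variant",
    "run_all_variants",
]

VARIANTS = ("TNS", "TSNS", "TYS", "TSYS", "TSYLS", "TSYLC")


@dataclass(frozen=True)
class ClassificationReport:
    """Pooled LOOCV confusion counts and derived rates."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sen(self) -> float:
        return metrics(self.tp, self.tn, self.fp, self.fn)[1]

    @property
    def spe(self) -> float:
        return metrics(self.tp, self.tn, self.fp, self.fn)[2]

    @property
    def yi(self) -> float:
        return youden(self.sen, self.spe)

    def as_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
                "ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
                "YI": self.yi}


def metrics(tp: int, tn: int, fp: int, fn: int):
    """Accuracy, sensitivity (recall on positives) and specificity."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion table")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a class is absent: SEN/SPE undefined")
    return (tp + tn) / n, tp / (tp + fn), tn / (tn + fp)


def youden(sen: float, spe: float) -> float:
    """Youden's index J = SEN + SPE - 1."""
    if not (0 <= sen <= 1 and 0 <= spe <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sen + spe - 1


def _coerce_labels(y) -> np.ndarray:
    """Map two-class labels to +/-1 with the positive class = OVX.

    String labels: 'OVX' (case-insensitive) is positive when present,
    otherwise the first sorted value.  Numeric +/-1 passed through.
    """
    y = np.asarray(y)
    values = np.unique(y)
    if values.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if set(values.tolist()) == {-1, 1}:
        return y.astype(int)
    vals = [str(v).upper() for v in values]
    pos = values[vals.index("OVX")] if "OVX" in vals else values[0]
    return np.where(y == pos, 1, -1)


def loocv_svm(features, labels, C: float = 1.0) -> ClassificationReport:
    """Pooled-confusion LOOCV with a linear SVM.

    Each sample is predicted by an SVM trained on the other n-1 samples;
    standardization statistics come from the training fold only, so no
    information leaks from the held-out sample.  Deterministic.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _coerce_labels(labels)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    if y.size != n:
        raise ValueError("features and labels disagree on sample count")

    tp = tn = fp = fn = 0
    for i in range(n):
        train = np.ones(n, bool)
        train[i] = False
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            raise ValueError("a training fold lost a class")
        X_tr = X[train]
        mean = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X_tr - mean) / sd, y_tr)
        pred = int(clf.predict(((X[i] - mean) / sd)[None, :])[0])
        if y[i] == 1:
            tp += pred == 1
            fn += pred != 1
        else:
            tn += pred == -1
            fp += pred != -1
    return ClassificationReport(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def _variant_matrix(tag, texture_simple, texture_weighted, shape):
    tag = tag.upper()
    if tag == "TNS":
        return texture_simple
    if tag == "TSNS":
        return pd.concat([texture_simple, shape], axis=1)
    if tag == "TYS":
        return texture_weighted
    if tag in ("TSYS", "TSYLS", "TSYLC"):
        return pd.concat([texture_weighted, shape], axis=1)
    raise ValueError(f"unknown variant tag: {tag!r}")


def run_variant(texture_simple: pd.DataFrame, texture_weighted: pd.DataFrame,
                shape: pd.DataFrame, labels, tag: str, *,
                lam1: float | None = None, C: float = 1.0,
                selection_scope: str = "full"):
    """Evaluate one pipeline variant; returns (report, selected names or None).

    For the two selection variants the subset is, by default, chosen once
    on the full dataset before LOOCV (mirroring the historical protocol);
    ``selection_scope="nested"`` redoes the selection inside every
    training fold, the statistically safer mode.
    """
    tag = tag.upper()
    X = _variant_matrix(tag, texture_simple, texture_weighted, shape)
    y = _coerce_labels(labels)
    if tag not in ("TSYLS", "TSYLC"):
        return loocv_svm(X.to_numpy(float), y, C=C), None

    dispersion = tag == "TSYLC"
    if selection_scope == "full":
        res = DispersionLasso.from_dataframe(
            X.assign(label=y), dispersion=dispersion, lam1=lam1).fit()
        names = res.selected_names
        if not names:
            names = list(X.columns)
        return loocv_svm(X[names].to_numpy(float), y, C=C), names
    if selection_scope != "nested":
        raise ValueError("selection_scope must be 'full' or 'nested'")

    n = len(X)
    tp = tn = fp = fn = 0
    last_names: list[str] = []
    for i in range(n):
        train = np.ones(n, bool)
        train[i] = False
        res = DispersionLasso.from_dataframe(
            X.iloc[train].assign(label=y[train]),
            dispersion=dispersion, lam1=lam1).fit()
        names = res.selected_names or list(X.columns)
        last_names = names
        sub = X[names].to_numpy(float)
        X_tr = sub[train]
        mean, sd = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X_tr - mean) / sd, y[train])
        pred = int(clf.predict(((sub[i] - mean) / sd)[None, :])[0])
        if y[i] == 1:
            tp += pred == 1
            fn += pred != 1
        else:
            tn += pred == -1
            fp += pred != -1
    report = ClassificationReport(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
    return report, last_names


def run_all_variants(texture_simple, texture_weighted, shape, labels,
                     **kwargs) -> dict[str, dict]:
    """All six variants as one JSON-ready mapping."""
    out = {}
    for tag in VARIANTS:
        report, names = run_variant(texture_simple, texture_weighted, shape,
                                    labels, tag, **kwargs)
        entry = report.as_dict()
        if names is not None:
            entry["selected_features"] = names
        out[tag] = entry
    return out
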