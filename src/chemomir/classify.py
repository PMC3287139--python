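"""Cancer-vs-normal differential signature and multi-classifier prediction.

Differential expression uses the classical pooled-variance two-sample t-test
per feature with Benjamini-Hochberg FDR, reporting the linear-scale
cancer/normal ratio ``2**(mean_cancer - mean_normal)`` of the log2 values.

Class prediction follows the microarray protocol of repeated random
1:1 training/test partitions: features are re-selected on each training half
(t-test ``p < alpha``), six classifiers are fitted, and the per-classifier
median test accuracy over all partitions is reported.  The six rules are the
compound covariate predictor (CCP), diagonal linear discriminant analysis
(DLDA), 1- and 3-nearest neighbours, nearest centroid, and a linear SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureStat",
    "PartitionResult",
    "CLASSIFIERS",
    "t_test_per_feature",
    "bh_fdr",
    "train_classifier",
    "predict",
    "cross_partition_accuracy",
]

CLASSIFIERS = ("CCP", "DLDA", "1NN", "3NN", "NC", "SVM")


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FeatureStat:
    """One row of the differential-expression table (t, p, FDR, ratio)."""

    feature_id: str
    statistic: float
    p: float
    fdr: float
    ratio: float  # geometric-mean cancer/normal ratio, linear scale


def _two_class_masks(labels, classes=("cancer", "normal")):
    labels = np.asarray(labels)
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    if not m1.any() or not m2.any():
        raise ValueError(f"both classes {classes} must be present")
    return m1, m2


def t_test_per_feature(X: pd.DataFrame, labels, classes=("cancer", "normal")) -> pd.DataFrame:
    """Pooled-variance two-sample t-test for every feature (row) of ``X``.

    Returns a DataFrame indexed by feature with columns ``statistic, p, fdr,
    ratio, usable``.  Features with zero pooled variance are flagged unusable
    and excluded from the FDR computation.  Masked (NaN) entries are dropped
    per feature; features left with fewer than two samples in either class
    are likewise flagged.
    """
    m1, m2 = _two_class_masks(labels, classes)
    A = X.to_numpy()[:, np.asarray(m1)]
    B = X.to_numpy()[:, np.asarray(m2)]
    n1 = np.sum(~np.isnan(A), axis=1)
    n2 = np.sum(~np.isnan(B), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(A, axis=1)
        mean2 = np.nanmean(B, axis=1)
        var1 = np.nanvar(A, axis=1, ddof=1)
        var2 = np.nanvar(B, axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = np.where(df > 0, ((n1 - 1) * var1 + (n2 - 1) * var2) / np.maximum(df, 1), np.nan)
    se = np.sqrt(pooled * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    usable = (n1 >= 2) & (n2 >= 2) & (pooled > 0)
    t = np.where(usable, (mean1 - mean2) / np.where(se > 0, se, np.nan), np.nan)
    p = np.where(usable, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    fdr = np.full(len(X), np.nan)
    if usable.any():
        fdr[usable] = bh_fdr(p[usable])
    out = pd.DataFrame(
        {
            "statistic": t,
            "p": p,
            "fdr": fdr,
            "ratio": np.power(2.0, mean1 - mean2),
            "usable": usable,
        },
        index=pd.Index(X.index, name="feature_id"),
    )
    return out


def _select_features(X_train: pd.DataFrame, labels, alpha, classes):
    tab = t_test_per_feature(X_train, labels, classes)
    sel = tab[(tab["p"] < alpha) & tab["usable"]]
    return list(sel.index), tab


@dataclass
class _Fitted:
    method: str
    features: list
    classes: tuple
    majority: str
    impl: object = None  # sklearn estimator or closed-form parameters


def train_classifier(X_train: pd.DataFrame, labels, method, selection_alpha=0.05,
                     classes=("cancer", "normal")) -> _Fitted:
    """Select features on the training data only, then fit one classifier.

    If no feature passes selection the classifier degrades to predicting the
    majority training class (with a warning), keeping the protocol total.
    """
    if method not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {method!r}; choose from {CLASSIFIERS}")
    labels = np.asarray(labels)
    m1, m2 = _two_class_masks(labels, classes)
    majority = classes[0] if m1.sum() >= m2.sum() else classes[1]
    feats, tab = _select_features(X_train, labels, selection_alpha, classes)
    fitted = _Fitted(method=method, features=feats, classes=tuple(classes), majority=majority)
    if not feats:
        warnings.warn(f"{method}: no features passed selection at alpha={selection_alpha}; "
                      "predicting majority class")
        return fitted

    M = X_train.loc[feats].to_numpy().T  # samples x features
    A, B = M[m1], M[m2]
    if method == "CCP":
        t = tab.loc[feats, "statistic"].to_numpy()
        c1 = A @ t
        c2 = B @ t
        fitted.impl = {"t": t, "threshold": 0.5 * (c1.mean() + c2.mean()),
                       "sign1": np.sign(c1.mean() - c2.mean()) or 1.0}
    elif method == "DLDA":
        n1, n2 = A.shape[0], B.shape[0]
        pooled = ((n1 - 1) * A.var(axis=0, ddof=1) + (n2 - 1) * B.var(axis=0, ddof=1)) / (n1 + n2 - 2)
        pooled = np.where(pooled > 0, pooled, np.inf)  # zero-variance features carry no weight
        fitted.impl = {"mu1": A.mean(axis=0), "mu2": B.mean(axis=0), "var": pooled}
    elif method in ("1NN", "3NN"):
        k = 1 if method == "1NN" else 3
        est = KNeighborsClassifier(n_neighbors=min(k, M.shape[0]))
        fitted.impl = est.fit(M, labels)
    elif method == "NC":
        fitted.impl = NearestCentroid().fit(M, labels)
    elif method == "SVM":
        est = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        fitted.impl = est.fit(M, labels)
    return fitted


def predict(classifier: _Fitted, X_test: pd.DataFrame) -> np.ndarray:
    """Predict class labels for the columns (samples) of ``X_test``."""
    c1, c2 = classifier.classes
    n = X_test.shape[1]
    if not classifier.features:
        return np.full(n, classifier.majority, dtype=object)
    M = X_test.loc[classifier.features].to_numpy().T
    if classifier.method == "CCP":
        par = classifier.impl
        c = M @ par["t"]
        side = par["sign1"] * (c - par["threshold"])
        return np.where(side >= 0, c1, c2).astype(object)
    if classifier.method == "DLDA":
        par = classifier.impl
        d1 = (((M - par["mu1"]) ** 2) / par["var"]).sum(axis=1)
        d2 = (((M - par["mu2"]) ** 2) / par["var"]).sum(axis=1)
        return np.where(d1 <= d2, c1, c2).astype(object)
    return np.asarray(classifier.impl.predict(M), dtype=object)


@dataclass
class PartitionResult:
    """Per-partition test accuracies of one classifier and their median."""

    classifier: str
    accuracies: list = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))


def cross_partition_accuracy(X: pd.DataFrame, labels, n_partitions=100,
                             selection_alpha=0.05, seed=0,
                             classes=("cancer", "normal"),
                             methods=CLASSIFIERS) -> dict:
    """Random 1:1 class-stratified partitions; returns {method: PartitionResult}.

    Feature selection is redone on each training half so no information leaks
    from the test half.  With stratified splits a degenerate (single-class)
    training half cannot arise as long as both classes have >= 4 samples.
    """
    labels = pd.Series(np.asarray(labels), index=X.columns)
    m1, m2 = _two_class_masks(labels.to_numpy(), classes)
    if m1.sum() < 4 or m2.sum() < 4:
        raise ValueError("need >= 4 samples per class")
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(m1)
    idx2 = np.flatnonzero(m2)
    results = {m: PartitionResult(classifier=m) for m in methods}
    for _ in range(n_partitions):
        p1 = rng.permutation(idx1)
        p2 = rng.permutation(idx2)
        tr = np.concatenate([p1[: len(p1) // 2], p2[: len(p2) // 2]])
        te = np.concatenate([p1[len(p1) // 2:], p2[len(p2) // 2:]])
        X_tr, X_te = X.iloc[:, tr], X.iloc[:, te]
        y_tr, y_te = labels.iloc[tr].to_numpy(), labels.iloc[te].to_numpy()
        for m in methods:
            clf = train_classifier(X_tr, y_tr, m, selection_alpha, classes)
            acc = float(np.mean(predict(clf, X_te) == y_te))
            results[m].accuracies.append(acc)
    return results
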