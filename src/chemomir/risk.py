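"""Supervised principal-component survival risk prediction.

The predictive index (PI) follows Bair-Tibshirani supervised principal
components as implemented for survival risk grouping: (1) screen features by
univariate Cox regression against TTP at ``selection_alpha``; (2) center the
selected-feature submatrix by its training means; (3) take the first two
principal components of the centered samples-by-features submatrix (no
variance scaling); (4) fit a Cox model of TTP on the two PC scores, giving
coefficients (b1, b2); (5) the PI of a sample is ``b1*u1 + b2*u2`` with
``u_k = sum_i V_ik (x_i - m_i)`` — equivalently a weighted sum of centered
log intensities with weights ``w_i = b1*V_i1 + b2*V_i2``.  High PI means
rapid progression.

A new sample is placed on the training PI distribution by its midrank
percentile (the training median maps to exactly 50%) and called high-risk
when the percentile exceeds the cutoff (default 67).  Significance of the
association between expression and TTP is assessed by the log-rank statistic
of leave-one-out cross-validated risk groups, referenced against its
permutation null distribution (survival labels jointly reshuffled, the whole
pipeline — screening, PCs, Cox — re-run per permutation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import cox_screen, cox_fit, select_survival_features

__all__ = [
    "RiskModel",
    "RiskCall",
    "PermutationResult",
    "fit_risk_model",
    "predict_pi",
    "pi_percentile",
    "assign_risk_group",
    "loocv_risk_groups",
    "km_estimate",
    "logrank_statistic",
    "permutation_significance",
    "save_model",
    "load_model",
]

DEFAULT_CUTOFF = 67.0

MODEL_FORMAT_VERSION = 1


@dataclass
class RiskModel:
    """Fitted supervised-PC predictor.

    ``loadings`` are the two orthonormal PC loading vectors over the selected
    features, ``pc_betas`` the Cox coefficients on the PC scores, ``weights``
    their contraction ``loadings @ pc_betas`` (so PI = weights . (x - means)),
    and ``training_pi`` the training-set PI distribution used for percentiles.
    """

    selected_features: list
    means: np.ndarray
    loadings: np.ndarray        # (k, 2)
    pc_betas: np.ndarray        # (2,)
    weights: np.ndarray         # (k,)
    training_pi: np.ndarray
    cutoff_percentile: float = DEFAULT_CUTOFF
    selection_alpha: float = 0.05


@dataclass
class RiskCall:
    sample_id: str
    predictive_index: float
    percentile: float
    group: str  # low | high


@dataclass
class PermutationResult:
    lr_observed: float
    p: float
    n_perm: int
    null_stats: np.ndarray = field(repr=False, default=None)


def _first_two_pcs(Xc):
    """Loadings (k,2) and scores (n,2) of the first two PCs of centered Xc."""
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:2].T
    # deterministic sign convention (PI is invariant to it): largest-magnitude
    # entry of each loading vector is positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return loadings, Xc @ loadings


def fit_risk_model(X: pd.DataFrame, time, event, selection_alpha=0.05,
                   cutoff=DEFAULT_CUTOFF) -> RiskModel:
    """Fit the supervised-PC predictor on a training cohort.

    ``X`` is features-by-samples.  Raises ``ValueError`` when fewer than two
    features pass the Cox screen (use a larger ``selection_alpha``).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if X.shape[1] != time.size:
        raise ValueError("X columns must match survival records")
    if time.size <= 2:
        raise ValueError("training n must exceed 2")
    sel = select_survival_features(X, time, event, alpha=selection_alpha)
    feats = sel.selected
    if len(feats) < 2:
        raise ValueError(
            f"only {len(feats)} feature(s) passed Cox screening at "
            f"alpha={selection_alpha}; increase selection_alpha"
        )
    sub = X.loc[feats].to_numpy().T           # samples x features
    means = sub.mean(axis=0)
    Xc = sub - means
    loadings, scores = _first_two_pcs(Xc)
    betas, _ = cox_fit(scores, time, event)
    weights = loadings @ betas
    training_pi = Xc @ weights
    return RiskModel(selected_features=list(feats), means=means, loadings=loadings,
                     pc_betas=betas, weights=weights, training_pi=training_pi,
                     cutoff_percentile=float(cutoff), selection_alpha=float(selection_alpha))


def predict_pi(model: RiskModel, x) -> float:
    """Predictive index of one sample (Series or dict of feature -> value)."""
    x = pd.Series(x)
    missing = [f for f in model.selected_features if f not in x.index or pd.isna(x[f])]
    if missing:
        raise ValueError(f"sample lacks selected feature(s): {missing[:5]}")
    v = x.loc[model.selected_features].to_numpy(dtype=float)
    return float((v - model.means) @ model.weights)


def pi_percentile(model_or_training_pi, pi: float) -> float:
    """Midrank percentile of ``pi`` on the training PI distribution.

    ``100 * (#{train < pi} + 0.5 * #{train == pi}) / n``; the training median
    of an odd-sized training set maps to exactly 50%.
    """
    train = model_or_training_pi.training_pi if isinstance(model_or_training_pi, RiskModel) \
        else np.asarray(model_or_training_pi, dtype=float)
    less = np.count_nonzero(train < pi)
    equal = np.count_nonzero(train == pi)
    return 100.0 * (less + 0.5 * equal) / train.size


def assign_risk_group(percentile: float, cutoff=DEFAULT_CUTOFF) -> str:
    """'high' iff the percentile strictly exceeds the cutoff."""
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    return "high" if percentile > cutoff else "low"


def risk_call(model: RiskModel, sample_id, x) -> RiskCall:
    pi = predict_pi(model, x)
    pct = pi_percentile(model, pi)
    return RiskCall(sample_id=sample_id, predictive_index=pi, percentile=pct,
                    group=assign_risk_group(pct, model.cutoff_percentile))


# ---------------------------------------------------------------------------
# cross-validated risk groups and permutation significance
# ---------------------------------------------------------------------------

def _fit_fold(Xarr, time, event, alpha, beta0=None):
    """Screen + 2 PCs + Cox on one training fold; None when degenerate."""
    scr = cox_screen(Xarr, time, event, beta0=beta0)
    sel = np.flatnonzero(scr.usable & (scr.p < alpha))
    if sel.size < 2:
        return None
    sub = Xarr[:, sel]
    means = sub.mean(axis=0)
    Xc = sub - means
    loadings, scores = _first_two_pcs(Xc)
    try:
        betas, _ = cox_fit(scores, time, event)
    except (RuntimeError, ValueError):
        return None
    w = loadings @ betas
    return sel, means, w, Xc @ w


def _loocv_group_labels(Xarr, time, event, alpha, cutoff):
    """Cross-validated high/low labels; Xarr is samples x features.

    Returns (is_high: bool array, pi, percentile, n_fallback) where folds that
    cannot support the model (fewer than 2 screened features, or a Cox fit
    failure on the PC scores) default the left-out sample to low risk.
    """
    n = Xarr.shape[0]
    is_high = np.zeros(n, dtype=bool)
    pis = np.full(n, np.nan)
    pcts = np.full(n, np.nan)
    n_fallback = 0
    # the full-data univariate fits warm-start every leave-one-out screen
    warm = cox_screen(Xarr, time, event).beta
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        fold = _fit_fold(Xarr[mask], time[mask], event[mask], alpha, beta0=warm)
        if fold is None:
            n_fallback += 1
        else:
            sel, means, w, train_pi = fold
            pi = (Xarr[i, sel] - means) @ w
            less = np.count_nonzero(train_pi < pi)
            equal = np.count_nonzero(train_pi == pi)
            pct = 100.0 * (less + 0.5 * equal) / train_pi.size
            pis[i] = pi
            pcts[i] = pct
            is_high[i] = pct > cutoff
        mask[i] = True
    return is_high, pis, pcts, n_fallback


def loocv_risk_groups(X: pd.DataFrame, time, event, selection_alpha=0.05,
                      cutoff=DEFAULT_CUTOFF) -> pd.DataFrame:
    """Leave-one-out cross-validated risk groups.

    For each sample the entire model (screening, PCs, Cox on PC scores) is
    refit on the remaining n-1 samples, and the left-out sample's PI is
    ranked against that fold's training PI distribution.  Folds with fewer
    than two screened features assign low risk (counted and warned).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if X.shape[1] < 10:
        raise ValueError("LOOCV needs n >= 10 samples")
    Xarr = np.ascontiguousarray(X.to_numpy().T)
    is_high, pis, pcts, n_fb = _loocv_group_labels(Xarr, time, event,
                                                   selection_alpha, cutoff)
    if n_fb:
        warnings.warn(f"{n_fb} LOOCV fold(s) had <2 selected features or a "
                      "degenerate Cox fit; left-out samples assigned low risk")
    return pd.DataFrame(
        {
            "predictive_index": pis,
            "percentile": pcts,
            "group": np.where(is_high, "high", "low"),
        },
        index=pd.Index(X.columns, name="sample_id"),
    )


def km_estimate(time, event):
    """Kaplan-Meier product-limit estimate.

    Returns a ``pd.Series`` of survival probability indexed by time (starting
    at 0 with probability 1).  Negative times raise ``ValueError``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("empty survival input")
    if np.any(time < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    s.name = "survival"
    return s


def _logrank_chi2(g1: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Two-group log-rank chi-square (1 df); g1 marks membership of group 1."""
    et = np.unique(time[event])
    if et.size == 0:
        return 0.0
    ts = np.sort(time)
    ts1 = np.sort(time[g1])
    te = np.sort(time[event])
    te1 = np.sort(time[event & g1])
    n_at = ts.size - np.searchsorted(ts, et, side="left")
    n1_at = ts1.size - np.searchsorted(ts1, et, side="left")
    d = np.searchsorted(te, et, side="right") - np.searchsorted(te, et, side="left")
    d1 = np.searchsorted(te1, et, side="right") - np.searchsorted(te1, et, side="left")
    frac = n1_at / n_at
    o_minus_e = d1.sum() - (d * frac).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0)
    v = np.where(n_at > 1, v, 0.0).sum()
    if v <= 0:
        return 0.0
    return float(o_minus_e ** 2 / v)


def logrank_statistic(groups, time, event) -> float:
    """Standard two-group log-rank chi-square statistic over pooled times."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = pd.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly 2 nonempty groups required")
    return _logrank_chi2(groups == labels[0], time, event)


def permutation_significance(X: pd.DataFrame, time, event, n_perm=1000, seed=0,
                             selection_alpha=0.05,
                             cutoff=DEFAULT_CUTOFF) -> PermutationResult:
    """Permutation significance of the cross-validated risk-group separation.

    The observed statistic ``LR_d`` is the log-rank chi-square of the LOOCV
    risk groups on the real data.  For each permutation the (time, event)
    pairs are jointly reshuffled across samples (expression fixed) and the
    full LOOCV pipeline is re-run; ``p = (1 + #{LR_perm >= LR_d}) /
    (1 + n_perm)``.  A permutation (or the observed run) in which every
    sample lands in one group contributes a statistic of 0.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    Xarr = np.ascontiguousarray(np.asarray(X, dtype=float).T)

    def lr_of(t, e):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            is_high, _, _, _ = _loocv_group_labels(Xarr, t, e, selection_alpha, cutoff)
        if is_high.all() or not is_high.any():
            return 0.0
        return _logrank_chi2(is_high, t, e)

    lr_obs = lr_of(time, event)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(time.size)
        null[b] = lr_of(time[perm], event[perm])
    p = (1.0 + np.count_nonzero(null >= lr_obs)) / (1.0 + n_perm)
    return PermutationResult(lr_observed=lr_obs, p=float(p), n_perm=int(n_perm),
                             null_stats=null)


# ---------------------------------------------------------------------------
# serialization (versioned text format)
# ---------------------------------------------------------------------------

def save_model(model: RiskModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "selected_features": list(model.selected_features),
        "means": model.means.tolist(),
        "loadings": model.loadings.tolist(),
        "pc_betas": model.pc_betas.tolist(),
        "weights": model.weights.tolist(),
        "training_pi": model.training_pi.tolist(),
        "cutoff_percentile": model.cutoff_percentile,
        "selection_alpha": model.selection_alpha,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> RiskModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {payload.get('format_version')}")
    return RiskModel(
        selected_features=list(payload["selected_features"]),
        means=np.asarray(payload["means"], dtype=float),
        loadings=np.asarray(payload["loadings"], dtype=float),
        pc_betas=np.asarray(payload["pc_betas"], dtype=float),
        weights=np.asarray(payload["weights"], dtype=float),
        training_pi=np.asarray(payload["training_pi"], dtype=float),
        cutoff_percentile=float(payload["cutoff_percentile"]),
        selection_alpha=float(payload["selection_alpha"]),
    )
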