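"""Proportional-hazards screening of miRNA expression against time to progression.

Each miRNA is related to TTP through its own univariate Cox model; features
with Wald ``p < alpha`` are split into a chemoresistance list (hazard ratio
above 1: overexpression goes with rapid progression) and a chemosensitivity
list (hazard ratio below 1: overexpression goes with delayed progression).

The screening engine (`cox_screen`) fits every feature simultaneously with a
vectorized Newton iteration on the Efron-tie partial likelihood.  That matters
because the risk predictor re-runs the entire screen inside every
leave-one-out fold of every permutation replicate, so single-model fitting
overhead is multiplied by ~10^5.  `cox_fit` is the companion multivariate
solver used for the two principal-component covariates of the risk model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._cox_kernels import multiv_newton, screen_newton
from .classify import bh_fdr

__all__ = [
    "CoxScreenResult",
    "SurvivalFeatureStat",
    "SurvivalSelection",
    "cox_screen",
    "cox_fit",
    "cox_fit_single",
    "select_survival_features",
]

#: beta magnitude beyond which a univariate fit is declared monotone-likelihood
BETA_MAX = 15.0


class _RiskSetIndex:
    """Sorted-order bookkeeping for Efron partial-likelihood sums.

    Samples are sorted by time ascending with events preceding censored
    samples at tied times, so the events of each distinct event time occupy a
    contiguous block starting at the first at-risk row of that time.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if not np.all(np.isfinite(time)):
            raise ValueError("non-finite survival times")
        if np.any(time < 0):
            raise ValueError("negative survival times")
        self.n = time.size
        self.n_events = int(event.sum())
        self.order = np.lexsort((~event, time))
        t = time[self.order]
        e = event[self.order]
        etimes, d = np.unique(t[e], return_counts=True)
        self.risk_start = np.searchsorted(t, etimes, side="left").astype(np.int64)
        self.d = d.astype(np.int64)


def _seg_sums(v, start, d):
    """Sums of rows ``start[g] .. start[g]+d[g]-1`` for each group g."""
    pad = np.zeros((1,) + v.shape[1:], dtype=v.dtype)
    cs = np.concatenate([pad, np.cumsum(v, axis=0)])
    return cs[start + d] - cs[start]


@dataclass
class CoxScreenResult:
    """Per-feature univariate Cox fits, aligned with the input feature axis."""

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    usable: np.ndarray  # converged, non-constant, non-monotone likelihood
    constant: np.ndarray
    diverged: np.ndarray

    @property
    def hazard_ratio(self):
        return np.exp(self.beta)


def cox_screen(X, time, event, *, max_iter=50, grad_tol=1e-8,
               beta0=None) -> CoxScreenResult:
    """Fit an independent univariate Cox model per feature (column of ``X``).

    Parameters
    ----------
    X : (n_samples, n_features) array
        Expression values; each column is one covariate.
    time, event : (n_samples,) arrays
        Follow-up time and event indicator (1 = progression observed).
    beta0 : optional (n_features,) array
        Warm-start coefficients (e.g. the full-data fit when screening
        leave-one-out folds); convergence criteria are unchanged.

    Efron tie handling; Newton-Raphson run until the score (gradient) falls
    below ``grad_tol`` in absolute value.  Features whose likelihood is
    monotone (|beta| exceeding ``BETA_MAX``), constant features and
    non-converged fits are flagged unusable rather than raising.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    idx = _RiskSetIndex(time, event)
    if idx.n_events == 0:
        raise ValueError("no events: all samples censored")
    if idx.n_events < 2:
        raise ValueError("fewer than 2 events")
    if X.shape[0] != idx.n:
        raise ValueError("X rows must match the number of samples")

    n, p = X.shape
    Xs = X[idx.order]
    constant = Xs.std(axis=0) == 0
    # centering leaves beta unchanged but keeps exp(eta) well scaled
    Z = Xs - Xs.mean(axis=0)
    sum_x_events = _seg_sums(Z, idx.risk_start, idx.d).sum(axis=0)

    b0 = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    b0[~np.isfinite(b0)] = 0.0
    beta, hess, conv = screen_newton(
        np.ascontiguousarray(Z.T), idx.risk_start, idx.d, sum_x_events,
        b0, grad_tol, max_iter, BETA_MAX, 2.0,
    )
    converged = conv.astype(bool)
    diverged = np.abs(beta) > BETA_MAX
    usable = (~constant) & converged & (~diverged) & (hess < 0)
    se = np.full(p, np.nan)
    np.sqrt(np.divide(-1.0, hess, out=np.full(p, np.nan), where=usable), out=se, where=usable)
    z = np.where(usable, beta / se, np.nan)
    pval = np.where(usable, 2.0 * special.ndtr(-np.abs(z)), np.nan)
    return CoxScreenResult(beta=beta, se=se, z=z, p=pval, usable=usable,
                           constant=constant, diverged=diverged)


def cox_fit(Z, time, event, *, max_iter=100, grad_tol=1e-8):
    """Multivariate Cox fit (Efron ties) for a small number of covariates.

    Returns ``(beta, cov)`` where ``cov`` is the inverse observed information.
    Raises ``RuntimeError`` on non-convergence.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    idx = _RiskSetIndex(time, event)
    if idx.n_events == 0:
        raise ValueError("no events: all samples censored")
    Zs = Z[idx.order]
    Zs = Zs - Zs.mean(axis=0)
    sum_z_events = _seg_sums(Zs, idx.risk_start, idx.d).sum(axis=0)
    try:
        beta, H, status = multiv_newton(
            np.ascontiguousarray(Zs), idx.risk_start, idx.d, sum_z_events,
            grad_tol, max_iter, 2.0 * BETA_MAX, 5.0,
        )
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular information matrix in Cox fit") from exc
    if status == 2:
        raise RuntimeError("Cox fit diverged (monotone likelihood or singular information)")
    if status != 0:
        raise RuntimeError("Cox fit did not converge")
    cov = np.linalg.inv(-H)
    return beta, cov


@dataclass
class SurvivalFeatureStat:
    """Univariate Cox result for one feature (one row of a Table-3-like table)."""

    feature_id: str
    beta: float
    hazard_ratio: float
    p: float
    se: float
    fdr: float = float("nan")

    @property
    def direction(self) -> str:
        return "resistance" if self.hazard_ratio > 1.0 else "sensitivity"


def cox_fit_single(x, time, event, *, feature_id="feature") -> SurvivalFeatureStat:
    """Univariate Cox fit for a single covariate vector.

    Raises ``ValueError`` for all-censored input ("no events") or a constant
    covariate ("no variation"), and ``RuntimeError`` when the partial
    likelihood is monotone (no finite maximizer).
    """
    x = np.asarray(x, dtype=float)
    res = cox_screen(x[:, None], time, event)
    if bool(res.constant[0]):
        raise ValueError("no variation in covariate")
    if bool(res.diverged[0]) or not bool(res.usable[0]):
        raise RuntimeError("monotone partial likelihood: no finite estimate")
    return SurvivalFeatureStat(
        feature_id=feature_id,
        beta=float(res.beta[0]),
        hazard_ratio=float(np.exp(res.beta[0])),
        p=float(res.p[0]),
        se=float(res.se[0]),
    )


@dataclass
class SurvivalSelection:
    """Screened features split by hazard direction.

    ``table`` carries one row per tested feature (beta, hazard ratio, Wald p,
    BH-FDR over all tested features, list membership); the two id lists are
    sorted by ascending p.
    """

    table: pd.DataFrame
    resistance: list = field(default_factory=list)
    sensitivity: list = field(default_factory=list)

    @property
    def selected(self) -> list:
        return list(self.resistance) + list(self.sensitivity)


def select_survival_features(X: pd.DataFrame, time, event, alpha=0.05) -> SurvivalSelection:
    """Screen every feature (row of ``X``) against TTP by univariate Cox.

    Features with Wald ``p < alpha`` enter the chemoresistance list when
    HR > 1 and the chemosensitivity list when HR < 1.  FDR (Benjamini-
    Hochberg) is computed over all usable tested features.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    res = cox_screen(X.to_numpy().T, time, event)
    tab = pd.DataFrame(
        {
            "beta": res.beta,
            "hazard_ratio": res.hazard_ratio,
            "p": res.p,
            "usable": res.usable,
        },
        index=pd.Index(X.index, name="feature_id"),
    )
    fdr = np.full(len(tab), np.nan)
    mask = res.usable
    if mask.any():
        fdr[mask] = bh_fdr(res.p[mask])
    tab["fdr"] = fdr
    sel = tab[(tab["p"] < alpha) & tab["usable"]].sort_values("p")
    resistance = list(sel.index[sel["hazard_ratio"] > 1.0])
    sensitivity = list(sel.index[sel["hazard_ratio"] < 1.0])
    tab["list"] = ""
    tab.loc[resistance, "list"] = "resistance"
    tab.loc[sensitivity, "list"] = "sensitivity"
    return SurvivalSelection(table=tab, resistance=resistance, sensitivity=sensitivity)
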