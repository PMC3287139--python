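"""Log transformation, per-array lowess (M-vs-A) normalization, replicate
collapsing and missing-value handling for two-channel miRNA arrays.

The array reports, per probe, the log2 ratio M of sample to reference signal
and the mean log2 intensity A.  Intensity-dependent dye bias is removed per
array by subtracting a lowess fit of M on A.  Each mature miRNA is measured
by several replicate probes which are collapsed to their median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "log2_transform",
    "lowess_normalize",
    "normalize_matrix",
    "collapse_replicates",
    "drop_sparse_and_impute",
]

#: classical lowess defaults: span 2/3 of the data, 3 robustifying iterations
DEFAULT_SPAN = 2.0 / 3.0
DEFAULT_ROBUST_ITERS = 3


def log2_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of a positive ratio matrix; masked entries stay masked.

    Nonpositive unmasked values raise ``ValueError`` listing the offending
    entries (up to ten).
    """
    vals = raw.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        where = [
            f"(feature {raw.index[i]!r}, sample {raw.columns[j]!r}: {vals[i, j]!r})"
            for i, j in np.argwhere(bad)[:10]
        ]
        raise ValueError("nonpositive ratio(s): " + ", ".join(where))
    return pd.DataFrame(np.log2(vals), index=raw.index, columns=raw.columns)


def lowess_normalize(m, a, span=DEFAULT_SPAN, robust_iters=DEFAULT_ROBUST_ITERS):
    """Remove the intensity-dependent trend from one array's M values.

    Parameters
    ----------
    m : array of per-probe log2 ratios (M), NaN = missing
    a : array of per-probe mean log2 intensities (A)
    span : lowess span (fraction of probes per local fit), in (0, 1]

    Returns M minus the lowess fit of M on A, evaluated at each probe's A;
    masked entries stay masked.  Fewer than 10 unmasked probes raise
    ``ValueError`` (the smoother is underdetermined).
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("m and a must be 1-D arrays of equal length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    ok = ~np.isnan(m) & ~np.isnan(a)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 unmasked probes: lowess underdetermined")
    fit = _sm_lowess(m[ok], a[ok], frac=span, it=robust_iters, return_sorted=False)
    out = np.full_like(m, np.nan)
    out[ok] = m[ok] - fit
    return out


def normalize_matrix(M: pd.DataFrame, A: pd.DataFrame, span=DEFAULT_SPAN,
                     robust_iters=DEFAULT_ROBUST_ITERS) -> pd.DataFrame:
    """Apply :func:`lowess_normalize` to each array (column) of ``M``."""
    if not M.index.equals(A.index) or not M.columns.equals(A.columns):
        raise ValueError("M and A must share probe ids and sample ids")
    out = {}
    for col in M.columns:
        out[col] = lowess_normalize(M[col].to_numpy(), A[col].to_numpy(),
                                    span=span, robust_iters=robust_iters)
    return pd.DataFrame(out, index=M.index)


def collapse_replicates(probe_matrix: pd.DataFrame, probe_to_mirna) -> pd.DataFrame:
    """Median-collapse replicate probes to one row per mature miRNA.

    ``probe_to_mirna`` maps every probe id to its miRNA; a probe missing from
    the map raises ``ValueError``.  Per sample, the median is taken over the
    unmasked replicates; the collapsed value is masked only if every
    replicate is masked.  Row order follows first appearance of each miRNA.
    """
    mapping = pd.Series(probe_to_mirna)
    missing = probe_matrix.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"probe(s) absent from the replicate map: {list(missing[:5])}")
    groups = mapping.loc[probe_matrix.index]
    order = groups.drop_duplicates().to_list()
    collapsed = probe_matrix.groupby(groups.to_numpy(), sort=False).median()
    collapsed = collapsed.loc[order]
    collapsed.index.name = "feature_id"
    return collapsed


def drop_sparse_and_impute(X: pd.DataFrame, max_missing_frac=0.5) -> pd.DataFrame:
    """Drop features masked in more than ``max_missing_frac`` of samples and
    impute the remaining missing entries with the feature's median."""
    frac = X.isna().mean(axis=1)
    kept = X.loc[frac <= max_missing_frac]
    med = kept.median(axis=1)
    return kept.T.fillna(med).T
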