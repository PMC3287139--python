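"""Relative quantification of miRNA qPCR validations by the ddCt method.

Duplicate-well Ct values are averaged, normalized to the RNU6 endogenous
control by subtraction (dCt = mean target Ct - mean reference Ct), and
referenced to a control baseline (ddCt = dCt_test - dCt_control).  Relative
expression is ``2**(-ddCt)``; fold changes are reported on the log2 scale as
``-ddCt`` (a fold change of -1 means a 50% decrease).  Group comparison uses
the pooled-variance Student t-test on the log2-scale fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_ct", "ddct_expression", "group_compare", "analyze_ct_table"]

DEFAULT_REFERENCE = "RNU6"


def delta_ct(target_cts, reference_cts) -> float:
    """dCt = mean(target wells) - mean(reference wells)."""
    target = np.asarray(list(np.atleast_1d(target_cts)), dtype=float)
    reference = np.asarray(list(np.atleast_1d(reference_cts)), dtype=float)
    if reference.size == 0 or np.isnan(reference).all():
        raise ValueError("missing reference (endogenous control) wells")
    if target.size == 0 or np.isnan(target).all():
        raise ValueError("missing target wells")
    return float(np.nanmean(target) - np.nanmean(reference))


@dataclass
class RelativeExpression:
    ddct: float
    expression: float        # 2 ** (-ddCt), linear scale
    fold_change_log2: float  # -ddCt


def ddct_expression(test_dct: float, control_dct: float) -> RelativeExpression:
    """Relative expression of a test sample against a control baseline."""
    ddct = float(test_dct) - float(control_dct)
    return RelativeExpression(ddct=ddct, expression=2.0 ** (-ddct),
                              fold_change_log2=-ddct)


def group_compare(cancer_fc, normal_fc):
    """Two-sided pooled-variance t-test on log2-scale fold changes.

    Returns ``(t, p)``; a zero pooled variance yields ``(nan, nan)`` (the
    comparison is flagged rather than fabricated).
    """
    a = np.asarray(list(cancer_fc), dtype=float)
    b = np.asarray(list(normal_fc), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def analyze_ct_table(ct: pd.DataFrame, reference=DEFAULT_REFERENCE,
                     control_group="normal"):
    """Full ddCt workflow on a well-level Ct table.

    ``ct`` has columns sample_id, group, well, target, ct.  The control
    baseline for each target is the mean dCt of the ``control_group`` samples.
    Returns ``(per_sample, per_target)``: per-sample dCt/ddCt/expression/fold
    change, and a per-target cancer-vs-normal t-test table.
    """
    required = {"sample_id", "group", "target", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    targets = [t for t in ct["target"].unique() if t != reference]
    if not targets:
        raise ValueError("no non-reference targets in the Ct table")

    ref = ct[ct["target"] == reference].groupby("sample_id")["ct"].mean()
    rows = []
    for target in targets:
        sub = ct[ct["target"] == target]
        tmean = sub.groupby("sample_id")["ct"].mean()
        groups = sub.groupby("sample_id")["group"].first()
        missing_ref = tmean.index.difference(ref.index)
        if len(missing_ref):
            raise ValueError(f"missing reference wells for sample(s) "
                             f"{list(missing_ref[:5])}")
        dct = tmean - ref.loc[tmean.index]
        control = dct[groups == control_group]
        if control.empty:
            raise ValueError(f"no {control_group!r} samples to set the baseline")
        baseline = float(control.mean())
        for sid, value in dct.items():
            rel = ddct_expression(value, baseline)
            rows.append({"sample_id": sid, "group": groups[sid], "target": target,
                         "delta_ct": value, "ddct": rel.ddct,
                         "expression": rel.expression,
                         "fold_change_log2": rel.fold_change_log2})
    per_sample = pd.DataFrame(rows)

    cmp_rows = []
    for target, grp in per_sample.groupby("target", sort=False):
        fc_c = grp.loc[grp["group"] == "cancer", "fold_change_log2"]
        fc_n = grp.loc[grp["group"] == control_group, "fold_change_log2"]
        t, p = group_compare(fc_c, fc_n)
        cmp_rows.append({"target": target, "t": t, "p": p,
                         "mean_fc_cancer": float(fc_c.mean()),
                         "mean_fc_normal": float(fc_n.mean())})
    per_target = pd.DataFrame(cmp_rows)
    return per_sample, per_target
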