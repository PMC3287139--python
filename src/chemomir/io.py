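"""Tab-separated readers/writers for expression, clinical, truth and Ct tables.

All tables are UTF-8 TSV with '.' decimal separators.  Expression matrices
are stored features-by-samples: first column = feature id, header row =
sample ids, empty cells = missing values (kept as NaN, never zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_ct_tsv",
    "write_ct_tsv",
]

CLINICAL_COLUMNS = ["class_label", "ttp_months", "event", "pair_id", "timepoint"]


class ParseError(ValueError):
    """Malformed input table (ragged row, duplicate id, non-numeric cell)."""


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a feature-by-sample log-ratio matrix from TSV.

    Empty cells become NaN (masked).  Duplicate sample or feature ids,
    ragged rows and non-numeric cells raise :class:`ParseError` naming the
    offending row/column.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    width = lines[0].count("\t")
    for i, ln in enumerate(lines[1:], start=2):
        if ln.count("\t") != width:
            raise ParseError(f"{path}: ragged row at line {i}")
    header = lines[0].split("\t")[1:]
    seen = set()
    for col in header:
        if col in seen:
            raise ParseError(f"{path}: duplicate sample id {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    values = df.to_numpy()
    out = np.full(values.shape, np.nan)
    empty = values == ""
    try:
        out[~empty] = values[~empty].astype(float)
    except ValueError:
        bad = np.zeros(values.shape, dtype=bool)
        for (i, j), v in np.ndenumerate(values):
            if v != "":
                try:
                    float(v)
                except ValueError:
                    bad[i, j] = True
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric cell {values[i, j]!r} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        ) from None
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    res.index.name = df.index.name or "feature_id"
    return res


def write_expression_tsv(matrix: pd.DataFrame, path, *, sig_digits=6) -> None:
    """Write a feature-by-sample matrix as TSV, NaN as empty cell."""
    out = matrix.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", float_format=f"%.{sig_digits}g", na_rep="")


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a clinical table (sample_id, class_label, ttp_months, event,
    pair_id, timepoint) and validate its pairing invariants."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate sample id")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df["ttp_months"] = pd.to_numeric(df["ttp_months"].replace("", np.nan))
    df["event"] = pd.to_numeric(df["event"].replace("", np.nan))
    validate_clinical(df)
    return df[CLINICAL_COLUMNS]


def validate_clinical(df: pd.DataFrame) -> None:
    has_pair = df["pair_id"].astype(str) != ""
    has_tp = df["timepoint"].astype(str).isin(["pre", "post"])
    if (has_pair & ~has_tp).any():
        bad = df.index[has_pair & ~has_tp][0]
        raise ParseError(f"sample {bad!r}: pair_id without a pre/post timepoint")
    paired = df[has_pair]
    for pid, grp in paired.groupby("pair_id"):
        tps = sorted(grp["timepoint"])
        if tps != ["post", "pre"]:
            raise ParseError(f"pair {pid!r} must occur exactly once as pre and once as post")
    ttp = df["ttp_months"]
    if (ttp.dropna() < 0).any():
        raise ParseError("negative ttp_months")


def write_clinical_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def read_ct_tsv(path) -> pd.DataFrame:
    """Read a qPCR Ct table with columns sample_id, group, well, target, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str,
                                            "well": str, "target": str})
    required = {"sample_id", "group", "well", "target", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"])
    return df


def write_ct_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
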