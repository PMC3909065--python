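"""Readers and writers for the pipeline's CSV dialects.

One long-format C_T dialect is shared by the array screen and the
validation plates: columns exactly ``sample_id, mirna_id, replicate,
plate_id, ct``, with ``ct`` a decimal number or the literal token
``Undetermined``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CT_COLUMNS, SAMPLE_COLUMNS, UNDETERMINED

__all__ = ["read_ct_table", "write_ct_table", "read_sample_sheet", "write_sample_sheet"]


class CtTableError(ValueError):
    """Malformed C_T table."""


def read_ct_table(path) -> pd.DataFrame:
    """Read and validate a long-format C_T CSV.

    Enforces the exact header, numeric-or-'Undetermined' ct values, and
    uniqueness of (sample_id, mirna_id, replicate, plate_id); violations
    raise with the offending column or 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "mirna_id": str,
                                  "plate_id": str, "ct": str})
    if list(df.columns) != CT_COLUMNS:
        raise CtTableError(
            f"bad header: expected {CT_COLUMNS}, found {list(df.columns)}")
    ct = df["ct"].str.strip()
    numeric = pd.to_numeric(ct, errors="coerce")
    bad = ct.ne(UNDETERMINED) & numeric.isna()
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise CtTableError(f"non-numeric ct values (and not '{UNDETERMINED}') "
                           f"at data row(s) {rows}")
    dup = df.duplicated(["sample_id", "mirna_id", "replicate", "plate_id"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()[:10]
        raise CtTableError(f"duplicate (sample, mirna, replicate, plate) "
                           f"at data row(s) {rows}")
    out = df.copy()
    out["ct"] = np.where(numeric.isna(), UNDETERMINED,
                         numeric.astype(object))
    out["replicate"] = out["replicate"].astype(int)
    return out


def write_ct_table(df: pd.DataFrame, path) -> None:
    df[CT_COLUMNS].to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "grade": str,
                                  "nodal_status": str, "stage": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s): {missing}")
    return df[SAMPLE_COLUMNS]


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[SAMPLE_COLUMNS].to_csv(path, index=False)
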