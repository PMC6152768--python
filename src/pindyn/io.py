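"""Table dialects shared by the generators and the analysis stages.

Five plain-text dialects, all with a header line:

========== ========= =======================================================
dialect    separator columns
========== ========= =======================================================
relax_tsv  tab       residue R1 R1_err R2 R2_err NOE NOE_err
exsy_tsv   tab       signal t_mix_s ratio ratio_err replicate
hdx_tsv    tab       residue t_min intensity
melt_csv   comma     T_C theta222
itc_csv    comma     injection volume_uL heat_ucal
========== ========= =======================================================

Readers validate the header and every cell, reporting the offending column
or line; writers emit full-precision floats so a write→read round trip is
exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .relaxmap import ResidueRelaxationRecord

__all__ = ["DIALECTS", "read_table", "write_table", "records_from_relax"]

DIALECTS: dict[str, dict] = {
    "relax_tsv": {
        "sep": "\t",
        "columns": ["residue", "R1", "R1_err", "R2", "R2_err",
                    "NOE", "NOE_err"],
        "unique": "residue",
    },
    "exsy_tsv": {
        "sep": "\t",
        "columns": ["signal", "t_mix_s", "ratio", "ratio_err", "replicate"],
        "unique": None,
    },
    "hdx_tsv": {
        "sep": "\t",
        "columns": ["residue", "t_min", "intensity"],
        "unique": None,
    },
    "melt_csv": {
        "sep": ",",
        "columns": ["T_C", "theta222"],
        "unique": "T_C",
    },
    "itc_csv": {
        "sep": ",",
        "columns": ["injection", "volume_uL", "heat_ucal"],
        "unique": "injection",
    },
}


def read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's table dialects."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; "
                         f"expected one of {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]
    df = pd.read_csv(path, sep=spec["sep"])
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) "
                         f"{', '.join(missing)} for dialect {dialect}")
    numeric = [c for c in spec["columns"] if c != "signal"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: non-numeric value in column "
                             f"{col!r} at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: empty cell in column {col!r} "
                             f"at line {line}")
        df[col] = coerced
    key = spec["unique"]
    if key is not None and df[key].duplicated().any():
        dup = df.loc[df[key].duplicated(), key].iloc[0]
        raise ValueError(f"{path}: duplicated {key} value {dup!r}")
    return df[spec["columns"]]


def write_table(df: pd.DataFrame, path: str | Path, dialect: str) -> None:
    """Write a table in one of the pipeline's dialects at full precision."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    spec = DIALECTS[dialect]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write {dialect}: missing column(s) "
                         f"{', '.join(missing)}")
    out = df[spec["columns"]].copy()
    # repr-style float formatting round-trips exactly
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=spec["sep"], index=False,
               float_format=lambda x: np.format_float_positional(
                   x, unique=True, trim="0"))


def records_from_relax(df: pd.DataFrame) -> list[ResidueRelaxationRecord]:
    """Convert a validated relax_tsv table into typed residue records."""
    return [
        ResidueRelaxationRecord(
            residue_id=int(row.residue),
            R1=row.R1, R1_err=row.R1_err,
            R2=row.R2, R2_err=row.R2_err,
            hNOE=row.NOE, hNOE_err=row.NOE_err,
        )
        for row in df.itertuples()
    ]
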