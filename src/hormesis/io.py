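"""Reading and writing participant tables and result artifacts."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_table", "InputError"]


class InputError(ValueError):
    """Malformed input table."""


def read_table(path, id_col: str = "pid") -> pd.DataFrame:
    """Read a participant table CSV: header row, empty cells as missing,
    all data columns numeric.

    Raises
    ------
    InputError
        On an empty file, duplicate participant identifiers, or a
        non-numeric value (the error names the row and column).
    """
    table = pd.read_csv(path)
    if len(table) == 0:
        raise InputError(f"{path}: no data rows")
    if id_col in table.columns:
        dup = table[id_col][table[id_col].duplicated()]
        if len(dup):
            raise InputError(
                f"{path}: duplicate participant ids (first: {dup.iloc[0]!r})"
            )
    for col in table.columns:
        if table[col].dtype == object:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = table[col].notna() & coerced.isna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise InputError(
                    f"{path}: non-numeric value {table[col].iloc[row]!r} "
                    f"in column {col!r}, row {row}"
                )
            table[col] = coerced
    return table
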