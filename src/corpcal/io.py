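"""Reading forecast-outcome tables and writing result artifacts."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pav import PairedSample

__all__ = ["read_pairs", "decomposition_table"]


def read_pairs(
    path,
    outcome: str,
    forecasts: Optional[Sequence[str]] = None,
    na: str = "drop",
    delimiter: str = ",",
) -> dict:
    """Read one or more forecast columns paired with an outcome column.

    Parameters
    ----------
    path : str or file-like
        Delimited text file with a header row.
    outcome : str
        Name of the binary outcome column (values 0/1).
    forecasts : sequence of str, optional
        Forecast column names; defaults to every numeric column other
        than the outcome.
    na : {"drop", "error"}
        Whether rows with missing values are dropped (with a warning)
        or rejected.

    Returns
    -------
    dict mapping forecast column name -> PairedSample
    """
    df = pd.read_csv(path, delimiter=delimiter)
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not found in {list(df.columns)}")
    if forecasts is None:
        forecasts = [
            c
            for c in df.columns
            if c != outcome and pd.api.types.is_numeric_dtype(df[c])
        ]
        if not forecasts:
            raise ValueError("no numeric forecast columns found")
    missing = [c for c in forecasts if c not in df.columns]
    if missing:
        raise ValueError(f"forecast column(s) not found: {missing}")

    samples = {}
    for col in forecasts:
        sub = df[[col, outcome]]
        bad = sub.isna().any(axis=1)
        if bad.any():
            if na == "error":
                rows = (np.flatnonzero(bad) + 2).tolist()  # header is line 1
                raise ValueError(f"missing values in rows {rows[:10]}")
            warnings.warn(
                f"dropping {int(bad.sum())} row(s) with missing values for {col!r}",
                stacklevel=2,
            )
            sub = sub[~bad]
        x = sub[col].to_numpy(dtype=float)
        y = sub[outcome].to_numpy(dtype=float)
        for arr, kind, lo_ok in ((x, "forecast", (x >= 0) & (x <= 1)),
                                 (y, "outcome", (y == 0) | (y == 1))):
            offenders = np.flatnonzero(~lo_ok)
            if offenders.size:
                row = sub.index[offenders[0]] + 2
                raise ValueError(
                    f"invalid {kind} value {arr[offenders[0]]} in column "
                    f"{col if kind == 'forecast' else outcome!r}, file row {row}"
                )
        samples[col] = PairedSample(x=x, y=y)
    return samples


def decomposition_table(samples: dict, rule="brier") -> pd.DataFrame:
    """One decomposition row per forecast method (columns S, MCB, DSC, UNC)."""
    from .scores import corp_decompose

    rows = []
    for name, sample in samples.items():
        dec = corp_decompose(sample, rule)
        rows.append(
            {
                "forecast": name,
                "mean_score": dec.S_X,
                "MCB": dec.mcb,
                "DSC": dec.dsc,
                "UNC": dec.unc,
            }
        )
    return pd.DataFrame(rows)
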