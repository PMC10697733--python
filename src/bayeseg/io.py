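"""Table reading/writing and JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DataValidationError, TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "write_report", "jsonify"]

SIGMA_COLUMN = "sigma"


def _sniff_sep(path: Path) -> str:
    """Guess the delimiter (comma/tab/semicolon) from the header line."""
    import csv

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_timeseries(path, sigma_column: str = SIGMA_COLUMN) -> TimeSeries:
    """Load a CSV/TSV table: first column x, then y replicates, optional sigma.

    The delimiter is sniffed by pandas; a header row is required.  Missing
    values are rejected (the likelihood factorization assumes a complete
    grid).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: need at least an x and one y column")
    if df.isna().any().any():
        rows = list(df.index[df.isna().any(axis=1)][:10] + 2)  # header is row 1
        raise DataValidationError(f"{path}: missing values at file row(s) {rows}")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    dup = np.nonzero(np.diff(x) == 0)[0]
    if dup.size:
        rows = list(dup + 3)  # second of each duplicate pair, 1-based with header
        raise DataValidationError(f"{path}: duplicate x values at file row(s) {rows}")
    sigma = None
    ycols = list(df.columns[1:])
    if sigma_column in ycols:
        sigma = df[sigma_column].to_numpy(dtype=float)
        ycols.remove(sigma_column)
    if not ycols:
        raise DataValidationError(f"{path}: no y columns left after sigma")
    y = df[ycols].to_numpy(dtype=float).T
    return TimeSeries(x=x, y=y, sigma=sigma)


def write_timeseries(ts: TimeSeries, path, x_name: str = "x") -> None:
    """Write a TimeSeries in the standard CSV layout (round-trip exact)."""
    cols = {x_name: ts.x}
    for r in range(ts.N_r):
        cols[f"y{r + 1}"] = ts.y[r]
    if ts.sigma is not None:
        cols[SIGMA_COLUMN] = ts.sigma
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def jsonify(obj):
    """Recursively convert numpy/dataclass values to plain JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("-inf" if obj < 0 else "inf")
    return obj


def write_report(payload: dict, path) -> None:
    """Write a JSON report deterministically (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(jsonify(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
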