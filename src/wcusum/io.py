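"""Reading numeric matrices and serializing test results.

Input files are plain CSV/TSV numeric tables, rows = time points by
default, with an optional single header row (auto-detected when the
first row is non-numeric).  Results round-trip through JSON; power
reports are written as CSV with one row per grid cell.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from ._version import __version__
from .errors import InvalidInputError
from .series import SeriesData


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    return ","


def read_matrix(path, delimiter: str | None = None, transpose: bool = False) -> SeriesData:
    """Read an n x q numeric table into SeriesData.

    A single leading header row is skipped automatically when any of
    its cells fails to parse as a number.  Ragged rows and non-numeric
    body cells raise typed errors naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file not found: {path}")
    delim = _sniff_delimiter(path, delimiter)
    rows: list[list[float]] = []
    width = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, rec in enumerate(reader, start=1):
            rec = [c.strip() for c in rec if c.strip() != ""] if rec else []
            if not rec:
                continue
            try:
                vals = [float(c) for c in rec]
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise InvalidInputError(f"{path}:{lineno}: non-numeric cell in {rec!r}") from None
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise InvalidInputError(
                    f"{path}:{lineno}: ragged row of width {len(vals)}, expected {width}"
                )
            rows.append(vals)
    if not rows:
        raise InvalidInputError(f"{path}: no numeric data found")
    arr = np.asarray(rows, dtype=float)
    if transpose:
        arr = arr.T
    if arr.shape[0] < 3:
        raise InvalidInputError(
            f"{path}: need at least 3 time points (rows), got {arr.shape[0]}; "
            "use transpose=True if time runs across columns"
        )
    return SeriesData(arr)


def write_result(result, path, fmt: str = "json", seed: int | None = None) -> None:
    """Serialize a results object (or PowerReport) to JSON or CSV."""
    path = Path(path)
    try:
        if hasattr(result, "table"):  # PowerReport
            if fmt == "csv":
                result.table.to_csv(path, index=False)
            else:
                payload = {"software_version": __version__, "seed": seed,
                           "cells": result.table.to_dict(orient="records")}
                path.write_text(json.dumps(payload, indent=2) + "\n")
            return
        payload = result.to_dict()
        payload["software_version"] = __version__
        if seed is not None:
            payload["seed"] = seed
        if fmt == "json":
            path.write_text(json.dumps(payload, indent=2) + "\n")
        elif fmt == "csv":
            with path.open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(payload.keys())
                writer.writerow(payload.values())
        else:
            raise InvalidInputError(f"format must be 'json' or 'csv', got {fmt!r}")
    except OSError as exc:
        raise InvalidInputError(f"cannot write result to {path}: {exc}") from exc


def read_result(path) -> dict:
    """Read back a JSON result written by :func:`write_result`."""
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InvalidInputError(f"cannot read result from {path}: {exc}") from exc
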