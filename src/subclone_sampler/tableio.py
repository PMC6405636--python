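"""Reading and writing design tables and one-row result records.

The on-disk contract: a single header line, tab- (or comma-) separated,
column names and order exactly as in :data:`~subclone_sampler.design.TABLE_COLUMNS`,
floats printed with 6 significant digits.  Every emitted table re-parses
into an equal :class:`DesignTable`.
"""

from __future__ import annotations

import sys
from typing import IO

import pandas as pd

from .design import TABLE_COLUMNS, DesignTable

__all__ = ["format_float", "write_design_table", "read_design_table", "write_record"]

_DELIMS = {"tsv": "\t", "csv": ","}


def format_float(x: float) -> str:
    """6 significant digits; integral values kept integral."""
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e15:
        return str(int(xf))
    return f"{xf:.6g}"


def _open_out(path: str | None) -> tuple[IO[str], bool]:
    if path is None or path == "-":
        return sys.stdout, False
    return open(path, "w"), True


def write_record(fields: dict, path: str | None = None, fmt: str = "tsv") -> None:
    """One header line + one value line."""
    delim = _DELIMS[fmt]
    out, close = _open_out(path)
    try:
        out.write(delim.join(fields.keys()) + "\n")
        out.write(
            delim.join(
                format_float(v) if isinstance(v, float) else str(v)
                for v in fields.values()
            )
            + "\n"
        )
    finally:
        if close:
            out.close()


def write_design_table(
    table: DesignTable, path: str | None = None, fmt: str = "tsv"
) -> None:
    delim = _DELIMS[fmt]
    out, close = _open_out(path)
    try:
        out.write(delim.join(TABLE_COLUMNS) + "\n")
        for row in table.frame.itertuples(index=False):
            out.write(
                delim.join(
                    [
                        format_float(float(row.frequency)),
                        str(int(row.subclone_count)),
                        format_float(float(row.confidence)),
                        str(int(row.min_captured)),
                        str(int(row.min_sample_size)),
                        format_float(float(row.achieved_probability)),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            out.close()


def read_design_table(path: str, pop_size: int, fmt: str = "tsv") -> DesignTable:
    """Parse a written table back; the population size is metadata not
    stored in the rows, so the caller supplies it."""
    frame = pd.read_csv(path, sep=_DELIMS[fmt])
    if list(frame.columns) != TABLE_COLUMNS:
        raise ValueError(
            f"unexpected columns {list(frame.columns)}; expected {TABLE_COLUMNS}"
        )
    frame = frame.astype(
        {
            "frequency": float,
            "subclone_count": int,
            "confidence": float,
            "min_captured": int,
            "min_sample_size": int,
            "achieved_probability": float,
        }
    )
    freqs = tuple(dict.fromkeys(frame["frequency"].tolist()))
    confs = tuple(dict.fromkeys(frame["confidence"].tolist()))
    k = int(frame["min_captured"].iloc[0]) if len(frame) else 0
    return DesignTable(int(pop_size), k, freqs, confs, frame)
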