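"""Readers and writers for peak tables, annotations and result tables.

All files are delimited UTF-8 text with a header row: comma-separated on
write, comma or tab sniffed on read. Peak tables carry one sample-id column
plus the 39 GP columns in any order; they are canonicalized to GP1..GP39.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import (
    GP_COLUMNS,
    RESULT_COLUMNS,
    GlycanPeakMatrix,
    MetaResultRow,
    frame_to_rows,
    rows_to_frame,
    validate_annotation,
)
from .exceptions import SchemaError, ValidationError

_ID_CANDIDATES = ("sample_id", "sample", "id")


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=None, engine="python")


def read_peak_table(
    path: str | os.PathLike, id_column: str | None = None, scale_tag: str = "raw"
) -> GlycanPeakMatrix:
    """Read a sample × peak table into a :class:`GlycanPeakMatrix`.

    Parameters
    ----------
    path
        CSV/TSV file with a sample-id column and 39 GP columns.
    id_column
        Name of the sample-id column; autodetected among
        ``sample_id``/``sample``/``id`` (else the first non-GP column).
    scale_tag
        Scale of the stored values; files written upstream of normalization
        are ``raw`` (the default).
    """
    frame = _read_delimited(path)
    if id_column is None:
        candidates = [c for c in _ID_CANDIDATES if c in frame.columns]
        if not candidates:
            nongp = [c for c in frame.columns if c not in GP_COLUMNS]
            if not nongp:
                raise SchemaError("peak table lacks a sample-id column")
            candidates = [nongp[0]]
        id_column = candidates[0]
    elif id_column not in frame.columns:
        raise SchemaError(f"id column {id_column!r} not in file")
    frame = frame.set_index(id_column)
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    return GlycanPeakMatrix(frame, scale_tag)


def write_peak_table(matrix: GlycanPeakMatrix, path: str | os.PathLike) -> None:
    out = matrix.data.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, index=False, float_format="%.12g")


def read_annotation(
    path: str | os.PathLike, centers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read and validate a sample-annotation table (one row per sample)."""
    frame = _read_delimited(path)
    frame["sample_id"] = frame["sample_id"].astype(str)
    return validate_annotation(frame, centers=centers)


def write_annotation(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    annotation.to_csv(path, index=False)


def write_result_table(
    rows: Iterable[MetaResultRow] | pd.DataFrame, path: str | os.PathLike
) -> None:
    """Write meta-analysis results sorted by adjusted p ascending.

    Values are written at 12 significant digits so that a write→read round
    trip reproduces them at that precision; use
    :func:`format_result_table` for the human-facing rendering.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    if len(frame) == 0:
        raise ValidationError("nothing to write: empty result set")
    frame = frame.sort_values(
        ["p_adjusted", "p_value", "trait_code"], kind="mergesort"
    ).reset_index(drop=True)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_result_table(
    path: str | os.PathLike, as_rows: bool = False
) -> pd.DataFrame | list[MetaResultRow]:
    frame = _read_delimited(path)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"result table missing columns: {missing}")
    frame = frame.loc[:, list(RESULT_COLUMNS)]
    return frame_to_rows(frame) if as_rows else frame


def format_result_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Render results the way published glycome tables print them.

    Effects and standard errors at 5 decimals; p-values in scientific
    notation with 3 significant digits below 1e-3, else 5 decimals.
    """

    def fmt_p(p: float) -> str:
        return f"{p:.2e}" if p < 1e-3 else f"{p:.5f}"

    out = frame.copy()
    for col in ("effect", "se", "ci_low", "ci_high"):
        out[col] = out[col].map(lambda v: f"{v:.5f}")
    out["tau2"] = out["tau2"].map(lambda v: f"{v:.6f}")
    for col in ("p_value", "p_adjusted"):
        out[col] = out[col].map(fmt_p)
    return out
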