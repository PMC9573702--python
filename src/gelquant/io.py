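"""Reading and writing the plain-text tabular formats of the pipeline.

Spot tables are CSV/TSV with a ``spot_id`` column, one column per gel and
optional trailing metadata columns (``pI_obs``, ``Mr_obs_kDa``).  Empty
cells denote spots not detected on that gel; explicit zeros are detected
zero-volume spots.  Design files map ``gel_id`` to ``group`` with an
optional ``replicate`` column.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SPOT_META_COLUMNS, ExperimentDesign, SpotVolumeTable
from .errors import FormatError, ValidationError


def _sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if Path(path).suffix.lower() in (".tsv", ".tab") else "csv"
    if dialect not in ("csv", "tsv"):
        raise FormatError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _header(path: Path, sep: str) -> list[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            return next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None


def read_spot_table(path, dialect: str | None = None) -> SpotVolumeTable:
    """Read a spot-volume table from CSV/TSV.

    Gel identity is carried by the header names, not by column position.
    Raises :class:`FormatError` for duplicate ids and
    :class:`ValidationError` for negative volumes.
    """
    path = Path(path)
    sep = _sep(path, dialect)
    header = _header(path, sep)
    if not header or header[0] != "spot_id":
        raise FormatError(f"{path}: first column must be 'spot_id', got {header[:1]}")
    gel_cols = [c for c in header[1:] if c not in SPOT_META_COLUMNS]
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"{path}: duplicate column names {dups}")
    df = pd.read_csv(path, sep=sep, dtype={"spot_id": str})
    df = df.set_index("spot_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate spot ids {dups}")
    meta_cols = [c for c in SPOT_META_COLUMNS if c in df.columns]
    meta = df[meta_cols].astype(float) if meta_cols else None
    vols = df[gel_cols]
    try:
        vols = vols.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric volume entry ({exc})") from None
    return SpotVolumeTable(vols, meta)


def write_spot_table(table: SpotVolumeTable, path, dialect: str | None = None) -> None:
    """Write a table so that :func:`read_spot_table` reproduces it.

    Missing entries become empty cells.  Volumes are written with full
    float precision (round-trip exact to 1e-9 and beyond).
    """
    path = Path(path)
    sep = _sep(path, dialect)
    out = table.volumes.copy()
    if table.spot_meta is not None:
        for col in table.spot_meta.columns:
            out[col] = table.spot_meta[col]
    out.to_csv(path, sep=sep, index_label="spot_id", na_rep="",
               float_format=None)


def read_design(path, dialect: str | None = None) -> ExperimentDesign:
    """Read a gel-to-group design file.

    Two columns (``gel_id, group``) or three (``gel_id, group, replicate``);
    replicate indices are auto-assigned in file order when absent.
    """
    path = Path(path)
    sep = _sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    expected = {"gel_id", "group"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: design needs columns gel_id and group")
    if df["gel_id"].duplicated().any():
        dups = df.loc[df["gel_id"].duplicated(), "gel_id"].unique().tolist()
        raise FormatError(f"{path}: gel assigned more than once: {dups}")
    df = df.set_index("gel_id")
    keep = ["group"] + (["replicate"] if "replicate" in df.columns else [])
    try:
        return ExperimentDesign(df[keep])
    except ValidationError:
        raise


def write_design(design: ExperimentDesign, path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep(path, dialect)
    design.assignment.to_csv(path, sep=sep, index_label="gel_id")
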