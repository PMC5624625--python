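"""Readers and writers for trees, community, trait and metadata tables.

Delimited tables are UTF-8 with a header row; the delimiter (tab or comma) is
auto-detected from the header line and the first column holds the row labels.
Braun-Blanquet ordinal cover codes are converted to percent-cover midpoints
via a configurable mapping.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datamodel import (
    CLIMATE_COLUMNS,
    METADATA_COLUMNS,
    TRAIT_COLUMNS,
    CommunityMatrix,
    DistanceMatrix,
    FormatError,
    Phylogeny,
    TraitTable,
)

__all__ = [
    "BRAUN_BLANQUET_MIDPOINTS",
    "bb_to_cover",
    "read_newick",
    "write_newick",
    "read_community",
    "read_traits",
    "read_metadata",
    "write_table",
    "read_distance",
    "write_distance",
]

#: percent-cover midpoints for the Braun-Blanquet ordinal scale.
#: r/+ are the conventional trace values; classes 1–5 take the midpoint of
#: their cover interval (1–5, 5–25, 25–50, 50–75, 75–100 %).
BRAUN_BLANQUET_MIDPOINTS: dict[str, float] = {
    "r": 0.1,
    "+": 0.5,
    "1": 2.5,
    "2": 15.0,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}


def bb_to_cover(code: str, mapping: dict[str, float] | None = None) -> float:
    """Convert a Braun-Blanquet cover-abundance code to a percent-cover midpoint.

    Parameters
    ----------
    code
        One of ``r, +, 1, 2, 3, 4, 5`` (whitespace tolerated).
    mapping
        Alternative code → midpoint table; defaults to
        :data:`BRAUN_BLANQUET_MIDPOINTS`.
    """
    table = BRAUN_BLANQUET_MIDPOINTS if mapping is None else mapping
    key = str(code).strip()
    if key not in table:
        raise FormatError(
            f"unknown Braun-Blanquet code {code!r}; accepted codes: {sorted(table)}"
        )
    return float(table[key])


def read_newick(path: str | Path | _io.StringIO) -> Phylogeny:
    """Parse a rooted Newick tree with branch lengths."""
    if isinstance(path, _io.StringIO):
        text = path.getvalue()
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse Newick: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylogeny.as_newick() + "\n", encoding="utf-8")


def _detect_sep(path: str | Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def _read_labelled(path: str | Path) -> pd.DataFrame:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def read_community(
    path: str | Path,
    braun_blanquet: bool = False,
    bb_mapping: dict[str, float] | None = None,
) -> CommunityMatrix:
    """Read a plots × species abundance table.

    With ``braun_blanquet=True`` cell values are ordinal cover codes
    (blank / 0 meaning absent) and are converted to percent-cover midpoints.
    """
    df = _read_labelled(path)
    if braun_blanquet:
        def convert(cell: object) -> float:
            if pd.isna(cell) or str(cell).strip() in {"", "0", "0.0"}:
                return 0.0
            return bb_to_cover(str(cell), bb_mapping)

        df = df.map(convert)
    df = df.astype(float)
    return CommunityMatrix(df)


def read_traits(path: str | Path) -> TraitTable:
    """Read a species-rows trait table; unknown columns are preserved but ignored."""
    return TraitTable(_read_labelled(path))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-plot metadata (transect, elevation, coordinates, slope, RAR, climate)."""
    df = _read_labelled(path)
    required = list(METADATA_COLUMNS) + list(CLIMATE_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata columns: {missing}")
    numeric = [c for c in required if c != "transect_id"]
    df[numeric] = df[numeric].astype(float)
    rar = df["rar"].to_numpy()
    if np.any((rar < 0) | (rar > 1)):
        raise FormatError("rar outside [0, 1]")
    if np.any(np.abs(df["latitude"].to_numpy()) > 90):
        raise FormatError("latitude outside [-90, 90]")
    if np.any(np.abs(df["longitude"].to_numpy()) > 180):
        raise FormatError("longitude outside [-180, 180]")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a labelled table as TSV, optionally preceded by a ``#`` comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


def read_distance(path: str | Path) -> DistanceMatrix:
    df = _read_labelled(path)
    return DistanceMatrix(labels=[str(c) for c in df.index], values=df.to_numpy(dtype=float))


def write_distance(dm: DistanceMatrix, path: str | Path, header_comment: str | None = None) -> None:
    write_table(dm.to_frame(), path, header_comment)
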