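"""Readers and writers for the plain-text formats used across the toolkit.

All tabular formats are TSV with a mandatory header, UTF-8, no quoting.
FASTA input may be gzip-compressed (detected by the ``.gz`` suffix).
Record ids are the FASTA header up to the first whitespace and are
treated as opaque strings.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "read_groups",
    "read_mapping",
    "write_manifest",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> sequence map.

    Sequences are uppercased; duplicate ids raise a ``ValueError``.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 80) -> None:
    """Write an id -> sequence map as multi-FASTA with line wrapping."""
    with _open_text(path, "wt") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature x sample count table (first column: feature id).

    Counts must be non-negative integers; violations are reported with
    the 1-based line number of the offending row.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature table {path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate feature ids in {path}: {dups}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
        if bad.any():
            line = int(bad.to_numpy().argmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"non-negative integer count required at line {line}, "
                f"column {col!r} of {path}"
            )
        df[col] = numeric.astype(int)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by its first (sample id) column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    df.index = df.index.astype(str)
    return df


def read_groups(path) -> dict[str, set[str]]:
    """Read a category-group TSV with columns ``group`` and ``category``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"group", "category"} <= set(df.columns):
        raise ValueError(f"group file {path} needs columns 'group' and 'category'")
    groups: dict[str, set[str]] = {}
    for row in df.itertuples():
        groups.setdefault(row.group, set()).add(row.category)
    return groups


def read_mapping(path) -> dict[str, str]:
    """Read a reference -> representative TSV mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"mapping file {path} needs two columns")
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_manifest(path, manifest: dict) -> None:
    """Write a JSON run manifest (inputs, parameters, seed, versions)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
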