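"""Habitat-labeled 16S rRNA reference databases.

A reference database is a collection of 16S rRNA gene sequences, each
labeled with exactly one environmental category (``soil``, ``marine``,
``human_gut``, ...) and the identifier of the research project it was
mined from.  Because public metagenome projects differ enormously in
size, databases are balanced by capping the number of sequences any
single project contributes per category (:func:`cap_per_project`).

The per-category sequence/project census of the public ProkAtlas habitat
database ships with the package (:func:`builtin_category_counts`) so that
coverage summaries can be reproduced without downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import io as hio

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledReference",
    "ReferenceDatabase",
    "load_reference_db",
    "cap_per_project",
    "category_summary",
    "builtin_category_counts",
    "write_db",
    "read_db",
]

_VALID_BASES = frozenset("ACGTN")


def _validate_sequence(seq_id: str, sequence: str) -> str:
    seq = sequence.upper()
    if len(seq) < 1:
        raise ValueError(f"sequence {seq_id!r} is empty")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains unsupported characters "
            f"{sorted(bad)}; only A, C, G, T and N are accepted"
        )
    return seq


@dataclass(frozen=True)
class LabeledReference:
    """One reference 16S sequence with its habitat label.

    Attributes
    ----------
    sequence_id : str
        Unique identifier within a database.
    sequence : str
        DNA over the alphabet {A, C, G, T, N}.
    category : str
        Environmental category label (lowercase token, e.g. ``"soil"``).
    project_id : str
        Identifier of the research project the sequence came from.
    """

    sequence_id: str
    sequence: str
    category: str
    project_id: str

    def __post_init__(self) -> None:
        if not self.category:
            raise ValueError("category must be non-empty")
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence_id, self.sequence)
        )


class ReferenceDatabase:
    """An in-memory collection of :class:`LabeledReference` records.

    Per-category and per-(category, project) sequence counts are derived
    from the records on construction, so they can never drift out of sync
    with the sequences themselves.
    """

    def __init__(self, references: Iterable[LabeledReference]):
        refs = list(references)
        seen: set[str] = set()
        for ref in refs:
            if ref.sequence_id in seen:
                raise ValueError(f"duplicate sequence_id {ref.sequence_id!r}")
            seen.add(ref.sequence_id)
        self._refs = refs
        self._by_id = {r.sequence_id: r for r in refs}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._refs)

    def __iter__(self) -> Iterator[LabeledReference]:
        return iter(self._refs)

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self._by_id

    def __getitem__(self, sequence_id: str) -> LabeledReference:
        return self._by_id[sequence_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return self._refs == other._refs

    # -- derived views ------------------------------------------------------
    @property
    def references(self) -> list[LabeledReference]:
        return list(self._refs)

    @property
    def categories(self) -> list[str]:
        return sorted({r.category for r in self._refs})

    @property
    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self._refs:
            sizes[r.category] = sizes.get(r.category, 0) + 1
        return sizes

    @property
    def project_sizes(self) -> dict[tuple[str, str], int]:
        sizes: dict[tuple[str, str], int] = {}
        for r in self._refs:
            key = (r.category, r.project_id)
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    def category_of(self, sequence_id: str) -> str:
        return self._by_id[sequence_id].category


def load_reference_db(fasta_path, labels_path) -> ReferenceDatabase:
    """Load a reference database from a FASTA file plus a label table.

    The label table is a TSV with header columns ``sequence_id``,
    ``category`` and ``project_id``.  Every labeled id must exist in the
    FASTA; FASTA records without a label are skipped with a warning.
    """
    sequences = hio.read_fasta(fasta_path)
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"sequence_id", "category", "project_id"}
    missing_cols = required - set(labels.columns)
    if missing_cols:
        raise ValueError(
            f"label table {labels_path} lacks columns {sorted(missing_cols)}"
        )
    dup = labels["sequence_id"][labels["sequence_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"duplicate sequence_id in label table: {sorted(dup.unique())}"
        )
    missing = [sid for sid in labels["sequence_id"] if sid not in sequences]
    if missing:
        raise ValueError(
            f"label table references ids absent from FASTA: {missing}"
        )
    refs = [
        LabeledReference(row.sequence_id, sequences[row.sequence_id],
                         row.category, row.project_id)
        for row in labels.itertuples()
    ]
    n_unlabeled = len(sequences) - len(refs)
    if n_unlabeled:
        logger.warning(
            "%d FASTA record(s) have no label and were skipped", n_unlabeled
        )
    return ReferenceDatabase(refs)


def cap_per_project(
    db: ReferenceDatabase, cap: int = 100, seed: int = 0
) -> ReferenceDatabase:
    """Subsample so no (category, project) pair exceeds ``cap`` sequences.

    Projects over the cap are downsampled uniformly at random without
    replacement; the result is deterministic for a fixed ``seed``, keeps
    the original record order, and is idempotent.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[LabeledReference]] = {}
    for ref in db:
        groups.setdefault((ref.category, ref.project_id), []).append(ref)
    keep: set[str] = set()
    # iterate in deterministic (sorted) group order so the RNG stream does
    # not depend on record order within the input
    for key in sorted(groups):
        members = groups[key]
        if len(members) <= cap:
            keep.update(r.sequence_id for r in members)
        else:
            idx = rng.choice(len(members), size=cap, replace=False)
            keep.update(members[i].sequence_id for i in idx)
    return ReferenceDatabase(r for r in db if r.sequence_id in keep)


def category_summary(
    db_or_counts: ReferenceDatabase | Mapping[str, int],
) -> pd.DataFrame:
    """Tabulate per-category sequence counts and cumulative coverage.

    Returns a DataFrame sorted by decreasing count with columns
    ``category``, ``n_sequences``, ``fraction`` and
    ``cumulative_fraction`` (fraction of all sequences covered by the
    largest k categories, row k).
    """
    if isinstance(db_or_counts, ReferenceDatabase):
        counts = db_or_counts.category_sizes
    else:
        counts = dict(db_or_counts)
    if not counts or sum(counts.values()) <= 0:
        raise ValueError("no categories with positive counts")
    ser = pd.Series(counts, name="n_sequences").sort_values(
        ascending=False, kind="stable"
    )
    total = ser.sum()
    out = ser.to_frame()
    out.index.name = "category"
    out = out.reset_index()
    out["fraction"] = out["n_sequences"] / total
    out["cumulative_fraction"] = out["fraction"].cumsum()
    return out


def builtin_category_counts() -> pd.DataFrame:
    """The per-category census of the public ProkAtlas habitat database.

    Columns: ``category``, ``n_sequences``, ``n_projects``.  115
    environmental categories totalling 361,474 sequences.
    """
    with resources.files("habscore.data").joinpath(
        "prokatlas_categories.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


# -- persistence ------------------------------------------------------------

_MANIFEST = "manifest.json"
_FASTA = "references.fasta"
_LABELS = "labels.tsv"


def write_db(db: ReferenceDatabase, path, extra_manifest: dict | None = None) -> None:
    """Persist a database as a directory: FASTA + label TSV + JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    hio.write_fasta({r.sequence_id: r.sequence for r in db}, path / _FASTA)
    with open(path / _LABELS, "w") as fh:
        fh.write("sequence_id\tcategory\tproject_id\n")
        for r in db:
            fh.write(f"{r.sequence_id}\t{r.category}\t{r.project_id}\n")
    manifest = {
        "format": "habscore-reference-db",
        "version": 1,
        "n_references": len(db),
        "category_sizes": db.category_sizes,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(path / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_db(path) -> ReferenceDatabase:
    """Load a database persisted by :func:`write_db`, verifying its counts."""
    path = Path(path)
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise ValueError(f"{path} is not a reference database (no {_MANIFEST})")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt manifest in {path}: {exc}") from exc
    db = load_reference_db(path / _FASTA, path / _LABELS)
    if manifest.get("n_references") != len(db):
        raise ValueError(
            f"manifest of {path} promises {manifest.get('n_references')} "
            f"references but {len(db)} were loaded; archive is truncated "
            "or inconsistent"
        )
    if manifest.get("category_sizes") != db.category_sizes:
        raise ValueError(f"manifest category counts of {path} do not match data")
    return db
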