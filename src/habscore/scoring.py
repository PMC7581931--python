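"""Habitat preference scores for query sequences and whole communities.

The habitat preference score of a query sequence is the composition of
environmental-category labels among its significant reference hits: if
a query hits two soil-labeled and one marine-labeled reference, its
score is {soil: 2/3, marine: 1/3}.  Because near-identical reference
sequences occur in several categories, a single query is routinely
mapped to more than one habitat; the score is therefore always read as
a composition (non-negative, summing to one), not as a classification.

A community sample is scored by averaging the score vectors of its
mapped features, weighted by read abundance by default.  Features with
no hit are excluded and reported separately as coverage (fraction of
features mapped, fraction of reads in mapped features), mirroring how
mapping rates are usually reported alongside the compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference_db import ReferenceDatabase
from .search import AlignmentHit, KmerIndex, SearchParams, build_index, search_queries

__all__ = [
    "HabitatScore",
    "CommunityProfile",
    "CoverageReport",
    "score_query",
    "score_queries",
    "score_community",
    "merge_categories",
    "score_matrix",
]


@dataclass(frozen=True)
class HabitatScore:
    """A composition over environmental categories for one subject.

    ``mapped`` is False when the subject had no significant hit, in
    which case ``scores`` is empty and ``n_hits`` is 0.
    """

    subject_id: str
    scores: Mapping[str, float] = field(default_factory=dict)
    n_hits: int = 0
    mapped: bool = False

    def __post_init__(self) -> None:
        if self.mapped:
            total = sum(self.scores.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"scores of {self.subject_id!r} sum to {total}, not 1"
                )
            if any(v < 0 for v in self.scores.values()):
                raise ValueError("scores must be non-negative")
        elif self.scores or self.n_hits:
            raise ValueError("unmapped subjects carry no scores and no hits")

    def get(self, category: str) -> float:
        return self.scores.get(category, 0.0)

    def group_sum(self, categories: Iterable[str]) -> float:
        return sum(self.scores.get(c, 0.0) for c in categories)


@dataclass(frozen=True)
class CoverageReport:
    """Mapping coverage of one sample: feature fraction and read fraction."""

    features_mapped: float
    reads_mapped: float


class CommunityProfile:
    """A feature x sample count table joined to feature sequences.

    ``counts`` is features (rows) by samples (columns), non-negative
    integers; every feature id must have a sequence.
    """

    def __init__(self, counts: pd.DataFrame, feature_sequences: Mapping[str, str]):
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [f for f in counts.index if f not in feature_sequences]
        if missing:
            raise ValueError(f"features without a sequence: {missing}")
        self.counts = counts.astype(int)
        self.feature_sequences = {f: feature_sequences[f] for f in counts.index}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def score_query(
    hits_for_one_query: Iterable[AlignmentHit],
    db: ReferenceDatabase,
    normalize_by_category_size: bool = False,
) -> HabitatScore:
    """Score one query from its hits against a labeled reference database.

    Default scoring counts hit references per category and normalizes to
    a composition.  With ``normalize_by_category_size`` each category
    count is divided by the category's database size before
    renormalizing, which damps the dominance of very large categories.
    """
    hits = list(hits_for_one_query)
    if not hits:
        return HabitatScore(subject_id="", mapped=False)
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(query_ids)}")
    ref_ids = [h.reference_id for h in hits]
    if len(set(ref_ids)) != len(ref_ids):
        raise ValueError("each reference may appear at most once per query")
    missing = [r for r in ref_ids if r not in db]
    if missing:
        raise ValueError(f"hits reference ids absent from the database: {missing}")
    counts: dict[str, float] = {}
    for h in hits:
        cat = db.category_of(h.reference_id)
        counts[cat] = counts.get(cat, 0.0) + 1.0
    if normalize_by_category_size:
        sizes = db.category_sizes
        counts = {c: n / sizes[c] for c, n in counts.items()}
    total = sum(counts.values())
    return HabitatScore(
        subject_id=next(iter(query_ids)),
        scores={c: v / total for c, v in counts.items()},
        n_hits=len(hits),
        mapped=True,
    )


def score_queries(
    hits: Iterable[AlignmentHit],
    db: ReferenceDatabase,
    normalize_by_category_size: bool = False,
) -> dict[str, HabitatScore]:
    """Group hits by query id and score each query."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return {
        qid: score_query(qhits, db, normalize_by_category_size)
        for qid, qhits in by_query.items()
    }


def score_community(
    profile: CommunityProfile,
    per_feature_scores: Mapping[str, HabitatScore],
    sample_id: str,
    weight_by_abundance: bool = True,
) -> tuple[HabitatScore, CoverageReport]:
    """Aggregate feature scores into one community-level habitat score.

    The community score is the read-abundance-weighted mean of the score
    vectors of mapped features present in the sample, renormalized over
    mapped features only (an unweighted mean when ``weight_by_abundance``
    is off).  Coverage reports the mapped fraction of features present
    in the sample and of their reads.
    """
    if sample_id not in profile.counts.columns:
        raise KeyError(f"sample {sample_id!r} not in profile")
    col = profile.counts[sample_id]
    present = col[col > 0]
    if present.empty:
        return (
            HabitatScore(subject_id=sample_id, mapped=False),
            CoverageReport(0.0, 0.0),
        )
    mapped_features = [
        f for f in present.index
        if f in per_feature_scores and per_feature_scores[f].mapped
    ]
    features_cov = len(mapped_features) / len(present)
    total_reads = int(present.sum())
    mapped_reads = int(present[mapped_features].sum()) if mapped_features else 0
    reads_cov = mapped_reads / total_reads
    if not mapped_features:
        return (
            HabitatScore(subject_id=sample_id, mapped=False),
            CoverageReport(features_cov, reads_cov),
        )
    accum: dict[str, float] = {}
    weight_total = 0.0
    for f in mapped_features:
        w = float(present[f]) if weight_by_abundance else 1.0
        weight_total += w
        for cat, v in per_feature_scores[f].scores.items():
            accum[cat] = accum.get(cat, 0.0) + w * v
    scores = {c: v / weight_total for c, v in accum.items()}
    total = sum(scores.values())
    scores = {c: v / total for c, v in scores.items()}
    n_hits = sum(per_feature_scores[f].n_hits for f in mapped_features)
    return (
        HabitatScore(subject_id=sample_id, scores=scores, n_hits=n_hits, mapped=True),
        CoverageReport(features_cov, reads_cov),
    )


def merge_categories(
    score: HabitatScore,
    groups: Mapping[str, Iterable[str]],
    include_other: bool = True,
    other_label: str = "other",
) -> HabitatScore:
    """Sum category scores into user-defined groups, preserving the total.

    Groups must be disjoint; categories covered by no group are pooled
    into ``other_label`` (or dropped, renormalizing, when
    ``include_other`` is off).
    """
    group_sets = {g: set(cats) for g, cats in groups.items()}
    seen: dict[str, str] = {}
    for g, cats in group_sets.items():
        for c in cats:
            if c in seen:
                raise ValueError(
                    f"category {c!r} appears in groups {seen[c]!r} and {g!r}"
                )
            seen[c] = g
    if not score.mapped:
        return HabitatScore(subject_id=score.subject_id, mapped=False)
    merged = {g: sum(score.scores.get(c, 0.0) for c in cats)
              for g, cats in group_sets.items()}
    leftover = sum(v for c, v in score.scores.items() if c not in seen)
    if include_other:
        merged[other_label] = leftover
    else:
        total = sum(merged.values())
        if total <= 0:
            return HabitatScore(subject_id=score.subject_id, mapped=False)
        merged = {g: v / total for g, v in merged.items()}
    # squash float drift so the composition invariant holds exactly enough
    total = sum(merged.values())
    merged = {g: v / total for g, v in merged.items()} if total > 0 else merged
    return HabitatScore(
        subject_id=score.subject_id,
        scores=merged,
        n_hits=score.n_hits,
        mapped=True,
    )


def score_matrix(
    profile: CommunityProfile,
    db: ReferenceDatabase,
    params: SearchParams | None = None,
    index: KmerIndex | None = None,
    weight_by_abundance: bool = True,
    normalize_by_category_size: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Search + score an entire community study in one call.

    Every feature sequence is searched once against ``db``; each sample
    is then aggregated with :func:`score_community`.  Returns
    ``(scores, coverage)``: a sample x category table (rows of mapped
    samples sum to 1; unmapped samples are all-NaN) and a per-sample
    coverage table with columns ``coverage_features``/``coverage_reads``.
    """
    params = params or SearchParams()
    hits = search_queries(
        profile.feature_sequences, db, params,
        index if index is not None else build_index(db, params.kmer_size),
    )
    per_feature = score_queries(hits, db, normalize_by_category_size)
    categories = db.categories
    rows = {}
    cov_rows = {}
    for sample_id in profile.sample_ids:
        score, cov = score_community(
            profile, per_feature, sample_id, weight_by_abundance
        )
        if score.mapped:
            rows[sample_id] = {c: score.scores.get(c, 0.0) for c in categories}
        else:
            rows[sample_id] = {c: np.nan for c in categories}
        cov_rows[sample_id] = {
            "coverage_features": cov.features_mapped,
            "coverage_reads": cov.reads_mapped,
        }
    scores_df = pd.DataFrame.from_dict(rows, orient="index")[categories]
    scores_df.index.name = "sample_id"
    cov_df = pd.DataFrame.from_dict(cov_rows, orient="index")
    cov_df.index.name = "sample_id"
    return scores_df, cov_df
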