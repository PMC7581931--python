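"""Similarity search of query 16S sequences against a labeled reference set.

A hit is a local alignment passing two filters: a minimum aligned length
(default 150 bp, long enough for reliable habitat assignment of partial
16S fragments) and a minimum percent identity (default 97%, the usual
species-level cutoff).  Candidate references are selected through an
exact k-mer index; each candidate pair is then aligned with an exact
affine-gap local (Smith-Waterman) dynamic program.  At most one hit —
the best-scoring HSP — is kept per (query, reference) pair.

Hits can also be imported from, and exported to, 12-column BLAST
tabular (``-outfmt 6``) files, so an external search engine can replace
the built-in one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .reference_db import ReferenceDatabase

__all__ = [
    "SearchParams",
    "AlignmentHit",
    "KmerIndex",
    "build_index",
    "align_pair",
    "search_queries",
    "import_tabular_hits",
    "write_tabular_hits",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds and alignment scoring scheme.

    ``gap_open`` is the cost charged once when a gap is opened, on top of
    ``gap_extend`` which is charged for every gapped position, so a gap
    of length L scores ``gap_open + L * gap_extend``.
    """

    min_aligned_length: int = 150
    min_percent_identity: float = 97.0
    kmer_size: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    max_hits_per_query: int | None = None
    search_both_strands: bool = True
    max_evalue: float | None = None
    min_seed_count: int = 2

    def __post_init__(self) -> None:
        if self.min_aligned_length < self.kmer_size:
            raise ValueError("min_aligned_length must be >= kmer_size")
        if not (0 < self.min_percent_identity <= 100):
            raise ValueError("min_percent_identity must be in (0, 100]")
        if self.match <= 0:
            raise ValueError("match score must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One query -> reference local alignment.

    Coordinates are 1-based inclusive and ascending on both sequences;
    reverse-strand hits are flagged by ``strand == "-"`` with query
    coordinates expressed on the original (plus-strand) query.
    ``aligned_length`` counts alignment columns including gaps, and
    ``percent_identity`` is 100 x matches / aligned_length.
    """

    query_id: str
    reference_id: str
    percent_identity: float
    aligned_length: int
    mismatches: int
    gap_openings: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str = "+"
    score: int = 0

    @property
    def matches(self) -> int:
        return int(round(self.percent_identity * self.aligned_length / 100.0))


# -- k-mer index ------------------------------------------------------------


class KmerIndex:
    """Exact-match k-mer -> (reference_id, offset) postings.

    k-mers containing N are excluded, so N never seeds an alignment.
    """

    def __init__(self, k: int):
        if not (8 <= k <= 16):
            raise ValueError("kmer_size must be in [8, 16]")
        self.k = k
        self.postings: dict[str, list[tuple[str, int]]] = {}

    def add(self, reference_id: str, sequence: str) -> None:
        k = self.k
        for off in range(len(sequence) - k + 1):
            kmer = sequence[off : off + k]
            if "N" in kmer:
                continue
            self.postings.setdefault(kmer, []).append((reference_id, off))

    def candidates(self, sequence: str, min_count: int = 1) -> set[str]:
        """Reference ids sharing >= ``min_count`` distinct k-mers with ``sequence``."""
        k = self.k
        counts: dict[str, int] = {}
        seen_kmers: set[str] = set()
        for off in range(len(sequence) - k + 1):
            kmer = sequence[off : off + k]
            if "N" in kmer or kmer in seen_kmers:
                continue
            seen_kmers.add(kmer)
            for ref_id in {rid for rid, _ in self.postings.get(kmer, ())}:
                counts[ref_id] = counts.get(ref_id, 0) + 1
        return {rid for rid, n in counts.items() if n >= min_count}


def build_index(db: ReferenceDatabase, kmer_size: int = 12) -> KmerIndex:
    """Index every reference sequence of ``db`` by its exact k-mers."""
    index = KmerIndex(kmer_size)
    for ref in db:
        index.add(ref.sequence_id, ref.sequence)
    return index


# -- pairwise alignment -----------------------------------------------------


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            # N is never a match, not even against another N
            matrix[a, b] = (
                params.match if (a == b and a != "N") else params.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_openings, aligned_length) of an alignment."""
    qrow = alignment[0]
    rrow = alignment[1]
    matches = mismatches = gap_openings = 0
    in_gap_q = in_gap_r = False
    for qc, rc in zip(qrow, rrow):
        if qc == "-":
            if not in_gap_q:
                gap_openings += 1
            in_gap_q = True
            in_gap_r = False
        elif rc == "-":
            if not in_gap_r:
                gap_openings += 1
            in_gap_r = True
            in_gap_q = False
        else:
            in_gap_q = in_gap_r = False
            if qc == rc and qc != "N":
                matches += 1
            else:
                mismatches += 1
    return matches, mismatches, gap_openings, len(qrow)


def _best_local_alignment(aligner, query: str, reference: str):
    alignments = aligner.align(query, reference)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    return best


def _align_one_strand(
    query: str,
    reference: str,
    params: SearchParams,
    aligner: Align.PairwiseAligner,
    query_id: str,
    reference_id: str,
    strand: str,
) -> AlignmentHit | None:
    best = _best_local_alignment(aligner, query, reference)
    if best is None:
        return None
    matches, mismatches, gap_openings, aligned_length = _alignment_stats(best)
    q0, q1 = int(best.coordinates[0][0]), int(best.coordinates[0][-1])
    r0, r1 = int(best.coordinates[1][0]), int(best.coordinates[1][-1])
    q_start, q_end = q0 + 1, q1
    if strand == "-":
        # map coordinates on the reverse-complemented query back to the
        # original query, keeping them ascending
        n = len(query)
        q_start, q_end = n - q1 + 1, n - q0
    return AlignmentHit(
        query_id=query_id,
        reference_id=reference_id,
        percent_identity=100.0 * matches / aligned_length,
        aligned_length=aligned_length,
        mismatches=mismatches,
        gap_openings=gap_openings,
        query_start=q_start,
        query_end=q_end,
        ref_start=r0 + 1,
        ref_end=r1,
        strand=strand,
        score=int(round(best.score)),
    )


def _score_floor(params: SearchParams) -> float:
    """Smallest possible score of an alignment passing the filters.

    A passing hit spans at least ``min_aligned_length`` columns with at
    least the identity fraction of matches; in the most penalized case
    every non-match column is a freshly opened gap.  Pairs scoring below
    this floor cannot yield a reportable hit, so a cheap score-only pass
    can skip the full alignment for them.
    """
    import math

    m_min = math.ceil(params.min_percent_identity / 100.0
                      * params.min_aligned_length)
    rest = params.min_aligned_length - m_min
    worst = min(params.mismatch, params.gap_extend)
    return m_min * params.match + rest * (worst + params.gap_open)


def _passes(hit: AlignmentHit, params: SearchParams) -> bool:
    return (
        hit.aligned_length >= params.min_aligned_length
        and hit.percent_identity >= params.min_percent_identity
    )


def _hit_order(hit: AlignmentHit):
    # best score first; ties broken by smaller query start, then
    # reference id, then plus strand
    return (-hit.score, hit.query_start, hit.reference_id, hit.strand)


def align_pair(
    query: str,
    reference: str,
    params: SearchParams | None = None,
    *,
    query_id: str = "query",
    reference_id: str = "reference",
    apply_thresholds: bool = True,
) -> AlignmentHit | None:
    """Best affine-gap local alignment between one query and one reference.

    Both strands of the query are considered when
    ``params.search_both_strands`` is set; the higher-scoring strand
    wins (plus strand on ties).  Returns ``None`` when no alignment has
    positive score, or — unless ``apply_thresholds`` is disabled — when
    the best alignment fails the length/identity filters.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    params = params or SearchParams()
    aligner = _make_aligner(params)
    query = query.upper()
    reference = reference.upper()
    hits = []
    fwd = _align_one_strand(
        query, reference, params, aligner, query_id, reference_id, "+"
    )
    if fwd is not None:
        hits.append(fwd)
    if params.search_both_strands:
        rev = _align_one_strand(
            reverse_complement(query), reference, params, aligner,
            query_id, reference_id, "-",
        )
        if rev is not None:
            hits.append(rev)
    if not hits:
        return None
    best = min(hits, key=_hit_order)
    if apply_thresholds and not _passes(best, params):
        return None
    return best


def search_queries(
    queries: Mapping[str, str] | Iterable[tuple[str, str]],
    db: ReferenceDatabase,
    params: SearchParams | None = None,
    index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """Search every query against ``db`` and collect the passing hits.

    Candidate references for a query are the ones sharing at least one
    exact k-mer with it (on either strand when both are searched); each
    candidate is then aligned exactly.  At most one hit per (query,
    reference) pair is returned, ordered by query id, then descending
    score, then query start, then reference id.
    """
    params = params or SearchParams()
    if index is None:
        index = build_index(db, params.kmer_size)
    elif index.k != params.kmer_size:
        raise ValueError(
            f"index k={index.k} does not match params.kmer_size={params.kmer_size}"
        )
    if isinstance(queries, Mapping):
        query_items = list(queries.items())
    else:
        query_items = list(queries)
    aligner = _make_aligner(params)
    score_floor = _score_floor(params)
    all_hits: list[AlignmentHit] = []
    for query_id, seq in query_items:
        seq = seq.upper()
        strands: dict[str, tuple[str, set[str]]] = {
            "+": (seq, index.candidates(seq, params.min_seed_count))
        }
        if params.search_both_strands:
            rc = reverse_complement(seq)
            strands["-"] = (rc, index.candidates(rc, params.min_seed_count))
        per_ref: dict[str, AlignmentHit] = {}
        for strand, (strand_seq, candidates) in strands.items():
            for ref_id in sorted(candidates):
                # score-only prescreen: cannot discard any passing hit
                if aligner.score(strand_seq, db[ref_id].sequence) < score_floor:
                    continue
                hit = _align_one_strand(
                    strand_seq, db[ref_id].sequence, params, aligner,
                    query_id, ref_id, strand,
                )
                if hit is None or not _passes(hit, params):
                    continue
                prev = per_ref.get(ref_id)
                if prev is None or _hit_order(hit) < _hit_order(prev):
                    per_ref[ref_id] = hit
        query_hits = sorted(per_ref.values(), key=_hit_order)
        if params.max_hits_per_query is not None:
            query_hits = query_hits[: params.max_hits_per_query]
        all_hits.extend(query_hits)
    return all_hits


# -- BLAST tabular interchange ----------------------------------------------

_N_COLUMNS = 12


def import_tabular_hits(path, params: SearchParams | None = None) -> list[AlignmentHit]:
    """Parse 12-column BLAST ``-outfmt 6`` hits, applying the search filters.

    Column order: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore.  Reverse-strand hits are recognized
    by descending subject coordinates, which are normalized to ascending.
    Rows failing ``min_aligned_length``/``min_percent_identity`` (or
    ``max_evalue`` when set) are dropped.
    """
    params = params or SearchParams()
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _N_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_N_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            (qseqid, sseqid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            sstart_i, send_i = int(sstart), int(send)
            strand = "+" if sstart_i <= send_i else "-"
            if strand == "-":
                sstart_i, send_i = send_i, sstart_i
            hit = AlignmentHit(
                query_id=qseqid,
                reference_id=sseqid,
                percent_identity=float(pident),
                aligned_length=int(length),
                mismatches=int(mismatch),
                gap_openings=int(gapopen),
                query_start=int(qstart),
                query_end=int(qend),
                ref_start=sstart_i,
                ref_end=send_i,
                strand=strand,
                score=int(round(float(bitscore))),
            )
            if not _passes(hit, params):
                continue
            if params.max_evalue is not None and float(evalue) > params.max_evalue:
                continue
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits as 12-column BLAST ``-outfmt 6`` TSV.

    The internal aligner computes no E-value, so that column is written
    as 0.0 and the raw alignment score fills the bitscore column.
    """
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = h.ref_start, h.ref_end
            if h.strand == "-":
                sstart, send = send, sstart
            fh.write(
                f"{h.query_id}\t{h.reference_id}\t{h.percent_identity:.2f}\t"
                f"{h.aligned_length}\t{h.mismatches}\t{h.gap_openings}\t"
                f"{h.query_start}\t{h.query_end}\t{sstart}\t{send}\t"
                f"0.0\t{h.score}\n"
            )
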