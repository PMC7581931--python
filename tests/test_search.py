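from __future__ import annotations

import numpy as np
import pytest

from habscore import (
    LabeledReference,
    ReferenceDatabase,
    SearchParams,
    align_pair,
    build_index,
    import_tabular_hits,
    search_queries,
    write_tabular_hits,
)
from habscore.search import reverse_complement

from conftest import mutate, random_seq
from oracles import smith_waterman_score


class TestKmerIndex:
    def _db(self, seqs):
        return ReferenceDatabase(
            LabeledReference(f"r{i}", s, "soil", "p")
            for i, s in enumerate(seqs)
        )

    def test_posting_count_is_length_minus_k_plus_one(self):
        index = build_index(self._db(["ACGTACGTACGTACGT"]), kmer_size=12)
        assert sum(len(v) for v in index.postings.values()) == 5

    def test_kmers_containing_n_are_excluded(self):
        seq = "ACGTN" * 10  # every 12-window contains an N
        index = build_index(self._db([seq]), kmer_size=12)
        assert sum(len(v) for v in index.postings.values()) == 0

    def test_identical_references_double_every_posting(self):
        seq = "ACGTAACCGGTTACGT"
        index = build_index(self._db([seq, seq]), kmer_size=12)
        assert all(len(v) == 2 for v in index.postings.values())

    def test_kmer_size_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_index(self._db(["ACGT" * 10]), kmer_size=7)


class TestAlignPair:
    def test_identical_sequences_align_end_to_end(self, rng):
        seq = random_seq(rng, 200)
        hit = align_pair(seq, seq)
        assert hit.percent_identity == 100.0
        assert hit.aligned_length == 200
        assert (hit.query_start, hit.query_end) == (1, 200)
        assert (hit.ref_start, hit.ref_end) == (1, 200)
        assert hit.strand == "+"
        assert hit.score == 200

    def test_single_mismatch_identity(self, rng):
        ref = random_seq(rng, 150)
        query = ref[:75] + ("A" if ref[75] != "A" else "C") + ref[76:]
        hit = align_pair(query, ref, SearchParams(min_percent_identity=90.0))
        assert hit.aligned_length == 150
        assert hit.percent_identity == pytest.approx(100 * 149 / 150)
        assert hit.mismatches == 1

    def test_below_length_threshold_returns_none(self, rng):
        seq = random_seq(rng, 100)
        assert align_pair(seq, seq, SearchParams(min_aligned_length=150)) is None

    def test_n_bases_never_count_as_matches(self):
        seq = "ACGTACGTACGTACGTACGT"
        query = seq[:10] + "N" + seq[11:]
        hit = align_pair(query, seq,
                         SearchParams(min_aligned_length=12,
                                      min_percent_identity=50.0))
        assert hit.percent_identity < 100.0

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_matches_smith_waterman_oracle_on_random_pairs(
        self, rng, permissive_params
    ):
        """Seeded on 200 random <=60-nt pairs, the best reported score and
        the score implied by the reported alignment statistics both equal
        an independent full-matrix Smith-Waterman."""
        p = permissive_params
        for _ in range(200):
            la = int(rng.integers(10, 61))
            lb = int(rng.integers(10, 61))
            a, b = random_seq(rng, la), random_seq(rng, lb)
            expected = smith_waterman_score(
                a, b, p.match, p.mismatch, p.gap_open, p.gap_extend
            )
            hit = align_pair(
                a, b,
                SearchParams(min_aligned_length=p.kmer_size,
                             min_percent_identity=p.min_percent_identity,
                             kmer_size=p.kmer_size,
                             search_both_strands=False),
                apply_thresholds=False,
            )
            got = 0 if hit is None else hit.score
            assert got == expected
            if hit is not None:
                # the reported stats must reproduce the reported score
                gap_cols = hit.aligned_length - hit.mismatches - hit.matches
                rebuilt = (
                    p.match * hit.matches
                    + p.mismatch * hit.mismatches
                    + p.gap_open * hit.gap_openings
                    + p.gap_extend * gap_cols
                )
                assert rebuilt == hit.score


class TestSearchQueries:
    @pytest.fixture
    def db_and_params(self, rng):
        refs = [
            LabeledReference(f"ref{i}", random_seq(rng, 300), "soil", "p")
            for i in range(4)
        ]
        db = ReferenceDatabase(refs)
        params = SearchParams(min_aligned_length=150,
                              min_percent_identity=97.0)
        return db, params

    def test_exact_query_hits_only_its_source(self, db_and_params):
        db, params = db_and_params
        hits = search_queries({"q": db["ref2"].sequence}, db, params)
        assert [h.reference_id for h in hits] == ["ref2"]
        assert hits[0].percent_identity == 100.0
        assert hits[0].strand == "+"

    def test_reverse_complement_query_found_on_minus_strand(self, db_and_params):
        db, params = db_and_params
        rc = reverse_complement(db["ref1"].sequence)
        hits = search_queries({"q": rc}, db, params)
        assert [(h.reference_id, h.strand) for h in hits] == [("ref1", "-")]
        assert hits[0].query_start == 1 and hits[0].query_end == 300

    def test_minus_strand_disabled_misses_reverse_complement(self, db_and_params):
        db, params = db_and_params
        rc = reverse_complement(db["ref1"].sequence)
        params = SearchParams(search_both_strands=False)
        assert search_queries({"q": rc}, db, params) == []

    def test_short_query_filtered_regardless_of_identity(self, db_and_params):
        db, params = db_and_params
        assert search_queries({"q": db["ref0"].sequence[:100]}, db, params) == []

    def test_every_reference_hits_itself_at_full_identity(self, db_and_params):
        db, params = db_and_params
        queries = {r.sequence_id: r.sequence for r in db}
        hits = search_queries(queries, db, params)
        self_hits = {h.query_id for h in hits
                     if h.reference_id == h.query_id
                     and h.percent_identity == 100.0}
        assert self_hits == set(queries)

    def test_raising_thresholds_never_adds_hits(self, rng):
        refs = [
            LabeledReference(f"ref{i}", random_seq(rng, 250), "soil", "p")
            for i in range(3)
        ]
        db = ReferenceDatabase(refs)
        queries = {
            f"q{i}": mutate(rng, refs[i % 3].sequence, 0.02)[: int(rng.integers(160, 250))]
            for i in range(5)
        }
        base = SearchParams(min_aligned_length=150, min_percent_identity=90.0)
        base_hits = {(h.query_id, h.reference_id)
                     for h in search_queries(queries, db, base)}
        for stricter in (
            SearchParams(min_aligned_length=200, min_percent_identity=90.0),
            SearchParams(min_aligned_length=150, min_percent_identity=97.0),
        ):
            strict_hits = {(h.query_id, h.reference_id)
                           for h in search_queries(queries, db, stricter)}
            assert strict_hits <= base_hits

    def test_strand_symmetry_of_hit_pairs(self, rng):
        refs = [
            LabeledReference(f"ref{i}", random_seq(rng, 250), "soil", "p")
            for i in range(3)
        ]
        db = ReferenceDatabase(refs)
        queries = {f"q{i}": mutate(rng, refs[i].sequence, 0.01)
                   for i in range(3)}
        params = SearchParams(min_percent_identity=95.0)
        fwd = search_queries(queries, db, params)
        rev = search_queries(
            {q: reverse_complement(s) for q, s in queries.items()}, db, params
        )
        assert {(h.query_id, h.reference_id) for h in fwd} == {
            (h.query_id, h.reference_id) for h in rev
        }
        flipped = {(h.query_id, h.reference_id): h.strand for h in rev}
        for h in fwd:
            assert flipped[(h.query_id, h.reference_id)] != h.strand

    def test_max_hits_per_query_truncates_by_score(self, rng):
        seq = random_seq(rng, 200)
        refs = [LabeledReference(f"ref{i}", mutate(rng, seq, 0.01 * i),
                                 "soil", "p") for i in range(4)]
        db = ReferenceDatabase(refs)
        params = SearchParams(min_percent_identity=80.0, max_hits_per_query=2)
        hits = search_queries({"q": seq}, db, params)
        assert len(hits) == 2
        assert hits[0].score >= hits[1].score


class TestTabularInterchange:
    ROW = "q1\tr1\t98.50\t{length}\t3\t0\t1\t{qend}\t{sstart}\t{send}\t1e-50\t180\n"

    def test_row_below_length_threshold_dropped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            self.ROW.format(length=149, qend=149, sstart=1, send=149)
        )
        assert import_tabular_hits(path, SearchParams()) == []

    def test_descending_subject_coordinates_mean_minus_strand(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            self.ROW.format(length=200, qend=200, sstart=220, send=21)
        )
        (hit,) = import_tabular_hits(path, SearchParams())
        assert hit.strand == "-"
        assert (hit.ref_start, hit.ref_end) == (21, 220)

    def test_valid_rows_pass_through(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "".join(
                f"q{i}\tr{i}\t99.00\t200\t2\t0\t1\t200\t1\t200\t0.0\t190\n"
                for i in range(10)
            )
        )
        assert len(import_tabular_hits(path, SearchParams())) == 10

    def test_wrong_column_count_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tr1\t99.00\t200\t2\t0\t1\t200\t1\t200\t0.0\t190\n"
            "q2\tr2\t99.00\t200\n"
        )
        with pytest.raises(ValueError, match=":2"):
            import_tabular_hits(path, SearchParams())

    def test_evalue_filter_applies_only_on_import(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            self.ROW.format(length=200, qend=200, sstart=1, send=200)
        )
        params = SearchParams(max_evalue=1e-60)
        assert import_tabular_hits(path, params) == []

    def test_export_import_round_trip(self, rng, tmp_path):
        ref = random_seq(rng, 250)
        db = ReferenceDatabase([LabeledReference("r1", ref, "soil", "p")])
        hits = search_queries(
            {"q": reverse_complement(mutate(rng, ref, 0.01))}, db,
            SearchParams(min_percent_identity=95.0),
        )
        assert hits
        path = tmp_path / "hits.tsv"
        write_tabular_hits(hits, path)
        rehydrated = import_tabular_hits(
            path, SearchParams(min_percent_identity=95.0)
        )
        assert len(rehydrated) == len(hits)
        for a, b in zip(hits, rehydrated):
            assert (a.query_id, a.reference_id, a.strand) == (
                b.query_id, b.reference_id, b.strand
            )
            assert a.aligned_length == b.aligned_length
            assert a.percent_identity == pytest.approx(
                b.percent_identity, abs=0.01
            )
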