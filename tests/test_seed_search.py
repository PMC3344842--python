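import pytest
from hypothesis import given, settings, strategies as st

from ghostseek.db_index import DELIMITER, ParamError, SearchParams, build_chunks
from ghostseek.oracle_fixtures import SyntheticSpec, generate_db, generate_reads
from ghostseek.seed_search import (
    Candidate,
    count_candidates,
    find_candidates,
    group_matches,
    query_keys,
)
from ghostseek.seq_io import ProteinRecord
from ghostseek.translate import TranslatedFrame, six_frame_translate

from naive_align import enumerate_kmers


def frame_of(residues, frame=1, read_id="q"):
    return TranslatedFrame(read_id=read_id, frame=frame, residues=residues, dna_length=3 * len(residues))


class TestQueryKeys:
    def test_skip_two(self):
        keys = query_keys(frame_of("A" * 25), 4, 2)
        assert len(keys) == 11
        assert [q for q, _ in keys] == list(range(0, 21, 2))

    def test_skip_one(self):
        assert len(query_keys(frame_of("A" * 25), 4, 1)) == 22

    def test_x_keys_omitted(self):
        assert query_keys(frame_of("MXKL"), 4, 1) == []

    def test_stop_keys_omitted(self):
        assert query_keys(frame_of("MK*LVAAA"), 4, 1) == [(3, "LVAA"), (4, "VAAA")]

    def test_short_frame_empty(self):
        assert query_keys(frame_of("MK"), 4, 1) == []


class TestGroupMatches:
    def test_same_bucket(self):
        # d=0 and d=3 both in region 0 with r=4 -> one candidate, support 2,
        # anchored at the region-pair boundary
        assert group_matches([0, 3], 4, 2) == [(4, 2)]

    def test_adjacent_buckets(self):
        # d=3 (region 0) and d=5 (region 1) -> the adjacent-region rule fires once
        assert group_matches([3, 5], 4, 2) == [(4, 2)]

    def test_far_apart_not_combined(self):
        assert group_matches([0, 100], 4, 2) == []

    def test_threshold_is_inclusive(self):
        # exactly t matches qualify (>= t, not > t)
        assert group_matches([0, 1], 4, 2) == [(4, 2)]

    def test_two_separate_candidates(self):
        out = group_matches([0, 1, 100, 101], 4, 2)
        assert out == [(4, 2), (104, 2)]

    def test_three_region_chain(self):
        # matches in three consecutive regions: overlapping pairs are emitted,
        # fully-contained flanking pairs are suppressed
        out = group_matches([0, 5, 9], 4, 1)
        assert out == [(4, 2), (8, 2)]

    def test_negative_starts(self):
        assert group_matches([-3, -1], 4, 2) == [(0, 2)]

    def test_each_candidate_window_covers_its_matches(self):
        # provable coverage: every match of an emitted pair lies within
        # [anchor - r, anchor + r) in start space
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(200):
            ds = sorted(rng.integers(-5, 60, size=rng.integers(1, 10)))
            r = int(rng.integers(1, 8))
            t = int(rng.integers(1, 4))
            for anchor, support in group_matches(ds, r, t):
                covered = [d for d in ds if anchor - r <= d < anchor + r]
                assert support == len(covered)
                assert support >= t

    def test_every_match_covered_at_t1(self):
        # completeness: with t=1 every match lies in some emitted pair
        import numpy as np

        rng = np.random.default_rng(1)
        for _ in range(200):
            ds = sorted(rng.integers(-10, 80, size=rng.integers(1, 12)))
            r = int(rng.integers(1, 8))
            pairs = group_matches(ds, r, 1)
            for d in ds:
                assert any(a - r <= d < a + r for a, _ in pairs), (ds, r, pairs)

    def test_bad_r(self):
        with pytest.raises(ParamError):
            group_matches([0], 0, 1)


class TestFindCandidates:
    def test_identical_sequence_single_candidate(self):
        seq = "MKWVLDEAFRTYHG"
        db = [ProteinRecord("a", seq)]
        [chunk] = build_chunks(db, SearchParams())
        keys = query_keys(frame_of(seq), 4, 1)
        cands = find_candidates(keys, chunk, r=4, t=1, frame=1)
        assert len(cands) == 1
        c = cands[0]
        assert c.db_seq_id == "a"
        # all matches predict start 0 (region 0); anchor is the pair boundary
        assert c.align_start == 4
        assert c.support == len(keys)

    def test_candidate_offset_sequence(self):
        db = [ProteinRecord("a", "WWWWW" + "MKWVLDEAFRTYHG")]
        [chunk] = build_chunks(db, SearchParams())
        keys = query_keys(frame_of("MKWVLDEAFRTYHG"), 4, 1)
        cands = find_candidates(keys, chunk, r=4, t=2, frame=1)
        assert len(cands) == 1
        # all matches predict start 5 (region 1); anchor is boundary 2*r = 8
        assert cands[0].align_start == 8

    def test_r_error(self, toy_chunks):
        with pytest.raises(ParamError):
            find_candidates([], toy_chunks[0], r=0, t=1)

    def test_no_support_across_delimiter(self, toy_chunks):
        # bucketing is per sequence: matches on different sequences never combine
        db = [ProteinRecord("a", "AAAMKWV"), ProteinRecord("b", "LDEAAAA")]
        [chunk] = build_chunks(db, SearchParams())
        keys = [(0, "MKWV"), (4, "LDEA")]
        # one match on each sequence; t=2 can never fire
        assert find_candidates(keys, chunk, r=100, t=2) == []

    def test_chunking_invariance_of_candidates(self, toy_db):
        """Sequence-relative bucketing makes candidates independent of packing."""
        spec = SyntheticSpec(n_db_seqs=10, n_reads=6, target_identity=0.8, seed=9)
        reads, _ = generate_reads(toy_db, spec)
        p1 = SearchParams()
        p2 = SearchParams(chunk_limit=300)
        one = build_chunks(toy_db, p1)
        many = build_chunks(toy_db, p2)
        assert len(many) > 1
        for read in reads:
            for fr in six_frame_translate(read, lenient=True):
                keys = query_keys(fr, 4, 2)
                a = [
                    (c.db_seq_id, _rel_start(c, one), c.support)
                    for ch in one
                    for c in find_candidates(keys, ch, 4, 2, fr.frame)
                ]
                b = [
                    (c.db_seq_id, _rel_start(c, many), c.support)
                    for ch in many
                    for c in find_candidates(keys, ch, 4, 2, fr.frame)
                ]
                assert sorted(a) == sorted(b)


def _rel_start(cand, chunks):
    for ch in chunks:
        if ch.chunk_id == cand.chunk_id:
            try:
                start, _ = ch.bounds(cand.db_seq_id)
            except KeyError:
                continue
            return cand.align_start - start
    raise AssertionError("candidate chunk not found")


@pytest.fixture(scope="module")
def fixture():
    spec = SyntheticSpec(n_db_seqs=30, n_reads=15, target_identity=(0.6, 0.9), seed=5)
    db = generate_db(spec)
    reads, _ = generate_reads(db, spec)
    return db, reads


class TestMonotonicity:
    @staticmethod
    def _candidates(db, reads, **kw):
        params = SearchParams(**kw)
        chunks = build_chunks(db, params)
        out = {}
        for read in reads:
            for fr in six_frame_translate(read, lenient=True):
                keys = query_keys(fr, params.k, params.s)
                cands = []
                for ch in chunks:
                    cands.extend(find_candidates(keys, ch, params.r, params.t, fr.frame))
                out[(read.id, fr.frame)] = cands
        return out

    @staticmethod
    def _assert_covered(strict, loose, r=4):
        """Every strict candidate has a loose candidate on the same subject
        within one region width (dedup may shift the anchor to an adjacent
        region pair)."""
        for key, cands in strict.items():
            for c in cands:
                assert any(
                    l.db_seq_id == c.db_seq_id and abs(l.align_start - c.align_start) <= r
                    for l in loose[key]
                ), (key, c)

    def test_t_monotone(self, fixture):
        db, reads = fixture
        by_t = {t: self._candidates(db, reads, t=t, s=1) for t in (1, 2, 3)}
        self._assert_covered(by_t[3], by_t[2])
        self._assert_covered(by_t[2], by_t[1])

    def test_s_monotone(self, fixture):
        db, reads = fixture
        by_s = {s: self._candidates(db, reads, s=s, t=1) for s in (1, 2, 4)}
        self._assert_covered(by_s[4], by_s[2])
        self._assert_covered(by_s[2], by_s[1])

    def test_k_monotone(self, fixture):
        db, reads = fixture
        by_k = {k: self._candidates(db, reads, k=k, t=1, s=1) for k in (3, 4)}
        # a k=4 exact match implies a k=3 match at the same start
        self._assert_covered(by_k[4], by_k[3])


class TestCountCandidates:
    def test_no_matches(self, toy_chunks, default_params):
        from ghostseek.seq_io import DnaRead

        reads = [DnaRead("r", "ACGACGACGACG")]
        counts = count_candidates(reads, toy_chunks, default_params)
        assert set(counts) == {("r", f) for f in (1, 2, 3, -1, -2, -3)}

    def test_consistency_with_find_candidates(self, toy_db, toy_chunks, default_params):
        spec = SyntheticSpec(n_db_seqs=10, n_reads=4, target_identity=1.0, indel_rate=0.0, seed=11)
        reads, _ = generate_reads(toy_db, spec)
        counts = count_candidates(reads, toy_chunks, default_params)
        for read in reads:
            for fr in six_frame_translate(read, lenient=True):
                expected = sum(
                    len(
                        find_candidates(
                            query_keys(fr, default_params.k, default_params.s),
                            ch,
                            default_params.r,
                            default_params.t,
                            fr.frame,
                        )
                    )
                    for ch in toy_chunks
                )
                assert counts[(read.id, fr.frame)] == expected

    def test_brute_force_recount(self, default_params):
        """Independent recount: enumerate every exact k-mer match by scanning,
        bucket by hand, and compare."""
        spec = SyntheticSpec(n_db_seqs=8, db_len_range=(40, 80), n_reads=5,
                             target_identity=0.85, seed=21)
        db = generate_db(spec)
        reads, _ = generate_reads(db, spec)
        chunks = build_chunks(db, default_params)
        counts = count_candidates(reads, chunks, default_params)
        k, s, r, t = 4, 2, 4, 2
        for read in reads:
            for fr in six_frame_translate(read, lenient=True):
                n = 0
                for rec in db:
                    starts = []
                    for q in range(0, len(fr.residues) - k + 1, s):
                        key = fr.residues[q : q + k]
                        if "X" in key or "*" in key:
                            continue
                        for off, kmer in enumerate_kmers(rec.residues, k):
                            if kmer == key:
                                starts.append(off - q)
                    n += len(group_matches(starts, r, t))
                assert counts[(read.id, fr.frame)] == n
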