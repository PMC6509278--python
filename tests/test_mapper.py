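"""Seed-and-extend mapper: index contracts, the dual-reference mechanism,
and exact agreement with a brute-force all-positions scorer."""

import numpy as np
import pytest

from numtshadow import build_index, build_indexes, map_all, map_read
from numtshadow.mapper import ReadAlignment
from numtshadow.sequencing import ReadSet, Provenance, sequence_reads
from numtshadow import Stoichiometry, mda_fragments
from numtshadow._util import encode, random_dna, revcomp
from conftest import make_numt, make_world


class TestBuildIndex:
    def test_position_count_linear_contig(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 1_000)
        idx = build_index({"chr1": seq}, k=15, mito_name=None)
        assert sum(len(v) for v in idx.table.values()) == 1_000 - 15 + 1

    def test_duplicate_kmer_both_positions(self):
        rng = np.random.default_rng(2)
        unit = random_dna(rng, 20)
        seq = unit + random_dna(rng, 100) + unit + random_dna(rng, 60)
        idx = build_index({"chr1": seq}, k=15, mito_name=None)
        assert len(idx.table[unit[:15]]) == 2

    def test_k_bounds(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 100)
        with pytest.raises(ValueError):
            build_index({"chr1": seq}, k=10, mito_name=None)
        with pytest.raises(ValueError):
            build_index({"chr1": seq}, k=32, mito_name=None)

    def test_contig_shorter_than_k(self):
        with pytest.raises(ValueError):
            build_index({"chr1": "ACGTACGT"}, k=15, mito_name=None)

    def test_mito_wrap_extension(self, mito2k):
        idx = build_index({"mito": mito2k.sequence}, k=15, wrap=100)
        assert idx.mito_length == 2_000
        assert len(idx.arrays["mito"]) == 2_100


class TestMapRead:
    def test_error_free_read_maps_exactly(self, mito16k):
        idx = build_index({"mito": mito16k.sequence}, k=15)
        read = mito16k.sequence[7_000:7_150]
        aln = map_read("r1", read, idx)
        assert (aln.status, aln.contig, aln.position, aln.strand, aln.mismatches) == (
            "mapped", "mito", 7_000, "+", 0)
        assert aln.score == 150

    def test_reverse_strand_read(self, mito16k):
        idx = build_index({"mito": mito16k.sequence}, k=15)
        aln = map_read("r1", revcomp(mito16k.sequence[7_000:7_150]), idx)
        assert (aln.status, aln.position, aln.strand) == ("mapped", 7_000, "-")

    def test_origin_spanning_read_uses_circular_coordinates(self, mito16k):
        L = mito16k.length
        idx = build_index({"mito": mito16k.sequence}, k=15, wrap=300)
        read = mito16k.sequence[L - 50 :] + mito16k.sequence[:100]
        aln = map_read("r1", read, idx)
        assert (aln.status, aln.position) == ("mapped", L - 50)

    def test_junk_read_unmapped(self, mito16k):
        rng = np.random.default_rng(4)
        idx = build_index({"mito": mito16k.sequence}, k=15)
        aln = map_read("r1", random_dna(rng, 150), idx)
        assert aln.status == "unmapped"

    def test_exact_repeat_is_ambiguous(self):
        rng = np.random.default_rng(5)
        unit = random_dna(rng, 200)
        seq = random_dna(rng, 300) + unit + random_dna(rng, 300) + unit + random_dna(rng, 300)
        idx = build_index({"chr1": seq}, k=15, mito_name=None)
        aln = map_read("r1", unit[20:170], idx)
        assert aln.status == "ambiguous"

    def test_numt_read_rehomed_by_combined_reference(self, mito2k):
        """The central mechanism: a NUMT read passes the identity filter on
        the mito-only reference but maps to its nuclear origin when that
        origin is present."""
        w = make_world(mito2k)
        muts = {p: next(b for b in "ACGT" if b != mito2k.sequence[p])
                for p in range(720, 860, 20)}  # 7 mismatches in [700, 850)
        make_numt(w, mito_start=500, length=800, mutations=muts, numt_id="n7")
        mito_idx, comb_idx = build_indexes(w, k=15, wrap=300)
        numt_seq = w.numt_mito_sequence(w.numts[0])
        read = numt_seq[200:350]  # mito [700, 850): carries all 7 mismatches
        aln_r = map_read("r1", read, mito_idx, accept_min_identity=0.90)
        assert (aln_r.status, aln_r.contig, aln_r.position) == ("mapped", "mito", 700)
        assert aln_r.mismatches == 7  # identity 143/150 = 95.3%
        aln_c = map_read("r1", read, comb_idx, accept_min_identity=0.90)
        assert (aln_c.status, aln_c.contig, aln_c.mismatches) == ("mapped", "nuc_n7", 0)

    def test_low_identity_numt_read_unmapped_on_mito(self, mito2k):
        w = make_world(mito2k)
        muts = {p: next(b for b in "ACGT" if b != mito2k.sequence[p])
                for p in range(705, 850, 5)}  # 29 mismatches: identity ~81%
        make_numt(w, mito_start=500, length=800, mutations=muts, numt_id="nlow")
        mito_idx, comb_idx = build_indexes(w, k=15, wrap=300)
        read = w.numt_mito_sequence(w.numts[0])[200:350]
        assert map_read("r1", read, mito_idx).status == "unmapped"
        aln_c = map_read("r1", read, comb_idx)
        assert (aln_c.status, aln_c.contig) == ("mapped", "nuc_nlow")


def brute_force_map(read_id, sequence, contigs, accept_min_identity=0.88):
    """Independent oracle: score every position on every strand of every
    linear contig and apply the same acceptance rules as the mapper."""
    n = len(sequence)
    best = []
    best_mism = n + 1
    for name, seq in contigs.items():
        arr = encode(seq)
        if len(arr) < n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, n)
        for strand, q in (("+", sequence), ("-", revcomp(sequence))):
            mism = (windows != encode(q)).sum(axis=1)
            m = int(mism.min())
            if m < best_mism:
                best_mism = m
                best = [(name, int(p), strand) for p in np.nonzero(mism == m)[0]]
            elif m == best_mism:
                best += [(name, int(p), strand) for p in np.nonzero(mism == m)[0]]
    if not best or (n - best_mism) / n < accept_min_identity:
        return ReadAlignment(read_id, "", "unmapped")
    if len(best) > 1:
        return ReadAlignment(read_id, "", "ambiguous")
    name, pos, strand = best[0]
    return ReadAlignment(read_id, "", "mapped", contig=name, position=pos,
                         strand=strand, score=(n - best_mism) - best_mism,
                         mismatches=best_mism)


class TestOracleEquivalence:
    def test_matches_brute_force_on_short_reads(self):
        """1,000 random 60 bp reads over a 2 kb reference: status, position,
        strand and score agree with the all-positions scorer."""
        rng = np.random.default_rng(99)
        ref = random_dna(rng, 2_000)
        contigs = {"chr1": ref}
        idx = build_index(contigs, k=15, mito_name=None)
        n_mapped = n_unmapped = 0
        for i in range(1_000):
            kind = rng.random()
            if kind < 0.85:  # genuine read with 0-3 substitutions
                start = int(rng.integers(0, 2_000 - 60))
                read = list(ref[start : start + 60])
                for p in rng.choice(60, size=int(rng.integers(0, 4)), replace=False):
                    read[p] = "ACGT"[(("ACGT".index(read[p])) + int(rng.integers(1, 4))) % 4]
                read = "".join(read)
                if rng.random() < 0.5:
                    read = revcomp(read)
            else:  # junk
                read = random_dna(rng, 60)
            got = map_read(f"r{i}", read, idx)
            want = brute_force_map(f"r{i}", read, contigs)
            assert got.status == want.status, read
            if want.status == "mapped":
                n_mapped += 1
                assert (got.contig, got.position, got.strand, got.score) == (
                    want.contig, want.position, want.strand, want.score)
            else:
                n_unmapped += 1
        assert n_mapped > 700 and n_unmapped > 50


class TestMapAll:
    def _reads(self, world, n=2_000, seed=0, error_rate=0.002):
        pool = mda_fragments(world, Stoichiometry(50, 2, 10, 0.0), 500, 100, 4_000, seed=seed)
        return sequence_reads(pool, 100, n, error_rate, seed=seed + 1)

    def test_zero_numt_world_modes_identical(self, mito2k):
        w = make_world(mito2k)
        rs = self._reads(w)
        aln_r, aln_c, stats = map_all(rs, *build_indexes(w, k=15, wrap=300))
        for a, b in zip(aln_r, aln_c):
            assert (a.status, a.contig, a.position, a.strand, a.mismatches) == (
                b.status, b.contig, b.position, b.strand, b.mismatches)
        assert stats["rcrs_only"]["mito_mapped"] == stats["combined"]["mito_mapped"]

    def test_monotone_competition(self, mito2k):
        """Adding nuclear contigs to the reference can only remove or re-home
        reads: combined-mode mito reads are a subset of mito-only-mode ones."""
        for seed in range(3):
            w = make_world(mito2k, n_numts=4, size_range=(100, 800), seed=seed)
            rs = self._reads(w, seed=seed)
            aln_r, aln_c, _ = map_all(rs, *build_indexes(w, k=15, wrap=300))
            mito_r = {a.read_id for a in aln_r if a.status == "mapped" and a.contig == "mito"}
            mito_c = {a.read_id for a in aln_c if a.status == "mapped" and a.contig == "mito"}
            assert mito_c <= mito_r
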