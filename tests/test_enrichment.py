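"""Amplicon panel design, NUMT co-amplification and MDA fragmentation."""

import numpy as np
import pytest

from numtshadow import (
    Stoichiometry,
    amplify,
    design_amplicon_panel,
    generate_mito_reference,
    generate_numts,
    mda_fragments,
    numt_coamplified,
)
from numtshadow.enrichment import read_panel, read_pool, write_panel, write_pool
from numtshadow._util import arc_contains
from conftest import make_numt, make_world


class TestPanelDesign:
    def test_two_amplicon_lrpcr(self, mito16k):
        panel = design_amplicon_panel(mito16k, 2, primer_length=25, min_overlap=100)
        lengths = [b - a for a, b in panel.amplicons]
        assert len(lengths) == 2
        assert all(abs(l - (16_569 / 2 + 100)) <= 1 for l in lengths)

    def test_180_amplicon_panel(self, mito16k):
        panel = design_amplicon_panel(mito16k, 180, primer_length=20, min_overlap=30)
        lengths = [b - a for a, b in panel.amplicons]
        assert len(lengths) == 180
        assert all(abs(l - (16_569 / 180 + 30)) <= 1 for l in lengths)
        assert all(100 <= l <= 2_000 for l in lengths)  # short-amplicon regime

    def test_circular_coverage(self, mito16k):
        panel = design_amplicon_panel(mito16k, 9, primer_length=25, min_overlap=50)
        covered = np.zeros(mito16k.length, dtype=bool)
        for a, b in panel.amplicons:
            idx = np.arange(a, b) % mito16k.length
            covered[idx] = True
        assert covered.all()
        # adjacent overlap at least min_overlap
        for i, (a, b) in enumerate(panel.amplicons):
            nxt_a = panel.amplicons[(i + 1) % 9][0]
            if i + 1 == 9:
                nxt_a += mito16k.length
            assert b - nxt_a >= 50

    def test_infeasible_tiling_rejected(self):
        mito = generate_mito_reference(1_000, seed=1)
        with pytest.raises(ValueError):
            design_amplicon_panel(mito, 2_000, primer_length=20, min_overlap=10)


class TestCoamplification:
    def test_containment_with_clean_footprints(self, mito2k):
        w = make_world(mito2k)
        numt = make_numt(w, mito_start=200, length=1_500, numt_id="n1")
        panel = design_amplicon_panel(mito2k, 4, primer_length=25, min_overlap=50)
        assert numt_coamplified(numt, (300, 500), panel, max_primer_mismatches=2)

    def test_amplicon_longer_than_numt_never_coamplified(self, mito16k):
        panel = design_amplicon_panel(mito16k, 2, primer_length=25, min_overlap=100)
        numts, _ = generate_numts(mito16k, 30, size_range=(100, 6_000), seed=2)
        for numt in numts:
            for amp in panel.amplicons:
                assert not numt_coamplified(numt, amp, panel)

    def test_primer_footprint_mismatches_block(self, mito2k):
        w = make_world(mito2k)
        # 5 mismatches inside the left primer footprint of amplicon (300, 500)
        muts = {p: next(b for b in "ACGT" if b != mito2k.sequence[p])
                for p in range(300, 305)}
        numt = make_numt(w, mito_start=200, length=1_500, mutations=muts, numt_id="n2")
        panel = design_amplicon_panel(mito2k, 4, primer_length=25, min_overlap=50)
        assert not numt_coamplified(numt, (300, 500), panel, max_primer_mismatches=2)
        assert numt_coamplified(numt, (300, 500), panel, max_primer_mismatches=5)

    def test_wrapping_numt_containment(self, mito2k):
        w = make_world(mito2k)
        numt = make_numt(w, mito_start=1_900, length=300, numt_id="nwrap")
        panel = design_amplicon_panel(mito2k, 4, primer_length=20, min_overlap=50)
        # amplicon fully inside the wrapped projection [1900, 2200)
        assert numt_coamplified(numt, (1_950, 2_150), panel)
        assert not numt_coamplified(numt, (1_800, 2_000), panel)


class TestAmplify:
    def test_heteroplasmy_weight_fractions_exact(self, mito16k, alt_of):
        """At jackpot 0, alt-haplotype weight fraction equals the true frequency."""
        w = make_world(mito16k, [(4_000, alt_of(mito16k, 4_000), 0.03)])
        panel = design_amplicon_panel(mito16k, 9, primer_length=25, min_overlap=50)
        pool = amplify(w, panel, Stoichiometry(198, 2, 100, 0.0), seed=1)
        checked = 0
        for a, b in panel.amplicons:
            if not arc_contains(a, b, 4_000, 4_001, 16_569):
                continue
            checked += 1
            mols = [m for m in pool.molecules if m.mito_interval == (a, b)]
            total = sum(m.weight for m in mols)
            alt = sum(m.weight for m in mols
                      if m.sequence[(4_000 - a) % 16_569] == alt_of(mito16k, 4_000))
            assert alt / total == pytest.approx(0.03)
        assert checked >= 1

    def test_numt_weight_fraction_closed_form(self, mito16k):
        """One clean co-amplified diploid NUMT at C=198 contributes 2/200 = 1%."""
        w = make_world(mito16k)
        panel = design_amplicon_panel(mito16k, 9, primer_length=25, min_overlap=50)
        a, b = panel.amplicons[2]
        make_numt(w, mito_start=a - 100, length=(b - a) + 300, numt_id="big")
        pool = amplify(w, panel, Stoichiometry(198, 2, 100, 0.0), seed=1)
        mols = [m for m in pool.molecules if m.mito_interval == (a, b)]
        assert {m.origin for m in mols} == {"mito", "big"}
        total = sum(m.weight for m in mols)
        numt_w = sum(m.weight for m in mols if m.origin == "big")
        assert numt_w / total == pytest.approx(2 / 200)
        numt_mol = next(m for m in mols if m.origin == "big")
        assert numt_mol.sequence == w.mito.segment(a, b)  # no mutations planted

    def test_lrpcr_pool_contains_no_numt_molecules(self, mito16k):
        w = make_world(mito16k, n_numts=40, seed=6)
        panel = design_amplicon_panel(mito16k, 2, primer_length=25, min_overlap=100)
        pool = amplify(w, panel, Stoichiometry(100, 2, 100, 0.0), seed=1)
        assert all(m.origin == "mito" for m in pool.molecules)

    def test_homoplasmic_site_supported(self, mito16k, alt_of):
        w = make_world(mito16k, [(4_000, alt_of(mito16k, 4_000), 1.0)])
        panel = design_amplicon_panel(mito16k, 9, primer_length=25, min_overlap=50)
        pool = amplify(w, panel, Stoichiometry(100, 2, 100, 0.0), seed=1)
        covering = [m for m in pool.molecules
                    if arc_contains(*m.mito_interval, 4_000, 4_001, 16_569)]
        assert covering
        for m in covering:
            a, _ = m.mito_interval
            assert m.sequence[(4_000 - a) % 16_569] == alt_of(mito16k, 4_000)


class TestMdaFragments:
    def test_numt_free_world_all_mito(self, mito2k):
        w = make_world(mito2k)
        pool = mda_fragments(w, Stoichiometry(100, 2, 10, 0.0), 500, 100, 2_000, seed=3)
        assert len(pool.molecules) == 2_000
        assert all(m.origin == "mito" for m in pool.molecules)

    def test_deterministic_per_seed(self, mito2k):
        w = make_world(mito2k, n_numts=2, size_range=(100, 500), seed=1)
        p1 = mda_fragments(w, Stoichiometry(100, 2, 10, 0.0), 500, 100, 500, seed=3)
        p2 = mda_fragments(w, Stoichiometry(100, 2, 10, 0.0), 500, 100, 500, seed=3)
        assert [(m.origin, m.sequence) for m in p1.molecules] == [
            (m.origin, m.sequence) for m in p2.molecules
        ]

    def test_copy_number_stoichiometry_closed_form(self, mito16k):
        """Fraction of fragments covering a mid-NUMT site that are NUMT-derived
        converges to 2k / (C + 2k) for k=1 diploid NUMT and C=100."""
        w = make_world(mito16k)
        numt = make_numt(w, mito_start=6_000, length=5_000, numt_id="n5k", flank=2_000)
        site = 8_500  # mid-projection
        C = 100
        n_numt = n_mito = 0
        for seed in range(10):
            pool = mda_fragments(w, Stoichiometry(C, 2, 10, 0.0),
                                 fragment_length_mean=2_000, fragment_length_sd=300,
                                 n_fragments=20_000, seed=seed)
            for m in pool.molecules:
                if m.origin == "mito":
                    a, b = m.mito_interval
                    if arc_contains(a, b, site, site + 1, 16_569):
                        n_mito += 1
                elif m.origin == "n5k":
                    a, b = m.mito_interval
                    if a <= site < b:
                        n_numt += 1
        frac = n_numt / (n_numt + n_mito)
        expected = 2 / (C + 2)
        se = np.sqrt(expected * (1 - expected) / (n_numt + n_mito))
        assert abs(frac - expected) < 3 * se

    def test_heteroplasmy_carried_by_frequency(self, mito2k, alt_of):
        alt = alt_of(mito2k, 1_000)
        w = make_world(mito2k, [(1_000, alt, 0.3)])
        pool = mda_fragments(w, Stoichiometry(100, 2, 10, 0.0), 500, 50, 20_000, seed=4)
        covering = alt_n = 0
        for m in pool.molecules:
            a, b = m.mito_interval
            if arc_contains(a, b, 1_000, 1_001, 2_000):
                covering += 1
                if m.sequence[(1_000 - a) % 2_000] == alt:
                    alt_n += 1
        se = np.sqrt(0.3 * 0.7 / covering)
        assert abs(alt_n / covering - 0.3) < 3 * se


class TestPoolSerialization:
    def test_panel_roundtrip(self, tmp_path, mito16k):
        panel = design_amplicon_panel(mito16k, 9, primer_length=25, min_overlap=50)
        write_panel(panel, tmp_path / "panel.tsv")
        assert read_panel(tmp_path / "panel.tsv") == panel

    def test_pool_roundtrip(self, tmp_path, mito2k, alt_of):
        w = make_world(mito2k, [(700, alt_of(mito2k, 700), 0.1)], n_numts=2,
                       size_range=(100, 400), seed=2)
        panel = design_amplicon_panel(mito2k, 4, primer_length=20, min_overlap=40)
        pool = amplify(w, panel, Stoichiometry(50, 2, 10, 0.0), seed=5)
        write_pool(pool, tmp_path / "pool.fasta", tmp_path / "pool.tsv")
        back = read_pool(tmp_path / "pool.fasta", tmp_path / "pool.tsv")
        assert [(m.molecule_id, m.origin, m.sequence, m.mito_interval, m.weight)
                for m in back.molecules] == [
            (m.molecule_id, m.origin, m.sequence, m.mito_interval, m.weight)
            for m in pool.molecules]
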