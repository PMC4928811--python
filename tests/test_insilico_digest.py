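import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_protein
from oracles import brute_force_digest
from phosphopipe.insilico_digest import (
    ENZYMES,
    DigestParams,
    coverage,
    digest,
    peptide_mass,
    site_embedded,
)
from phosphopipe.tables_io import ProteinRecord

OPEN = DigestParams(enzyme="trypsin_lysC", max_missed=0,
                    detect_len=(None, None), detect_mass=(None, None))


def params(enzyme="trypsin_lysC", **kw):
    kw.setdefault("detect_len", (None, None))
    kw.setdefault("detect_mass", (None, None))
    return DigestParams(enzyme=enzyme, **kw)


class TestDigest:
    def test_tryptic_cuts_after_k_and_r(self):
        peps = digest(ProteinRecord("P", "MAKRWDL"), params(max_missed=0))
        assert [p.sequence for p in peps] == ["MAK", "R", "WDL"]
        assert [(p.start, p.end) for p in peps] == [(0, 3), (3, 4), (4, 7)]

    def test_missed_cleavages_add_concatenations(self):
        peps = {p.sequence for p in digest(ProteinRecord("P", "MAKRWDL"), params(max_missed=1))}
        assert peps == {"MAK", "R", "WDL", "MAKR", "RWDL"}

    def test_uncleavable_protein_yields_itself(self):
        peps = digest(ProteinRecord("P", "WWWW"), params(max_missed=0))
        assert [p.sequence for p in peps] == ["WWWW"]

    def test_n_terminal_enzyme_cuts_before_residue(self):
        peps = digest(ProteinRecord("P", "GAVG"), params("thermolysin", max_missed=0))
        assert [p.sequence for p in peps] == ["G", "A", "VG"]

    def test_x_never_matches_cleavage(self):
        peps = digest(ProteinRecord("P", "AXAXA"), params(max_missed=0))
        assert [p.sequence for p in peps] == ["AXAXA"]

    def test_zero_missed_fragments_reconstruct_protein(self, rng):
        for _ in range(20):
            prot = random_protein(rng, int(rng.integers(5, 60)))
            for enzyme in ENZYMES:
                frags = [p for p in digest(prot, params(enzyme, max_missed=2)) if p.missed == 0]
                assert "".join(f.sequence for f in frags) == prot.sequence

    @pytest.mark.parametrize("enzyme", sorted(ENZYMES))
    def test_matches_brute_force_enumeration(self, rng, enzyme):
        residues, terminus = ENZYMES[enzyme]
        for _ in range(60):
            prot = random_protein(rng, int(rng.integers(1, 51)))
            max_missed = int(rng.integers(0, 3))
            got = {(p.sequence, p.start, p.end, p.missed)
                   for p in digest(prot, params(enzyme, max_missed=max_missed))}
            assert got == brute_force_digest(prot.sequence, set(residues),
                                             terminus, max_missed)


class TestMass:
    def test_known_masses(self):
        assert peptide_mass("G", 0) == pytest.approx(75.03203, abs=1e-4)
        assert peptide_mass("GS", 1) == pytest.approx(242.03038, abs=1e-4)

    def test_empty_and_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("", 0)
        with pytest.raises(ValueError):
            peptide_mass("GZ", 0)

    def test_phospho_shift_additive(self):
        assert peptide_mass("ASK", 2) - peptide_mass("ASK", 0) == pytest.approx(2 * 79.96633)


class TestCoverage:
    def test_fully_tiled_protein_is_one(self):
        frac, covered = coverage(ProteinRecord("P", "MAKRWDL"), OPEN)
        assert frac == 1.0 and all(covered)

    def test_impossible_length_window_is_zero(self):
        p = params(max_missed=0, detect_len=(100, 200))
        frac, covered = coverage(ProteinRecord("P", "MAKRWDL"), p)
        assert frac == 0.0 and not any(covered)

    def test_union_of_detectable_peptides(self):
        # KKAAKAAAAA: tryptic 0-missed fragments K|K|AAK|AAAAA; with a
        # 3..5-residue window only AAK [2,5) and AAAAA [5,10) pass -> 8/10
        p = params(max_missed=0, detect_len=(3, 5))
        frac, covered = coverage(ProteinRecord("P", "KKAAKAAAAA"), p)
        assert frac == pytest.approx(0.8)
        assert covered == [False, False] + [True] * 8

    def test_monotone_in_window_and_missed(self, rng):
        for _ in range(10):
            prot = random_protein(rng, 60)
            narrow = coverage(prot, params(max_missed=0, detect_len=(8, 12)))[0]
            wider = coverage(prot, params(max_missed=0, detect_len=(5, 20)))[0]
            more_missed = coverage(prot, params(max_missed=2, detect_len=(8, 12)))[0]
            assert narrow <= wider
            assert narrow <= more_missed

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
    def test_missed_peptides_concatenate_zero_missed_runs(self, seq):
        prot = ProteinRecord("P", seq)
        peps = digest(prot, params(max_missed=2))
        zero = [p for p in peps if p.missed == 0]
        for p in peps:
            inside = [z for z in zero if p.start <= z.start and z.end <= p.end]
            assert len(inside) == p.missed + 1
            assert "".join(z.sequence for z in inside) == p.sequence


class TestSiteEmbedded:
    def test_site_inside_detectable_peptide(self):
        p = params(max_missed=0, detect_len=(3, None))
        assert site_embedded(ProteinRecord("P", "MAKRWDL"), 3, p)  # in MAK

    def test_singleton_fragment_needs_missed_cleavage(self):
        prot = ProteinRecord("P", "MAKRWDL")
        p0 = params(max_missed=0, detect_len=(3, None))
        p1 = params(max_missed=1, detect_len=(3, None))
        assert not site_embedded(prot, 4, p0)  # R alone is too short
        assert site_embedded(prot, 4, p1)  # MAKR / RWDL contain it

    def test_unrestricted_ranges_embed_every_site(self):
        prot = ProteinRecord("P", "MAKRWDL")
        assert all(site_embedded(prot, i, OPEN) for i in range(1, 8))

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            site_embedded(ProteinRecord("P", "MAKR"), 9, OPEN)


class TestParams:
    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValueError):
            DigestParams(detect_len=(10, 5))

    def test_custom_enzyme_requires_residues(self):
        with pytest.raises(ValueError):
            DigestParams(enzyme="custom")
        p = DigestParams(enzyme="custom", cleavage_residues=frozenset("D"), terminus="N")
        assert p.cleavage_residues == frozenset("D")

    def test_thermolysin_terminus_overridable(self):
        # the C-terminal variant of the thermolysin rule
        p = DigestParams(enzyme="custom", cleavage_residues=frozenset("VAMILF"),
                         terminus="C", max_missed=0,
                         detect_len=(None, None), detect_mass=(None, None))
        peps = digest(ProteinRecord("P", "GAVG"), p)
        assert [x.sequence for x in peps] == ["GA", "V", "G"]
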