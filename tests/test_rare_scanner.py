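import pytest

from oracles import naive_direct_repeats, naive_half_sites
from phosphopipe.rare_scanner import (
    find_direct_repeats,
    find_half_sites,
    hits_to_frame,
    reverse_complement,
    scan_gene_regions,
)
from phosphopipe.synthetic_data import SynthConfig, generate_regions_with_drs
from phosphopipe.tables_io import GeneRegion


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestHalfSites:
    @pytest.mark.parametrize("seq,expected", [
        ("AGGTCA", [(0, "+")]),
        ("GGTTGA", [(0, "+")]),   # R=G, K=T, S=G
        ("TGACCT", [(0, "-")]),   # reverse complement of AGGTCA
        ("ACGTAC", []),
        ("AGGTNA", []),           # N never matches
    ])
    def test_pattern(self, seq, expected):
        assert [(h.pos, h.strand) for h in find_half_sites(seq)] == expected

    def test_overlapping_matches_all_reported(self):
        # AGGTCA at 0 (+) and TCAGCA..? build overlap: AGGTCAGCA has
        # forward hexamer at 0; GGTCAG no; check a palindromic-ish overlap
        seq = "AGGTCAACCA"
        assert (0, "+") in naive_half_sites(seq)
        got = {(h.pos, h.strand) for h in find_half_sites(seq)}
        assert got == naive_half_sites(seq)

    def test_lowercase_uppercased_unless_masked(self):
        assert len(find_half_sites("aggtca")) == 1
        assert find_half_sites("aggtca", respect_mask=True) == []

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            find_half_sites("AGGTCQ")

    def test_matches_naive_scanner(self, rng):
        for _ in range(30):
            seq = random_dna(rng, 300)
            got = {(h.pos, h.strand) for h in find_half_sites(seq)}
            assert got == naive_half_sites(seq)


class TestDirectRepeats:
    def test_dr0_abutting(self):
        (dr,) = find_direct_repeats("AGGTCAAGGTCA")
        assert (dr.first.pos, dr.second.pos, dr.spacing, dr.strand) == (0, 6, 0, "+")

    def test_dr2_with_spacer(self):
        (dr,) = find_direct_repeats("AGGTCA" + "CT" + "GGTTGA")
        assert (dr.spacing, dr.strand) == (2, "+")

    def test_minus_strand_dr0_ordered_5prime_first(self):
        (dr,) = find_direct_repeats("TGACCTTGACCT")
        assert dr.strand == "-" and dr.spacing == 0
        # 5'->3' on the minus strand runs right-to-left on the forward one
        assert dr.first.pos == 6 and dr.second.pos == 0

    def test_gap_above_max_spacing_not_reported(self):
        seq = "AGGTCA" + "N" * 11 + "AGGTCA"
        assert find_direct_repeats(seq, range(11)) == []

    def test_mixed_strand_pairs_never_reported(self):
        seq = "AGGTCA" + "CC" + "TGACCT"  # + then - half-site
        assert find_direct_repeats(seq) == []

    def test_matches_naive_scanner(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 400)
            got = {
                (min(d.first.pos, d.second.pos), max(d.first.pos, d.second.pos),
                 d.spacing, d.strand)
                for d in find_direct_repeats(seq, range(11))
            }
            assert got == naive_direct_repeats(seq, range(11))

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 500)
            fwd = find_direct_repeats(seq, range(11))
            rev = find_direct_repeats(reverse_complement(seq), range(11))
            def per_spacing(drs):
                counts = {}
                for d in drs:
                    counts[d.spacing] = counts.get(d.spacing, 0) + 1
                return counts
            assert per_spacing(fwd) == per_spacing(rev)
            # strand labels swap under reverse complement
            n_plus = sum(1 for d in fwd if d.strand == "+")
            n_minus_rev = sum(1 for d in rev if d.strand == "-")
            assert n_plus == n_minus_rev


class TestScanGeneRegions:
    def test_planted_repeats_recovered_exactly(self):
        cfg = SynthConfig(n_genes=11, region_length=2000,
                          planted_dr_counts={s: 1 for s in range(11)}, seed=3)
        seqs, regions, truth = generate_regions_with_drs(cfg)
        hits, summary, skipped = scan_gene_regions(seqs, regions, flank=2000)
        assert not skipped
        got = sorted((h.gene_id, h.repeat.start, h.repeat.spacing, h.repeat.strand)
                     for h in hits)
        expected = sorted((d["gene_id"], d["pos"], d["spacing"], d["strand"])
                          for d in truth.planted_drs)
        assert got == expected
        assert summary["n_repeats"].sum() == 11

    def test_empty_window_all_zero(self):
        seqs = {"chr1": "ACCA" * 300}
        regions = [GeneRegion("G1", "chr1", 100, 200)]
        hits, summary, _ = scan_gene_regions(seqs, regions, flank=100)
        assert hits == [] and summary["n_repeats"].sum() == 0

    def test_missing_sequence_skipped_and_reported(self):
        regions = [GeneRegion("G1", "nowhere", 0, 10)]
        hits, _, skipped = scan_gene_regions({}, regions, flank=10)
        assert hits == [] and skipped == ["G1"]

    def test_shared_repeat_counted_once_per_gene(self):
        seq = "ACCA" * 30 + "AGGTCAAGGTCA" + "ACCA" * 30
        seqs = {"chr1": seq}
        regions = [GeneRegion("G1", "chr1", 100, 110),
                   GeneRegion("G2", "chr1", 130, 140)]
        hits, summary, _ = scan_gene_regions(seqs, regions, flank=200)
        assert len(hits) == 2  # one region-hit per gene
        row = summary[summary.spacing == 0].iloc[0]
        assert row.n_repeats == 2 and row.n_genes_with_repeat == 2

    def test_tss_window_is_strand_aware(self):
        # plant a DR just upstream of the gene start; a small TSS window on
        # the plus strand sees it, the same window on the minus strand
        # (anchored at the gene end) does not
        seq = "ACCA" * 25 + "AGGTCAAGGTCA" + "ACCA" * 25  # DR0 at 100..112
        seqs = {"chr1": seq}
        plus = [GeneRegion("G1", "chr1", 120, 190, "+")]
        minus = [GeneRegion("G1", "chr1", 120, 190, "-")]
        hits_plus, _, _ = scan_gene_regions(seqs, plus, flank=30, tss_only=True)
        hits_minus, _, _ = scan_gene_regions(seqs, minus, flank=30, tss_only=True)
        assert len(hits_plus) == 1 and hits_minus == []

    def test_hits_frame_columns(self):
        seqs = {"chr1": "AGGTCAAGGTCA"}
        regions = [GeneRegion("G1", "chr1", 0, 12)]
        hits, _, _ = scan_gene_regions(seqs, regions, flank=0)
        df = hits_to_frame(hits)
        assert list(df.columns) == ["seq_id", "start", "end", "gene_id", "spacing", "strand"]
        assert df.iloc[0].tolist() == ["chr1", 0, 12, "G1", 0, "+"]
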