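import math
from collections import Counter

import pytest

from phosphopipe.phospho_patterns import classify_site
from phosphopipe.psm_filters import FilterCriteria, filter_psms
from phosphopipe.synthetic_data import (
    CELL_LINES,
    CONDITIONS,
    FRACTIONS,
    REPLICATES,
    GroundTruth,
    SynthConfig,
    generate_dataset,
    generate_de_tables,
    generate_proteome,
    generate_regions_with_drs,
    simulate_identifications,
)
from phosphopipe.tables_io import read_bed, read_de_table, read_fasta, read_psm_table

SMALL = dict(n_proteins=40, n_de_genes=200, n_regulated_a=20, n_regulated_b=12,
             shared_regulated=5, n_genes=4, region_length=1200,
             planted_dr_counts={0: 1, 5: 1})


class TestProteome:
    def test_zero_proteins(self):
        proteins, truth = generate_proteome(SynthConfig(n_proteins=0, seed=1))
        assert proteins == [] and truth.sites == []

    def test_deterministic_given_seed(self):
        a, _ = generate_proteome(SynthConfig(**SMALL, seed=5))
        b, _ = generate_proteome(SynthConfig(**SMALL, seed=5))
        c, _ = generate_proteome(SynthConfig(**SMALL, seed=6))
        assert a == b
        assert a != c

    def test_planted_sites_match_their_sequence(self):
        proteins, truth = generate_proteome(SynthConfig(**SMALL, seed=2))
        seqs = {p.accession: p.sequence for p in proteins}
        assert truth.sites
        for site in truth.sites:
            assert seqs[site.accession][site.position - 1] == site.residue
            assert classify_site(seqs[site.accession], site.position) == site.site_class

    def test_pure_proline_class_mix(self):
        cfg = SynthConfig(**SMALL, seed=3,
                          class_mix={"P": 1.0, "A": 0.0, "B": 0.0, "other": 0.0})
        proteins, truth = generate_proteome(cfg)
        seqs = {p.accession: p.sequence for p in proteins}
        for site in truth.sites:
            assert seqs[site.accession][site.position] == "P"  # +1 neighbor

    def test_units_tile_the_protein(self):
        proteins, truth = generate_proteome(SynthConfig(**SMALL, seed=4))
        for prot in proteins:
            units = truth.units[prot.accession]
            assert "".join(u.sequence for u in units) == prot.sequence
            offset = 0
            for u in units:
                assert u.start == offset
                offset += len(u.sequence)


class TestIdentifications:
    def test_full_detection_no_noise_detects_everything(self):
        cfg = SynthConfig(**SMALL, seed=7, p_detect=1.0)
        proteins, truth = generate_proteome(cfg)
        simulate_identifications(proteins, truth, cfg)
        for cl in CELL_LINES:
            eligible_cyto = {
                p.accession for p in proteins
                if cl in truth.protein_cell_lines[p.accession]
                and truth.protein_fraction[p.accession] == "cytosolic"
            }
            for cond in CONDITIONS:
                for rep in REPLICATES:
                    key = f"{cl}/{cond}/{rep}/cytosolic"
                    assert set(truth.detected[key]) == eligible_cyto

    def test_both_replicate_fraction_near_p_squared(self):
        p = 0.8
        cfg = SynthConfig(n_proteins=2000, seed=8, p_detect=p,
                          shared_protein_fraction=1.0, phosphoprotein_fraction=0.0)
        proteins, truth = generate_proteome(cfg)
        simulate_identifications(proteins, truth, cfg)
        both = n = 0
        for frac in FRACTIONS:
            eligible = [a for a in truth.protein_fraction
                        if truth.protein_fraction[a] == frac]
            r1 = set(truth.detected[f"lineA/vehicle/R1/{frac}"])
            r2 = set(truth.detected[f"lineA/vehicle/R2/{frac}"])
            both += sum(1 for a in eligible if a in r1 and a in r2)
            n += len(eligible)
        se = math.sqrt(p * p * (1 - p * p) / n)
        assert abs(both / n - p * p) <= 3 * se

    def test_injected_bad_rows_counted_and_rejected(self):
        cfg = SynthConfig(**SMALL, seed=9, fraction_rank2=0.1, fraction_fail_conf=0.05)
        proteins, truth = generate_proteome(cfg)
        psms = simulate_identifications(proteins, truth, cfg)
        kept, tally = filter_psms(psms, FilterCriteria(use_fdr_flag=True))
        assert tally["rank"] == truth.n_injected_rank
        assert tally["fdr"] == truth.n_injected_conf
        assert len(kept) + sum(tally.values()) == len(psms)

    def test_response_label_controls_conditions(self):
        cfg = SynthConfig(**SMALL, seed=10, p_detect=1.0)
        proteins, truth = generate_proteome(cfg)
        psms = simulate_identifications(proteins, truth, cfg)
        by_acc_cond = Counter()
        for p in psms:
            if p.n_phospho:
                by_acc_cond[(p.accession, p.condition)] += 1
        for acc, label in truth.response_label.items():
            in_vehicle = by_acc_cond[(acc, "vehicle")] > 0
            in_ra = by_acc_cond[(acc, "RA")] > 0
            if label == "-":
                assert in_vehicle and not in_ra
            elif label == "+":
                assert in_ra and not in_vehicle
            else:
                assert in_vehicle and in_ra


class TestRegionsAndDe:
    def test_zero_planted_motif_free(self):
        cfg = SynthConfig(n_genes=3, region_length=800, planted_dr_counts={}, seed=12)
        seqs, regions, truth = generate_regions_with_drs(cfg)
        from phosphopipe.rare_scanner import find_direct_repeats, find_half_sites
        for seq in seqs.values():
            assert find_half_sites(seq) == [] and find_direct_repeats(seq) == []

    def test_minus_strand_planting_recovered_with_strand(self):
        cfg = SynthConfig(n_genes=2, region_length=1000,
                          planted_dr_counts={3: 4}, minus_strand_fraction=1.0, seed=13)
        _, _, truth = generate_regions_with_drs(cfg)
        assert len(truth.planted_drs) == 4
        assert all(d["strand"] == "-" for d in truth.planted_drs)

    def test_planting_overflow_rejected(self):
        cfg = SynthConfig(n_genes=1, region_length=100,
                          planted_dr_counts={10: 10}, seed=14)
        with pytest.raises(ValueError, match="overflow"):
            generate_regions_with_drs(cfg)

    def test_de_tables_deterministic(self):
        a1, b1, _ = generate_de_tables(SynthConfig(**SMALL, seed=15))
        a2, b2, _ = generate_de_tables(SynthConfig(**SMALL, seed=15))
        assert a1 == a2 and b1 == b2


class TestDatasetRoundTrip:
    def test_generated_files_parse_and_truth_roundtrips(self, tmp_path):
        cfg = SynthConfig(**SMALL, seed=16)
        truth = generate_dataset(cfg, tmp_path)
        proteome = read_fasta(tmp_path / "proteome.fasta")
        assert len(proteome) == SMALL["n_proteins"]
        psms = read_psm_table(tmp_path / "psms.tsv")
        assert psms
        seqs = {p.accession: p.sequence for p in proteome}
        for psm in psms:
            assert seqs[psm.accession][psm.start:psm.start + len(psm.peptide)] == psm.peptide
        assert len(read_bed(tmp_path / "regions.bed")) == SMALL["n_genes"]
        assert len(read_de_table(tmp_path / "de_lineA.tsv")) == SMALL["n_de_genes"]
        loaded = GroundTruth.from_json(tmp_path / "truth.json")
        assert loaded.sites == truth.sites
        assert loaded.detected == truth.detected

    def test_byte_identical_across_reruns(self, tmp_path):
        cfg1 = SynthConfig(**SMALL, seed=17)
        cfg2 = SynthConfig(**SMALL, seed=17)
        generate_dataset(cfg1, tmp_path / "a")
        generate_dataset(cfg2, tmp_path / "b")
        for name in ("proteome.fasta", "psms.tsv", "regions.fasta", "regions.bed",
                     "de_lineA.tsv", "de_lineB.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
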