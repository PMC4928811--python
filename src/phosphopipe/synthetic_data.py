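"""Synthetic inputs with known ground truth for every pipeline stage.

The study design emulated here: two cell lines, each sampled with and
without retinoic-acid (RA) treatment, in two replicate experiments, in two
subcellular fractions.  Raw identifications, gene regions with planted
response elements and differential-expression tables are all generated from
configurable distributions, and the exact truth (planted sites, per-sample
detection, planted repeats, regulated genes) is recorded alongside.

Proteins are built as concatenations of "peptide units": segments ending in
K or R with no internal K/R, so each unit is a known peptide with a known
protein offset.  Phosphosites are planted inside designated units with their
residue and motif class forced by construction (e.g. a proline written at +1
for a proline-directed site), which makes multiplicity, residue and class
mixes exact sampling targets rather than emergent properties.

Reproducibility: every generator derives its random stream from
``default_rng([seed, stream_id])`` with a fixed per-generator stream id, so
modules can be regenerated independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import rare_scanner
from .tables_io import (
    DeGeneRow,
    GeneRegion,
    ProteinRecord,
    PsmRecord,
    SiteProb,
    write_bed,
    write_de_table,
    write_fasta,
    write_psm_table,
)

STREAM_IDS = {"proteome": 1, "psms": 2, "regions": 3, "de": 4}

#: background residues for peptide-unit interiors: the 20 standard amino
#: acids minus K/R (reserved for unit termini) — S/T/Y stay in the
#: background, they are simply never reported as phosphorylated.
_BACKGROUND_AA = "ACDEFGHILMNPQSTVWY"
_NUCLEOTIDES = "ACGT"

CELL_LINES = ("lineA", "lineB")
CONDITIONS = ("vehicle", "RA")
REPLICATES = ("R1", "R2")
FRACTIONS = ("cytosolic", "nuclear")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from one master seed."""
    return np.random.default_rng([int(seed), STREAM_IDS[name]])


@dataclass
class SynthConfig:
    """All knobs of the generators; defaults emulate the study conditions.

    The residue mix is the marginal distribution over reported phospho
    events: mostly serine (70%), little threonine (5%), trace tyrosine
    (0.4%), the remainder ambiguous (localization below 99%).  Multiplicity
    defaults make mono- and bi-phosphorylated peptides the majority with 5%
    tri-phosphorylated.
    """

    # proteome
    n_proteins: int = 200
    units_per_protein: tuple[int, int] = (8, 16)  # inclusive range
    unit_len: tuple[int, int] = (8, 20)
    phospho_unit_len: tuple[int, int] = (16, 26)
    phosphoprotein_fraction: float = 0.5
    phospho_units_per_protein: tuple[int, int] = (1, 4)
    multiplicity_mix: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    residue_marginal: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.70, "T": 0.05, "Y": 0.004, "ambiguous": 0.246}
    )
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"P": 0.40, "A": 0.30, "B": 0.15, "other": 0.15}
    )
    # identification simulation
    p_detect: float = 0.8
    p_two_peptides: float = 1.0
    n_base_peptides: int = 3
    p_detect_phospho_unit: float = 1.0
    response_mix: Mapping[str, float] = field(
        default_factory=lambda: {"±": 0.6, "-": 0.2, "+": 0.2}
    )
    shared_protein_fraction: float = 0.7
    charge_mix: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1}
    )
    score_pass_shift: float = 1.0  # mean score offset above the charge threshold
    score_fail_shift: float = -1.0
    score_sd: float = 0.2
    fraction_rank2: float = 0.0  # injected known-bad rows, as a fraction of good rows
    fraction_fail_conf: float = 0.0
    # gene regions / direct repeats
    n_genes: int = 11
    region_length: int = 3000
    planted_dr_counts: Mapping[int, float] = field(
        default_factory=lambda: {s: 1 for s in range(11)}
    )
    minus_strand_fraction: float = 0.5
    # differential expression
    n_de_genes: int = 2000
    n_regulated_a: int = 140
    n_regulated_b: int = 100
    shared_regulated: int = 28
    discordant_fraction: float = 0.25  # of the shared regulated genes
    effect_lfc: tuple[float, float] = (1.5, 4.0)
    effect_log10p: tuple[float, float] = (4.0, 8.0)
    null_lfc_limit: float = 0.8  # null |log2fc| stays strictly below the cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in (self.multiplicity_mix, self.residue_marginal, self.class_mix,
                    self.response_mix, self.charge_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mix must sum to 1, got {total}: {mix}")
        for p in (self.p_detect, self.p_two_peptides, self.phosphoprotein_fraction,
                  self.shared_protein_fraction, self.minus_strand_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def ambiguous_fraction(self) -> float:
        return self.residue_marginal.get("ambiguous", 0.0)

    @property
    def residue_mix_localized(self) -> dict[str, float]:
        """S/T/Y mix conditional on the site being localized."""
        loc = {r: v for r, v in self.residue_marginal.items() if r != "ambiguous"}
        total = sum(loc.values())
        return {r: v / total for r, v in loc.items()}


@dataclass
class TrueSite:
    accession: str
    position: int  # 1-based in the protein
    residue: str
    site_class: str
    unit_index: int


@dataclass
class PeptideUnit:
    sequence: str
    start: int  # 0-based offset in the protein
    is_phospho: bool
    site_offsets: tuple[int, ...] = ()  # 1-based positions within the unit


@dataclass
class GroundTruth:
    """Everything the generators decided, for truth-vs-recovered checks."""

    sites: list[TrueSite] = field(default_factory=list)
    units: dict[str, list[PeptideUnit]] = field(default_factory=dict)
    protein_fraction: dict[str, str] = field(default_factory=dict)
    protein_cell_lines: dict[str, list[str]] = field(default_factory=dict)
    response_label: dict[str, str] = field(default_factory=dict)
    detected: dict[str, list[str]] = field(default_factory=dict)  # "cl/cond/rep/frac" -> accessions
    n_injected_rank: int = 0
    n_injected_conf: int = 0
    planted_drs: list[dict] = field(default_factory=list)
    regulated: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True, ensure_ascii=False))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["sites"] = [TrueSite(**s) for s in data["sites"]]
        data["units"] = {
            acc: [PeptideUnit(u["sequence"], u["start"], u["is_phospho"],
                              tuple(u["site_offsets"])) for u in units]
            for acc, units in data["units"].items()
        }
        return cls(**data)


def _choice(rng: np.random.Generator, mix: Mapping) -> object:
    keys = list(mix.keys())
    return keys[rng.choice(len(keys), p=np.asarray([mix[k] for k in keys], float))]


def _random_unit(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_BACKGROUND_AA), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _plant_phospho_unit(
    rng: np.random.Generator, cfg: SynthConfig, multiplicity: int
) -> tuple[str, list[int], list[str], list[str]]:
    """A peptide unit with ``multiplicity`` sites of forced residue/class.

    Returns (sequence, 1-based site offsets, residues, classes).  Sites are
    spaced >= 6 apart so the forced −3..+1 neighborhoods never interact.
    """
    length = int(rng.integers(cfg.phospho_unit_len[0], cfg.phospho_unit_len[1] + 1))
    needed = 4 + (multiplicity - 1) * 6  # first site at index >= 3, then 6 apart
    if length - 3 < needed:
        length = needed + 4
    seq = list(_random_unit(rng, length))
    # candidate indices: leave room for -3 and +1 neighbors, keep off the
    # terminal K/R
    first = int(rng.integers(3, length - 2 - (multiplicity - 1) * 6))
    indices = [first + 6 * i for i in range(multiplicity)]
    residues, classes = [], []
    mix = cfg.residue_mix_localized
    for idx in indices:
        residue = str(_choice(rng, mix))
        site_class = str(_choice(rng, cfg.class_mix))
        seq[idx] = residue
        if site_class == "P":
            seq[idx + 1] = "P"
        elif site_class == "A":
            seq[idx + 1] = str(rng.choice(["D", "E"]))
        elif site_class == "B":
            seq[idx + 1] = "G"
            seq[idx - 3] = str(rng.choice(["K", "R"]))
        else:  # other: scrub every motif position
            seq[idx + 1] = "G"
            seq[idx - 3] = "G"
            seq[idx - 2] = "G"
        if site_class in ("P", "A"):  # basic residues upstream would not
            # change the class (P/A take precedence) but keep truth clean
            pass
        residues.append(residue)
        classes.append(site_class)
    return "".join(seq), [i + 1 for i in indices], residues, classes


def generate_proteome(
    config: SynthConfig, seed: int | None = None
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Random proteome with phosphosites planted at the configured mixes."""
    rng = substream(config.seed if seed is None else seed, "proteome")
    truth = GroundTruth()
    proteins: list[ProteinRecord] = []
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:05d}"
        is_phospho = rng.random() < config.phosphoprotein_fraction
        n_units = int(rng.integers(config.units_per_protein[0], config.units_per_protein[1] + 1))
        n_phospho_units = 0
        if is_phospho:
            n_phospho_units = int(rng.integers(
                config.phospho_units_per_protein[0],
                config.phospho_units_per_protein[1] + 1,
            ))
            n_units = max(n_units, n_phospho_units + 2)
        phospho_slots = set(
            rng.choice(n_units, size=n_phospho_units, replace=False).tolist()
        ) if n_phospho_units else set()
        units: list[PeptideUnit] = []
        offset = 0
        seen_sequences: set[str] = set()
        for u in range(n_units):
            if u in phospho_slots:
                multiplicity = int(_choice(rng, config.multiplicity_mix))
                seq, offsets, residues, classes = _plant_phospho_unit(rng, config, multiplicity)
                units.append(PeptideUnit(seq, offset, True, tuple(offsets)))
                for off, res, cls in zip(offsets, residues, classes):
                    truth.sites.append(TrueSite(acc, offset + off, res, cls, u))
            else:
                seq = _random_unit(rng, int(rng.integers(config.unit_len[0], config.unit_len[1] + 1)))
                while seq in seen_sequences:  # keep base peptides distinct
                    seq = _random_unit(rng, int(rng.integers(config.unit_len[0], config.unit_len[1] + 1)))
                units.append(PeptideUnit(seq, offset, False))
            seen_sequences.add(units[-1].sequence)
            offset += len(units[-1].sequence)
        truth.units[acc] = units
        truth.protein_fraction[acc] = FRACTIONS[int(rng.random() < 0.5)]
        shared = rng.random() < config.shared_protein_fraction
        truth.protein_cell_lines[acc] = (
            list(CELL_LINES) if shared else [CELL_LINES[int(rng.random() < 0.5)]]
        )
        if is_phospho and phospho_slots:
            truth.response_label[acc] = str(_choice(rng, config.response_mix))
        proteins.append(ProteinRecord(acc, "".join(u.sequence for u in units)))
    return proteins, truth


def _sample_key(cell_line: str, condition: str, replicate: str, fraction: str) -> str:
    return f"{cell_line}/{condition}/{replicate}/{fraction}"


def _draw_score(rng: np.random.Generator, cfg: SynthConfig, charge: int, passing: bool) -> float:
    thresholds = {1: 1.5, 2: 2.5, 3: 3.0, 4: 3.2}
    base = thresholds.get(charge, 3.2)
    shift = cfg.score_pass_shift if passing else cfg.score_fail_shift
    return float(base + shift + rng.normal(0.0, cfg.score_sd))


def simulate_identifications(
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SynthConfig,
    seed: int | None = None,
) -> list[PsmRecord]:
    """PSM rows for every cell line x condition x replicate x fraction.

    Detection is independent per (protein, sample) with probability
    ``p_detect``.  A detected protein emits >= 2 distinct unmodified
    peptides with probability ``p_two_peptides`` (one otherwise), plus its
    phosphopeptide units when its RA-response label allows the condition
    (label "−": vehicle only; "+": RA only; "±": both).  Optional known-bad
    rows (rank 2, or confidence failures with both a sub-threshold score and
    a cleared FDR flag) are appended and counted in the truth record.
    """
    rng = substream(config.seed if seed is None else seed, "psms")
    psms: list[PsmRecord] = []
    truth.detected = {}
    truth.n_injected_rank = 0
    truth.n_injected_conf = 0
    for cell_line in CELL_LINES:
        for condition in CONDITIONS:
            for replicate in REPLICATES:
                for fraction in FRACTIONS:
                    key = _sample_key(cell_line, condition, replicate, fraction)
                    truth.detected[key] = []
                    for protein in proteome:
                        acc = protein.accession
                        if cell_line not in truth.protein_cell_lines[acc]:
                            continue
                        if truth.protein_fraction[acc] != fraction:
                            continue
                        if rng.random() >= config.p_detect:
                            continue
                        truth.detected[key].append(acc)
                        units = truth.units[acc]
                        base_units = [u for u in units if not u.is_phospho]
                        n_base = (
                            min(config.n_base_peptides, len(base_units))
                            if rng.random() < config.p_two_peptides else 1
                        )
                        picked = rng.choice(len(base_units), size=n_base, replace=False)
                        for bi in sorted(picked):
                            psms.append(_make_psm(rng, config, protein, base_units[bi],
                                                  cell_line, condition, replicate, fraction))
                        label = truth.response_label.get(acc)
                        if label is None:
                            continue
                        if (label == "-" and condition != "vehicle") or (
                            label == "+" and condition != "RA"
                        ):
                            continue
                        for unit in units:
                            if unit.is_phospho and rng.random() < config.p_detect_phospho_unit:
                                psms.append(_make_psm(rng, config, protein, unit,
                                                      cell_line, condition, replicate, fraction))
    n_good = len(psms)
    n_rank = int(round(config.fraction_rank2 * n_good))
    n_conf = int(round(config.fraction_fail_conf * n_good))
    for i in range(n_rank + n_conf):
        template = psms[int(rng.integers(0, n_good))]
        bad_rank = i < n_rank
        psms.append(dataclasses.replace(
            template,
            rank=2 if bad_rank else 1,
            fdr_pass=bad_rank and template.fdr_pass,
            score=template.score if bad_rank
            else _draw_score(rng, config, template.charge, passing=False),
            site_probs=template.site_probs,
        ))
    truth.n_injected_rank = n_rank
    truth.n_injected_conf = n_conf
    return psms


def _make_psm(
    rng: np.random.Generator,
    cfg: SynthConfig,
    protein: ProteinRecord,
    unit: PeptideUnit,
    cell_line: str,
    condition: str,
    replicate: str,
    fraction: str,
) -> PsmRecord:
    charge = int(_choice(rng, cfg.charge_mix))
    site_probs = []
    for off in unit.site_offsets:
        if rng.random() < cfg.ambiguous_fraction:
            prob = float(rng.uniform(0.80, 0.9899))
        else:
            prob = float(rng.uniform(0.99, 1.0))
        site_probs.append(SiteProb(off, unit.sequence[off - 1], round(prob, 6)))
    return PsmRecord(
        peptide=unit.sequence,
        accession=protein.accession,
        start=unit.start,
        charge=charge,
        score=round(_draw_score(rng, cfg, charge, passing=True), 4),
        rank=1,
        fdr_pass=True,
        n_phospho=len(unit.site_offsets),
        site_probs=tuple(site_probs),
        cell_line=cell_line,
        condition=condition,
        replicate=replicate,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Gene regions with planted direct repeats
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NUCLEOTIDES), size=length))


def _scrub_half_sites(rng: np.random.Generator, seq: str, max_rounds: int = 200) -> str:
    """Rewrite hexamer windows until the sequence contains no half-site."""
    s = list(seq)
    for _ in range(max_rounds):
        matches = rare_scanner.find_half_sites("".join(s))
        if not matches:
            return "".join(s)
        for m in matches:
            for j in range(m.pos, m.pos + rare_scanner.HALF_SITE_LEN):
                s[j] = str(rng.choice(list(_NUCLEOTIDES)))
    raise RuntimeError("could not scrub half-sites from background sequence")


def _concrete_half_site(rng: np.random.Generator) -> str:
    return (str(rng.choice(["A", "G"])) + "G" + str(rng.choice(["G", "T"]))
            + "T" + str(rng.choice(["C", "G"])) + "A")


def generate_regions_with_drs(
    config: SynthConfig, seed: int | None = None
) -> tuple[dict[str, str], list[GeneRegion], GroundTruth]:
    """Motif-free background regions with direct repeats planted per spacing.

    Each planted-count entry may be fractional only in the sense of being an
    integer per spacing; repeats are distributed round-robin over genes.
    The final sequences are re-scanned and regeneration is retried until the
    scanner recovers exactly the planted repeats, so recovery is guaranteed
    by construction.
    """
    rng = substream(config.seed if seed is None else seed, "regions")
    total_planted = int(sum(config.planted_dr_counts.values()))
    plant_jobs: list[int] = []  # spacings, round-robin over genes
    for spacing, count in sorted(config.planted_dr_counts.items()):
        plant_jobs.extend([int(spacing)] * int(count))
    if config.n_genes == 0 and total_planted:
        raise ValueError("cannot plant repeats with zero genes")
    per_gene: dict[int, list[int]] = {i: [] for i in range(config.n_genes)}
    for j, spacing in enumerate(plant_jobs):
        per_gene[j % config.n_genes].append(spacing)

    truth = GroundTruth()
    sequences: dict[str, str] = {}
    regions: list[GeneRegion] = []
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:04d}"
        seq_id = f"chr_{gene_id}"
        spacings_here = per_gene[i]
        max_span = 12 + (max(spacings_here) if spacings_here else 0)
        if config.region_length <= max_span:
            raise ValueError("region_length too small for the requested spacings")
        needed = sum(12 + s + 12 for s in spacings_here)  # element + margin
        if needed > config.region_length:
            raise ValueError(
                f"planting overflow: {len(spacings_here)} repeats do not fit in "
                f"{config.region_length} nt"
            )
        for _attempt in range(50):
            seq = _scrub_half_sites(rng, _random_dna(rng, config.region_length))
            planted = _plant_repeats(rng, seq, spacings_here, config)
            if planted is None:
                continue
            seq, records = planted
            found = rare_scanner.find_direct_repeats(seq, range(11), seq_id)
            expected = sorted((r["pos"], r["spacing"], r["strand"]) for r in records)
            got = sorted((d.start, d.spacing, d.strand) for d in found)
            if got == expected:
                break
        else:
            raise RuntimeError(f"could not plant repeats cleanly in {gene_id}")
        sequences[seq_id] = seq
        for r in records:
            r["gene_id"] = gene_id
            r["seq_id"] = seq_id
            truth.planted_drs.append(r)
        third = config.region_length // 3
        regions.append(GeneRegion(gene_id, seq_id, third, 2 * third, "+"))
    return sequences, regions, truth


def _plant_repeats(
    rng: np.random.Generator, background: str, spacings: list[int], config: SynthConfig
) -> tuple[str, list[dict]] | None:
    """Write repeat elements into a motif-free background, well separated."""
    s = list(background)
    used: list[tuple[int, int]] = []
    records: list[dict] = []
    for spacing in spacings:
        elem_len = 12 + spacing
        for _try in range(200):
            pos = int(rng.integers(0, len(s) - elem_len + 1))
            window = (pos - 12, pos + elem_len + 12)  # margin blocks cross-element DRs
            if any(not (window[1] <= lo or window[0] >= hi) for lo, hi in used):
                continue
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            elem = (_concrete_half_site(rng)
                    + _random_dna(rng, spacing)
                    + _concrete_half_site(rng))
            if strand == "-":
                elem = rare_scanner.reverse_complement(elem)
            s[pos:pos + elem_len] = list(elem)
            used.append(window)
            records.append({"pos": pos, "spacing": spacing, "strand": strand})
            break
        else:
            return None
    return "".join(s), records


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def generate_de_tables(
    config: SynthConfig, seed: int | None = None
) -> tuple[list[DeGeneRow], list[DeGeneRow], GroundTruth]:
    """Two synthetic DE tables (cell lines A and B) with known regulation.

    Regulated genes receive |log2fc| in ``effect_lfc`` and p-values of
    1e-``effect_log10p``; null genes receive |log2fc| strictly below
    ``null_lfc_limit`` and uniform p-values, so threshold selection recovers
    the truth exactly.
    """
    rng = substream(config.seed if seed is None else seed, "de")
    if config.n_regulated_a > config.n_de_genes or config.n_regulated_b > config.n_de_genes:
        raise ValueError("more regulated genes than genes")
    genes = [f"g{i + 1:05d}" for i in range(config.n_de_genes)]
    order = rng.permutation(config.n_de_genes)
    n_shared = min(config.shared_regulated, config.n_regulated_a, config.n_regulated_b)
    shared = [genes[j] for j in order[:n_shared]]
    a_only = [genes[j] for j in order[n_shared:n_shared + config.n_regulated_a - n_shared]]
    b_start = n_shared + len(a_only)
    b_only = [genes[j] for j in order[b_start:b_start + config.n_regulated_b - n_shared]]

    def effect(sign: float) -> float:
        return float(sign * rng.uniform(*config.effect_lfc))

    def effect_p() -> float:
        return float(10.0 ** -rng.uniform(*config.effect_log10p))

    lfc_a: dict[str, float] = {}
    lfc_b: dict[str, float] = {}
    for g in a_only:
        lfc_a[g] = effect(rng.choice([-1.0, 1.0]))
    for g in b_only:
        lfc_b[g] = effect(rng.choice([-1.0, 1.0]))
    for g in shared:
        sign = float(rng.choice([-1.0, 1.0]))
        lfc_a[g] = effect(sign)
        discordant = rng.random() < config.discordant_fraction
        lfc_b[g] = effect(-sign if discordant else sign)

    def build(lfc_map: dict[str, float]) -> list[DeGeneRow]:
        rows = []
        for g in genes:
            if g in lfc_map:
                rows.append(DeGeneRow(g, lfc_map[g], effect_p()))
            else:
                lfc = float(rng.uniform(-config.null_lfc_limit, config.null_lfc_limit))
                rows.append(DeGeneRow(g, lfc, float(rng.uniform())))
        return rows

    rows_a, rows_b = build(lfc_a), build(lfc_b)
    truth = GroundTruth(regulated={
        "lineA": {
            "up": sorted(g for g, v in lfc_a.items() if v > 0),
            "down": sorted(g for g, v in lfc_a.items() if v < 0),
        },
        "lineB": {
            "up": sorted(g for g, v in lfc_b.items() if v > 0),
            "down": sorted(g for g, v in lfc_b.items() if v < 0),
        },
    })
    return rows_a, rows_b, truth


# ---------------------------------------------------------------------------
# One-call dataset writer
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    "small": dict(n_proteins=60, n_de_genes=400, n_regulated_a=30, n_regulated_b=20,
                  shared_regulated=8, n_genes=6, region_length=1500,
                  planted_dr_counts={s: 1 for s in range(6)}),
    "paper-scale": dict(n_proteins=2000, n_de_genes=20000, n_regulated_a=1400,
                        n_regulated_b=1000, shared_regulated=280, n_genes=40,
                        region_length=5000),
}


def generate_dataset(config: SynthConfig, outdir: str | Path) -> GroundTruth:
    """Write a self-contained dataset directory plus its ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome, truth = generate_proteome(config)
    psms = simulate_identifications(proteome, truth, config)
    sequences, regions, region_truth = generate_regions_with_drs(config)
    de_a, de_b, de_truth = generate_de_tables(config)
    truth.planted_drs = region_truth.planted_drs
    truth.regulated = de_truth.regulated

    write_fasta(proteome, outdir / "proteome.fasta")
    write_psm_table(psms, outdir / "psms.tsv")
    write_fasta(
        [ProteinRecord(sid, seq) for sid, seq in sequences.items()],
        outdir / "regions.fasta",
    )
    write_bed(regions, outdir / "regions.bed")
    write_de_table(de_a, outdir / "de_lineA.tsv")
    write_de_table(de_b, outdir / "de_lineB.tsv")
    truth.to_json(outdir / "truth.json")
    return truth
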