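"""Domain types, file readers/writers and run configuration.

All coordinates are 0-based half-open internally.  Positions shown to humans
(phosphosite tables, reports) are 1-based, matching the usual "S77" style of
naming a phosphorylated residue.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

VALID_PHOSPHO_RESIDUES = frozenset("STY")
AMBIGUOUS = "ambiguous"


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry.

    ``sequence`` is an uppercase amino-acid string over the 20 standard
    letters; ``X`` is permitted as an unknown residue (it never matches a
    protease cleavage residue and is never a phosphosite).
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")


@dataclass(frozen=True)
class SiteProb:
    """One phospho-localization probability on a peptide.

    ``position`` is 1-based within the peptide; ``residue`` is the amino acid
    at that position (S, T or Y); ``probability`` is the upstream
    localization probability in [0, 1].
    """

    position: int
    residue: str
    probability: float

    def __post_init__(self) -> None:
        if self.residue not in VALID_PHOSPHO_RESIDUES:
            raise ValueError(f"phospho residue must be S/T/Y, got {self.residue!r}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability out of [0,1]: {self.probability}")
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its evidence and sample labels."""

    peptide: str
    accession: str
    start: int  # 0-based offset of the peptide in the protein
    charge: int
    score: float
    rank: int
    fdr_pass: bool
    n_phospho: int
    site_probs: tuple[SiteProb, ...] = ()
    cell_line: str = ""
    condition: str = ""  # "vehicle" | "RA"
    replicate: str = ""  # "R1" | "R2"
    fraction: str = ""  # "cytosolic" | "nuclear"

    def __post_init__(self) -> None:
        if self.n_phospho > len(self.peptide):
            raise ValueError(
                f"n_phospho {self.n_phospho} exceeds peptide length for {self.peptide!r}"
            )
        if self.n_phospho < 0:
            raise ValueError("n_phospho must be >= 0")
        for sp in self.site_probs:
            if sp.position > len(self.peptide):
                raise ValueError(
                    f"site position {sp.position} outside peptide {self.peptide!r}"
                )
            if self.peptide[sp.position - 1] != sp.residue:
                raise ValueError(
                    f"site at peptide position {sp.position} is "
                    f"{self.peptide[sp.position - 1]!r}, not {sp.residue!r}"
                )

    @property
    def sample(self) -> tuple[str, str, str, str]:
        return (self.cell_line, self.condition, self.replicate, self.fraction)


@dataclass(frozen=True)
class PhosphoSite:
    """A localized (or ambiguous) phosphosite in protein coordinates.

    ``position`` is 1-based in the protein.  ``residue`` is ``"ambiguous"``
    exactly when the localization probability fell below the configured
    threshold; the phosphorylation event is still counted.
    """

    accession: str
    position: int
    residue: str  # "S" | "T" | "Y" | "ambiguous"
    probability: float
    site_class: str = ""  # "P" | "A" | "B" | "other" | ""

    def __post_init__(self) -> None:
        if self.residue not in VALID_PHOSPHO_RESIDUES and self.residue != AMBIGUOUS:
            raise ValueError(f"bad residue {self.residue!r}")
        if self.position < 1:
            raise ValueError("protein position is 1-based; must be >= 1")


@dataclass(frozen=True)
class GeneRegion:
    """Gene limits on a reference sequence, 0-based half-open."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class DeGeneRow:
    """One gene's differential-expression record."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float | None = None
    status: str = "ns"  # "up" | "down" | "ns"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"pvalue out of [0,1]: {self.pvalue}")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj out of [0,1]: {self.padj}")


@dataclass
class DigestParamsConfig:
    enzyme: str = "trypsin_lysC"
    max_missed: int = 2
    min_len: int = 7
    max_len: int = 35
    min_mass: float = 500.0
    max_mass: float = 5000.0


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the published defaults.

    ``score_by_charge`` maps charge state to the minimum search-engine score
    on the score-filter path (used when no upstream FDR flag is available);
    charges above the largest key use the last threshold.
    """

    score_by_charge: dict[int, float] = field(
        default_factory=lambda: {1: 1.5, 2: 2.5, 3: 3.0, 4: 3.2}
    )
    use_fdr_flag: bool = True
    max_rank: int = 1
    min_localization: float = 0.99
    min_peptides_per_protein: int = 2
    min_phosphopeptides: int = 1
    digestion: DigestParamsConfig = field(default_factory=DigestParamsConfig)
    flank: int = 10_000
    dr_spacings: tuple[int, ...] = tuple(range(11))
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not (0.0 < self.min_localization <= 1.0):
            raise ValueError("min_localization must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "score_by_charge" in data:
            data["score_by_charge"] = {
                int(k): float(v) for k, v in data["score_by_charge"].items()
            }
        if "digestion" in data and isinstance(data["digestion"], Mapping):
            data["digestion"] = DigestParamsConfig(**data["digestion"])
        if "dr_spacings" in data:
            data["dr_spacings"] = tuple(int(s) for s in data["dr_spacings"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dr_spacings"] = list(self.dr_spacings)
        return d

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(self.to_dict()))))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (order preserved, uppercased).

    Raises :class:`ParseError` on an empty sequence or a duplicate accession.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate accession {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

PSM_COLUMNS = [
    "peptide", "accession", "start", "charge", "score", "rank", "fdr_pass",
    "n_phospho", "site_probs", "cell_line", "condition", "replicate", "fraction",
]


def encode_site_probs(site_probs: Sequence[SiteProb]) -> str:
    """Encode localization probabilities as ``pos:res:prob;...`` (or ``.``)."""
    if not site_probs:
        return "."
    return ";".join(f"{sp.position}:{sp.residue}:{sp.probability:g}" for sp in site_probs)


def decode_site_probs(text: str) -> tuple[SiteProb, ...]:
    if not text or text in (".", "nan"):
        return ()
    out = []
    for chunk in text.split(";"):
        pos, res, prob = chunk.split(":")
        out.append(SiteProb(int(pos), res, float(prob)))
    return tuple(out)


def read_psm_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[PsmRecord]:
    """Read a PSM TSV into typed records.

    ``column_map`` renames file columns to the documented schema
    (``{file_column: schema_column}``) so exports with other headers can be
    consumed without rewriting them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records: list[PsmRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            records.append(
                PsmRecord(
                    peptide=row.peptide,
                    accession=row.accession,
                    start=int(row.start),
                    charge=int(row.charge),
                    score=float(row.score),
                    rank=int(row.rank),
                    fdr_pass=_parse_bool(row.fdr_pass),
                    n_phospho=int(row.n_phospho),
                    site_probs=decode_site_probs(row.site_probs),
                    cell_line=row.cell_line,
                    condition=row.condition,
                    replicate=row.replicate,
                    fraction=row.fraction,
                )
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        preview = "; ".join(f"line {i}: {msg}" for i, msg in bad_rows[:5])
        raise ParseError(f"{path}: {len(bad_rows)} malformed row(s): {preview}")
    return records


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    rows = []
    for p in psms:
        rows.append({
            "peptide": p.peptide, "accession": p.accession, "start": p.start,
            "charge": p.charge, "score": p.score, "rank": p.rank,
            "fdr_pass": int(p.fdr_pass), "n_phospho": p.n_phospho,
            "site_probs": encode_site_probs(p.site_probs),
            "cell_line": p.cell_line, "condition": p.condition,
            "replicate": p.replicate, "fraction": p.fraction,
        })
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_bool(text: str) -> bool:
    t = str(text).strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


# ---------------------------------------------------------------------------
# Phosphosite tables
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["accession", "position", "residue", "probability", "site_class"]


def write_site_table(sites: Iterable[PhosphoSite], path: str | Path) -> None:
    rows = [
        {"accession": s.accession, "position": s.position, "residue": s.residue,
         "probability": s.probability, "site_class": s.site_class}
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[PhosphoSite]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return [
        PhosphoSite(r.accession, int(r.position), r.residue,
                    float(r.probability), r.site_class)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# BED6 gene regions
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GeneRegion]:
    """Read BED6 (0-based half-open) gene regions."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            seq_id, start, end, name, _score, strand = parts[:6]
            try:
                regions.append(GeneRegion(name, seq_id, int(start), int(end), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "status"]


def read_de_table(path: str | Path) -> list[DeGeneRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "log2fc", "pvalue"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing mandatory column(s): {col}")
    rows = []
    for r in df.itertuples(index=False):
        padj = getattr(r, "padj", "")
        status = getattr(r, "status", "ns") or "ns"
        rows.append(DeGeneRow(
            r.gene_id, float(r.log2fc), float(r.pvalue),
            float(padj) if padj not in ("", ".") else None, status,
        ))
    return rows


def write_de_table(rows: Iterable[DeGeneRow], path: str | Path) -> None:
    recs = [
        {"gene_id": r.gene_id, "log2fc": r.log2fc, "pvalue": r.pvalue,
         "padj": "." if r.padj is None else r.padj, "status": r.status}
        for r in rows
    ]
    pd.DataFrame(recs, columns=DE_COLUMNS).to_csv(path, sep="\t", index=False)
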