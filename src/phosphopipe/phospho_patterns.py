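"""Phosphopeptide multiplicity, residue distribution and motif-class statistics.

Site classes follow the conventional kinase-motif reading of a phosphosite's
local sequence context:

* ``P`` (proline-directed): proline immediately C-terminal (+1), the CDK/MAPK
  context (e.g. SP);
* ``A`` (acidic): D or E at +1, the casein-kinase-style context (SD/SE);
* ``B`` (basic/basophilic): K or R at −3 or −2, the PKA/PKC-style context;
* ``other``: none of the above.

Precedence is P > A > B, so each site gets exactly one class.  The window
positions are configurable because conventions differ between tools.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .tables_io import AMBIGUOUS, PhosphoSite, PsmRecord

MULTIPLICITY_BINS = ("1P", "2P", "3P+")
RESIDUE_BINS = ("S", "T", "Y", AMBIGUOUS)
SITES_PER_PROTEIN_BINS = tuple(str(i) for i in range(1, 11)) + (">10",)


@dataclass(frozen=True)
class SiteClassRule:
    """Configurable neighborhood rule for P/A/B classification."""

    proline_offsets: tuple[int, ...] = (1,)
    acidic_offsets: tuple[int, ...] = (1,)
    basic_offsets: tuple[int, ...] = (-3, -2)
    acidic_residues: frozenset[str] = frozenset("DE")
    basic_residues: frozenset[str] = frozenset("KR")


DEFAULT_RULE = SiteClassRule()


def classify_site(sequence: str, position: int, rule: SiteClassRule = DEFAULT_RULE) -> str:
    """Class of the 1-based site in ``sequence``: "P", "A", "B" or "other".

    Neighbors that fall off either end of the sequence are treated as
    non-matching.
    """
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    idx = position - 1

    def residue_at(offset: int) -> str | None:
        j = idx + offset
        return sequence[j] if 0 <= j < len(sequence) else None

    if any(residue_at(o) == "P" for o in rule.proline_offsets):
        return "P"
    if any(residue_at(o) in rule.acidic_residues for o in rule.acidic_offsets):
        return "A"
    if any(residue_at(o) in rule.basic_residues for o in rule.basic_offsets):
        return "B"
    return "other"


def multiplicity_freq(phosphopeptides: Iterable[PsmRecord]) -> tuple[dict[str, float], int]:
    """Fractions of mono-/bi-/tri(+)-phosphorylated peptides and the total.

    Peptides with four or more phospho groups are binned into ``3P+``.
    Raises on an unphosphorylated input record.
    """
    counts = Counter()
    total = 0
    for psm in phosphopeptides:
        if psm.n_phospho < 1:
            raise ValueError(f"peptide {psm.peptide!r} has n_phospho = 0")
        key = "1P" if psm.n_phospho == 1 else ("2P" if psm.n_phospho == 2 else "3P+")
        counts[key] += 1
        total += 1
    freq = {b: (counts[b] / total if total else 0.0) for b in MULTIPLICITY_BINS}
    return freq, total


def residue_distribution(sites: Iterable[PhosphoSite]) -> tuple[dict[str, float], int]:
    """Fractions of S/T/Y/ambiguous over all phosphosite records."""
    counts = Counter(site.residue for site in sites)
    total = sum(counts.values())
    freq = {b: (counts[b] / total if total else 0.0) for b in RESIDUE_BINS}
    return freq, total


def dedupe_sites(sites: Iterable[PhosphoSite]) -> list[PhosphoSite]:
    """One record per (accession, position), keeping the best localization."""
    best: dict[tuple[str, int], PhosphoSite] = {}
    for site in sites:
        key = (site.accession, site.position)
        if key not in best or site.probability > best[key].probability:
            best[key] = site
    return [best[k] for k in sorted(best)]


def sites_per_protein(sites: Iterable[PhosphoSite]) -> dict[str, int]:
    """Histogram of deduplicated site counts per protein, with a ">10" bin."""
    per_protein: dict[str, set[int]] = defaultdict(set)
    for site in dedupe_sites(sites):
        per_protein[site.accession].add(site.position)
    hist: Counter = Counter()
    for positions in per_protein.values():
        n = len(positions)
        hist[str(n) if n <= 10 else ">10"] += 1
    return {b: hist[b] for b in SITES_PER_PROTEIN_BINS if hist[b]}


def class_distribution(
    sites: Iterable[PhosphoSite],
    sequences: Mapping[str, str],
    rule: SiteClassRule = DEFAULT_RULE,
) -> tuple[dict[str, float], int]:
    """Fractions of P/A/B/other over deduplicated, localized sites."""
    counts: Counter = Counter()
    for site in dedupe_sites(sites):
        if site.residue == AMBIGUOUS:
            continue  # context of an unlocalized event is undefined
        counts[classify_site(sequences[site.accession], site.position, rule)] += 1
    total = sum(counts.values())
    return {c: (counts[c] / total if total else 0.0) for c in ("P", "A", "B", "other")}, total


@dataclass(frozen=True)
class PatternSummary:
    """The headline phosphorylation-pattern statistics of one dataset."""

    multiplicity_freq: Mapping[str, float]
    total_peptides: int
    residue_freq: Mapping[str, float]
    total_sites: int
    sites_per_protein: Mapping[str, int]

    def to_rows(self) -> list[dict]:
        rows = [
            {"statistic": "multiplicity", "bin": b, "value": self.multiplicity_freq[b]}
            for b in MULTIPLICITY_BINS
        ]
        rows += [
            {"statistic": "residue", "bin": b, "value": self.residue_freq[b]}
            for b in RESIDUE_BINS
        ]
        rows += [
            {"statistic": "sites_per_protein", "bin": b, "value": n}
            for b, n in self.sites_per_protein.items()
        ]
        rows.append({"statistic": "total_phosphopeptides", "bin": "T", "value": self.total_peptides})
        return rows


def summarize_patterns(
    phosphopeptides: Sequence[PsmRecord], sites: Sequence[PhosphoSite]
) -> PatternSummary:
    mult, total_peps = multiplicity_freq(phosphopeptides)
    res, total_sites = residue_distribution(sites)
    return PatternSummary(
        multiplicity_freq=mult,
        total_peptides=total_peps,
        residue_freq=res,
        total_sites=total_sites,
        sites_per_protein=sites_per_protein(sites),
    )


def plot_pattern_summary(summary: PatternSummary, path: str) -> None:
    """Optional bar charts of the multiplicity and residue distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    axes[0].bar(MULTIPLICITY_BINS, [summary.multiplicity_freq[b] for b in MULTIPLICITY_BINS])
    axes[0].set_title(f"Phosphopeptide multiplicity (T={summary.total_peptides})")
    axes[0].set_ylabel("fraction")
    axes[1].bar(RESIDUE_BINS, [summary.residue_freq[b] for b in RESIDUE_BINS])
    axes[1].set_title("Phosphorylated residue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
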