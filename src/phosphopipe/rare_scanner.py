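"""Retinoic-acid response element (RARE) scanning.

A RARE half-site is the degenerate hexamer 5'-RGKTSA-3' (R = A/G, K = G/T,
S = C/G).  A direct repeat DRn is an ordered pair of half-sites in the same
orientation separated by an n-nucleotide spacer; DR0–DR10 are scanned by
default, DR5 being the canonical RAR/RXR element.  Gene windows extend the
gene limits by a configurable flank (default ±10 kb).

All output coordinates are forward-strand, 0-based.  On the minus strand the
repeat's "first" half-site is the 5'-most one in minus-strand reading order,
i.e. the right-most one on the forward sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables_io import GeneRegion

logger = logging.getLogger(__name__)

HALF_SITE_LEN = 6
#: forward-strand pattern for 5'-RGKTSA-3'
FORWARD_RE = re.compile(r"(?=([AG]G[GT]T[CG]A))")
#: forward-strand pattern matched by a half-site on the minus strand
#: (reverse complement of RGKTSA)
REVERSE_RE = re.compile(r"(?=(T[CG]A[AC]C[CT]))")

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HalfSiteMatch:
    seq_id: str
    pos: int  # 0-based start of the hexamer on the forward sequence
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class DirectRepeat:
    seq_id: str
    first: HalfSiteMatch
    second: HalfSiteMatch
    spacing: int
    strand: str

    @property
    def start(self) -> int:
        """Leftmost forward coordinate of the repeat."""
        return min(self.first.pos, self.second.pos)

    @property
    def end(self) -> int:
        return max(self.first.pos, self.second.pos) + HALF_SITE_LEN


def _prepare(sequence: str, respect_mask: bool) -> str:
    if respect_mask:
        # soft-masked (lowercase) bases are excluded from matching
        sequence = "".join(c if c.isupper() else "N" for c in sequence)
    else:
        sequence = sequence.upper()
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide character(s) in sequence: {sorted(bad)}")
    return sequence


def find_half_sites(
    sequence: str, seq_id: str = "", respect_mask: bool = False
) -> list[HalfSiteMatch]:
    """All RGKTSA half-sites on both strands; overlaps are all reported."""
    seq = _prepare(sequence, respect_mask)
    matches = [HalfSiteMatch(seq_id, m.start(), "+") for m in FORWARD_RE.finditer(seq)]
    matches += [HalfSiteMatch(seq_id, m.start(), "-") for m in REVERSE_RE.finditer(seq)]
    matches.sort(key=lambda h: (h.pos, h.strand))
    return matches


def find_direct_repeats(
    sequence: str,
    spacings: Iterable[int] = range(11),
    seq_id: str = "",
    respect_mask: bool = False,
) -> list[DirectRepeat]:
    """All same-strand half-site pairs whose spacer length is in ``spacings``.

    A half-site may participate in several repeats; mixed-strand pairs are
    never reported.
    """
    spacing_set = set(spacings)
    if any(s < 0 for s in spacing_set):
        raise ValueError("spacings must be non-negative")
    half_sites = find_half_sites(sequence, seq_id, respect_mask)
    by_strand: dict[str, list[HalfSiteMatch]] = {"+": [], "-": []}
    for h in half_sites:
        by_strand[h.strand].append(h)
    repeats: list[DirectRepeat] = []
    for strand, sites in by_strand.items():
        for i, left in enumerate(sites):
            for right in sites[i + 1:]:
                gap = right.pos - left.pos - HALF_SITE_LEN
                if gap > max(spacing_set, default=-1):
                    break
                if gap in spacing_set:
                    # minus-strand 5'->3' order is right-to-left on the
                    # forward sequence
                    first, second = (left, right) if strand == "+" else (right, left)
                    repeats.append(DirectRepeat(seq_id, first, second, gap, strand))
    repeats.sort(key=lambda d: (d.start, d.end, d.strand))
    return repeats


@dataclass(frozen=True)
class GeneDrHit:
    gene_id: str
    repeat: DirectRepeat


def scan_gene_regions(
    sequences: Mapping[str, str],
    regions: Sequence[GeneRegion],
    flank: int = 10_000,
    spacings: Iterable[int] = range(11),
    tss_only: bool = False,
    respect_mask: bool = False,
) -> tuple[list[GeneDrHit], pd.DataFrame, list[str]]:
    """Scan each gene's flanked window for direct repeats.

    With ``tss_only`` the window is centered on the transcription start site
    (strand-aware) instead of spanning the gene limits.  Returns per-gene
    hits with forward-sequence coordinates, a per-spacing summary with the
    total repeat count and the fraction of genes carrying at least one
    repeat of that spacing, and the list of skipped gene ids (no sequence).
    """
    spacings = sorted(set(spacings))
    hits: list[GeneDrHit] = []
    genes_with: dict[int, set[str]] = {s: set() for s in spacings}
    skipped: list[str] = []
    n_genes = 0
    for region in regions:
        seq = sequences.get(region.seq_id)
        if seq is None:
            logger.warning("gene %s: no sequence %r, skipped", region.gene_id, region.seq_id)
            skipped.append(region.gene_id)
            continue
        n_genes += 1
        if tss_only:
            tss = region.start if region.strand == "+" else region.end - 1
            lo, hi = tss - flank, tss + 1 + flank
        else:
            lo, hi = region.start - flank, region.end + flank
        lo, hi = max(0, lo), min(len(seq), hi)
        window = seq[lo:hi]
        for dr in find_direct_repeats(window, spacings, region.seq_id, respect_mask):
            shifted = DirectRepeat(
                dr.seq_id,
                HalfSiteMatch(dr.seq_id, dr.first.pos + lo, dr.first.strand),
                HalfSiteMatch(dr.seq_id, dr.second.pos + lo, dr.second.strand),
                dr.spacing,
                dr.strand,
            )
            hits.append(GeneDrHit(region.gene_id, shifted))
            genes_with[dr.spacing].add(region.gene_id)
    summary = pd.DataFrame({
        "spacing": spacings,
        "n_repeats": [sum(1 for h in hits if h.repeat.spacing == s) for s in spacings],
        "n_genes_with_repeat": [len(genes_with[s]) for s in spacings],
        "fraction_genes_with_repeat": [
            (len(genes_with[s]) / n_genes if n_genes else 0.0) for s in spacings
        ],
    })
    return hits, summary, skipped


def hits_to_frame(hits: Iterable[GeneDrHit]) -> pd.DataFrame:
    """BED-like table of repeats: seq_id, start, end, gene_id, spacing, strand."""
    return pd.DataFrame(
        [
            {
                "seq_id": h.repeat.seq_id,
                "start": h.repeat.start,
                "end": h.repeat.end,
                "gene_id": h.gene_id,
                "spacing": h.repeat.spacing,
                "strand": h.repeat.strand,
            }
            for h in hits
        ],
        columns=["seq_id", "start", "end", "gene_id", "spacing", "strand"],
    )
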