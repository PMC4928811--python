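"""In-silico protease digestion, detectable-peptide coverage and site embedment.

The digestion model is cleavage-rule based: an enzyme is a set of residues
and a terminus.  A C-terminal enzyme cuts the backbone after each matching
residue (trypsin after K/R); an N-terminal enzyme cuts before it (thermolysin
before V/A/M/I/L/F in its classical description).  Peptides with up to
``max_missed`` internal uncut sites are enumerated.  A peptide is
"detectable" when its length and monoisotopic mass both fall inside the
configured acquisition ranges; sequence coverage is the fraction of residues
contained in at least one detectable peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pyteomics import mass as _ptm_mass

from .tables_io import DigestParamsConfig, ProteinRecord

PHOSPHO_MASS = 79.96633  # monoisotopic HPO3, Da
WATER_MASS = 18.01056

#: Built-in cleavage rules: residue set and cut terminus.
ENZYMES: dict[str, tuple[frozenset[str], str]] = {
    "trypsin_lysC": (frozenset("KR"), "C"),
    "chymotrypsin": (frozenset("FWYL"), "C"),
    "thermolysin": (frozenset("VAMILF"), "N"),
}


@dataclass(frozen=True)
class DigestParams:
    """Cleavage rule plus detectability windows.

    ``detect_len`` and ``detect_mass`` are inclusive ranges; either bound may
    be ``None`` for no limit.
    """

    enzyme: str = "trypsin_lysC"
    cleavage_residues: frozenset[str] = frozenset()
    terminus: str = "C"
    max_missed: int = 2
    detect_len: tuple[int | None, int | None] = (7, 35)
    detect_mass: tuple[float | None, float | None] = (500.0, 5000.0)

    def __post_init__(self) -> None:
        if self.enzyme in ENZYMES and not self.cleavage_residues:
            residues, term = ENZYMES[self.enzyme]
            object.__setattr__(self, "cleavage_residues", residues)
            object.__setattr__(self, "terminus", term)
        if not self.cleavage_residues:
            raise ValueError(f"no cleavage residues for enzyme {self.enzyme!r}")
        if self.terminus not in ("C", "N"):
            raise ValueError("terminus must be 'C' or 'N'")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        for lo, hi in (self.detect_len, self.detect_mass):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError("degenerate detect range")

    @classmethod
    def from_config(cls, cfg: DigestParamsConfig) -> "DigestParams":
        return cls(
            enzyme=cfg.enzyme,
            max_missed=cfg.max_missed,
            detect_len=(cfg.min_len, cfg.max_len),
            detect_mass=(cfg.min_mass, cfg.max_mass),
        )


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int  # 0-based half-open protein coordinates
    end: int
    missed: int
    mass: float  # monoisotopic, Da; NaN when the sequence contains 'X'


def peptide_mass(sequence: str, n_phospho: int = 0) -> float:
    """Monoisotopic peptide mass in Da: residues + water + n_phospho * HPO3.

    Raises ``ValueError`` for an empty sequence or a non-standard residue.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = 0.0
    for aa in sequence:
        try:
            total += _ptm_mass.std_aa_mass[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in {sequence!r}") from None
    return total + WATER_MASS + n_phospho * PHOSPHO_MASS


def _cut_points(sequence: str, params: DigestParams) -> list[int]:
    """Internal cut positions (between residues i-1 and i), strictly inside."""
    cuts = []
    for i in range(1, len(sequence)):
        probe = sequence[i - 1] if params.terminus == "C" else sequence[i]
        if probe in params.cleavage_residues:  # 'X' is never in a residue set
            cuts.append(i)
    return cuts


def digest(protein: ProteinRecord, params: DigestParams) -> list[DigestPeptide]:
    """Enumerate digestion peptides with 0..max_missed missed cleavages.

    Ordered by (start, end).  An uncleavable protein yields itself.
    """
    seq = protein.sequence
    bounds = [0] + _cut_points(seq, params) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            pep = seq[start:end]
            m = peptide_mass(pep) if "X" not in pep else math.nan
            peptides.append(DigestPeptide(pep, start, end, missed=j - i - 1, mass=m))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def is_detectable(pep: DigestPeptide, params: DigestParams) -> bool:
    lo, hi = params.detect_len
    if lo is not None and len(pep.sequence) < lo:
        return False
    if hi is not None and len(pep.sequence) > hi:
        return False
    mlo, mhi = params.detect_mass
    if mlo is not None or mhi is not None:
        if math.isnan(pep.mass):  # 'X' residue: mass undefined, fails a mass window
            return False
        if mlo is not None and pep.mass < mlo:
            return False
        if mhi is not None and pep.mass > mhi:
            return False
    return True


def coverage(protein: ProteinRecord, params: DigestParams) -> tuple[float, list[bool]]:
    """Fraction of residues inside at least one detectable peptide, plus the map."""
    covered = [False] * len(protein.sequence)
    for pep in digest(protein, params):
        if is_detectable(pep, params):
            for i in range(pep.start, pep.end):
                covered[i] = True
    return sum(covered) / len(covered), covered


def site_embedded(protein: ProteinRecord, site_position: int, params: DigestParams) -> bool:
    """Whether a 1-based site falls inside some detectable digestion peptide."""
    if not (1 <= site_position <= len(protein.sequence)):
        raise ValueError(
            f"site {site_position} outside protein of length {len(protein.sequence)}"
        )
    _, covered = coverage(protein, params)
    return covered[site_position - 1]
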