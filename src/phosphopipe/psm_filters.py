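"""Confidence filtering of PSM tables and protein / phosphoprotein calling.

Two confidence paths are supported, mirroring common search-engine practice:

* the FDR path keeps rows whose upstream 1% target–decoy FDR flag is set;
* the score path applies a per-charge minimum score (used when the dataset
  is too small for FDR estimation, as for immunoprecipitation runs).

Both paths additionally require rank 1.  Rejections are tallied under
exactly one reason, rank being checked first, so the tally is reproducible.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .tables_io import AMBIGUOUS, PhosphoSite, PsmRecord, RunConfig

SampleKey = tuple[str, str, str, str]  # (cell_line, condition, replicate, fraction)

REASON_RANK = "rank"
REASON_FDR = "fdr"
REASON_SCORE = "score"


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for PSM confidence filtering and protein calling."""

    score_by_charge: Mapping[int, float] = None  # type: ignore[assignment]
    use_fdr_flag: bool = True
    max_rank: int = 1
    min_localization: float = 0.99
    min_peptides_per_protein: int = 2
    min_phosphopeptides: int = 1

    def __post_init__(self) -> None:
        if self.score_by_charge is None:
            object.__setattr__(self, "score_by_charge", {1: 1.5, 2: 2.5, 3: 3.0, 4: 3.2})
        if not (0.0 < self.min_localization <= 1.0):
            raise ValueError("min_localization must be in (0, 1]")
        if self.max_rank < 1 or self.min_peptides_per_protein < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "FilterCriteria":
        return cls(
            score_by_charge=dict(cfg.score_by_charge),
            use_fdr_flag=cfg.use_fdr_flag,
            max_rank=cfg.max_rank,
            min_localization=cfg.min_localization,
            min_peptides_per_protein=cfg.min_peptides_per_protein,
            min_phosphopeptides=cfg.min_phosphopeptides,
        )

    def score_threshold(self, charge: int) -> float:
        if charge < 1:
            raise ValueError(f"charge must be >= 1, got {charge}")
        if charge in self.score_by_charge:
            return self.score_by_charge[charge]
        return self.score_by_charge[max(self.score_by_charge)]


def filter_psms(
    psms: Iterable[PsmRecord], criteria: FilterCriteria
) -> tuple[list[PsmRecord], Counter]:
    """Apply rank and confidence filters; return kept rows and a rejection tally.

    Every input row is either kept or counted under exactly one rejection
    reason (``rank`` before ``fdr``/``score``), so kept + rejected equals the
    input count.
    """
    kept: list[PsmRecord] = []
    tally: Counter = Counter()
    for psm in psms:
        if psm.charge < 1:
            raise ValueError(f"charge must be >= 1, got {psm.charge}")
        if psm.rank > criteria.max_rank:
            tally[REASON_RANK] += 1
        elif criteria.use_fdr_flag:
            if psm.fdr_pass:
                kept.append(psm)
            else:
                tally[REASON_FDR] += 1
        elif psm.score >= criteria.score_threshold(psm.charge):
            kept.append(psm)
        else:
            tally[REASON_SCORE] += 1
    return kept, tally


def localize_sites(psm: PsmRecord, min_localization: float = 0.99) -> list[PhosphoSite]:
    """Map a PSM's phospho events to protein-coordinate phosphosites.

    The reported protein position is 1-based: peptide offset (0-based) plus
    the 1-based position within the peptide.  Events below the localization
    threshold keep their position but carry ``residue="ambiguous"``.
    """
    sites = []
    for sp in psm.site_probs:
        residue = sp.residue if sp.probability >= min_localization else AMBIGUOUS
        sites.append(
            PhosphoSite(
                accession=psm.accession,
                position=psm.start + sp.position,
                residue=residue,
                probability=sp.probability,
            )
        )
    return sites


def group_by_sample(psms: Iterable[PsmRecord]) -> dict[SampleKey, list[PsmRecord]]:
    groups: dict[SampleKey, list[PsmRecord]] = defaultdict(list)
    for psm in psms:
        groups[psm.sample].append(psm)
    return dict(groups)


def call_proteins(
    psms: Iterable[PsmRecord], min_peptides_per_protein: int = 2
) -> dict[SampleKey, set[str]]:
    """Per sample, the proteins backed by >= N distinct peptide sequences.

    Distinctness is by bare peptide sequence; modification state is ignored.
    """
    called: dict[SampleKey, set[str]] = {}
    for sample, rows in group_by_sample(psms).items():
        peptides_by_protein: dict[str, set[str]] = defaultdict(set)
        for psm in rows:
            peptides_by_protein[psm.accession].add(psm.peptide)
        called[sample] = {
            acc for acc, peps in peptides_by_protein.items()
            if len(peps) >= min_peptides_per_protein
        }
    return called


def call_phosphoproteins(
    called: Mapping[SampleKey, set[str]],
    psms: Iterable[PsmRecord],
    min_phosphopeptides: int = 1,
) -> dict[SampleKey, set[str]]:
    """Per sample, the called proteins carrying >= N phosphopeptides.

    Phosphopeptides on proteins outside the called set are dropped: the
    phosphoprotein set is always a subset of the called-protein set.
    """
    phospho: dict[SampleKey, set[str]] = {sample: set() for sample in called}
    counts: dict[SampleKey, Counter] = defaultdict(Counter)
    for psm in psms:
        if psm.n_phospho >= 1:
            counts[psm.sample][psm.accession] += 1
    for sample, base in called.items():
        phospho[sample] = {
            acc for acc in base if counts[sample][acc] >= min_phosphopeptides
        }
    return phospho
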