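"""Replicate/condition/cell-line set algebra and RA-response labeling.

The comparison unit is the consensus set: proteins identified in both
replicate experiments and in both the vehicle- and RA-treated extracts of a
cell line/fraction.  Phosphoprotein consensus is computed per condition
(intersection over replicates) and then crossed with the all-condition
consensus totals, so condition-specific phosphorylation survives the
crossing and can be labeled as vehicle-only (−), RA-only (+) or both (±).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, TypeVar

T = TypeVar("T", bound=Hashable)

LABEL_VEHICLE_ONLY = "-"
LABEL_RA_ONLY = "+"
LABEL_BOTH = "±"  # ±


@dataclass(frozen=True)
class VennCounts:
    only_a: int
    both: int
    only_b: int
    label_a: str = "A"
    label_b: str = "B"

    @property
    def size_a(self) -> int:
        return self.only_a + self.both

    @property
    def size_b(self) -> int:
        return self.only_b + self.both


def venn_counts(set_a: set, set_b: set, label_a: str = "A", label_b: str = "B") -> VennCounts:
    both = set_a & set_b
    return VennCounts(len(set_a - both), len(both), len(set_b - both), label_a, label_b)


def replicate_consensus(sets: Mapping[str, set[T]]) -> set[T]:
    """Intersection over labeled sets (e.g. {R1, R2} x {vehicle, RA}).

    Raises if any set is missing (None), naming the label.
    """
    if not sets:
        return set()
    for label, s in sets.items():
        if s is None:
            raise ValueError(f"missing set for label {label!r}")
    out: set[T] | None = None
    for s in sets.values():
        out = set(s) if out is None else out & s
    return out  # type: ignore[return-value]


def phospho_consensus(
    phospho_by_replicate: Mapping[str, set[T]], consensus_totals: set[T]
) -> set[T]:
    """Phosphoproteins seen in every replicate, crossed with consensus totals."""
    return replicate_consensus(phospho_by_replicate) & consensus_totals


def ra_response_class(
    phospho_vehicle: set[T], phospho_ra: set[T]
) -> dict[T, str]:
    """Label each phosphoprotein −, + or ± by where it was observed."""
    labels: dict[T, str] = {}
    for p in phospho_vehicle | phospho_ra:
        in_v, in_r = p in phospho_vehicle, p in phospho_ra
        labels[p] = LABEL_BOTH if (in_v and in_r) else (LABEL_VEHICLE_ONLY if in_v else LABEL_RA_ONLY)
    return labels


def phospho_fraction(n_phospho: int, n_total: int) -> int:
    """Percent of proteins that are phosphorylated, rounded half away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_phospho <= n_total):
        raise ValueError("need 0 <= n_phospho <= n_total")
    return int(math.floor(100.0 * n_phospho / n_total + 0.5))


@dataclass(frozen=True)
class CellLineFractionSummary:
    """Consensus sets and RA-response labels for one cell line and fraction."""

    cell_line: str
    fraction: str
    consensus_totals: frozenset
    phospho_vehicle: frozenset
    phospho_ra: frozenset
    response_labels: Mapping[str, str]

    @property
    def phosphoproteins(self) -> frozenset:
        return self.phospho_vehicle | self.phospho_ra

    @property
    def percent_phosphorylated_vehicle(self) -> int:
        return phospho_fraction(len(self.phospho_vehicle), len(self.consensus_totals))


def summarize_cell_line_fraction(
    called: Mapping[tuple[str, str, str, str], set[str]],
    phospho: Mapping[tuple[str, str, str, str], set[str]],
    cell_line: str,
    fraction: str,
    replicates: Iterable[str] = ("R1", "R2"),
    conditions: tuple[str, str] = ("vehicle", "RA"),
) -> CellLineFractionSummary:
    """Run the full consensus workflow for one cell line and fraction.

    ``called``/``phospho`` are keyed by (cell_line, condition, replicate,
    fraction) as produced by the PSM-calling stage.
    """
    replicates = list(replicates)

    def get(mapping, condition, replicate):
        key = (cell_line, condition, replicate, fraction)
        if key not in mapping:
            raise ValueError(f"missing sample {key!r}")
        return mapping[key]

    totals = replicate_consensus({
        f"{cond}/{rep}": get(called, cond, rep)
        for cond in conditions for rep in replicates
    })
    per_condition = {
        cond: phospho_consensus(
            {rep: get(phospho, cond, rep) for rep in replicates}, totals
        )
        for cond in conditions
    }
    vehicle_set, ra_set = per_condition[conditions[0]], per_condition[conditions[1]]
    return CellLineFractionSummary(
        cell_line=cell_line,
        fraction=fraction,
        consensus_totals=frozenset(totals),
        phospho_vehicle=frozenset(vehicle_set),
        phospho_ra=frozenset(ra_set),
        response_labels=ra_response_class(vehicle_set, ra_set),
    )
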