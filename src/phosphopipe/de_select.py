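"""Regulated-gene selection and cross-cell-line regulation comparison.

Genes are called regulated when |log2 fold-change| > 1 and BH-adjusted
p-value < 0.05 (both strict, both configurable).  The two cell lines'
up/down sets are then partitioned into line-exclusive and shared
(concordant/discordant) groups with percentages relative to each line's own
regulated total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .consensus_compare import phospho_fraction
from .tables_io import DeGeneRow


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fill_padj(rows: Iterable[DeGeneRow]) -> list[DeGeneRow]:
    """Return rows with ``padj`` filled by BH adjustment where absent."""
    rows = list(rows)
    if all(r.padj is not None for r in rows):
        return rows
    adjusted = bh_adjust([r.pvalue for r in rows])
    return [
        DeGeneRow(r.gene_id, r.log2fc, r.pvalue, float(a), r.status)
        for r, a in zip(rows, adjusted)
    ]


def select_regulated(
    de_table: Iterable[DeGeneRow],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets under strict thresholds."""
    rows = fill_padj(de_table)
    up = {r.gene_id for r in rows if r.log2fc > lfc_threshold and r.padj < alpha}
    down = {r.gene_id for r in rows if r.log2fc < -lfc_threshold and r.padj < alpha}
    return up, down


def annotate_status(
    de_table: Iterable[DeGeneRow],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> list[DeGeneRow]:
    """Rows with ``status`` set to up/down/ns from the thresholds."""
    rows = fill_padj(de_table)
    up, down = select_regulated(rows, lfc_threshold, alpha)
    return [
        DeGeneRow(
            r.gene_id, r.log2fc, r.pvalue, r.padj,
            "up" if r.gene_id in up else ("down" if r.gene_id in down else "ns"),
        )
        for r in rows
    ]


@dataclass(frozen=True)
class RegulationComparison:
    """Partition of two cell lines' regulated genes.

    The six sets partition the union of all regulated genes; percentages are
    of each line's own regulated-gene count, rounded to integers.
    """

    a_only_up: frozenset[str]
    a_only_down: frozenset[str]
    b_only_up: frozenset[str]
    b_only_down: frozenset[str]
    shared_concordant: frozenset[str]
    shared_discordant: frozenset[str]
    label_a: str = "A"
    label_b: str = "B"

    @property
    def a_regulated(self) -> int:
        return (len(self.a_only_up) + len(self.a_only_down)
                + len(self.shared_concordant) + len(self.shared_discordant))

    @property
    def b_regulated(self) -> int:
        return (len(self.b_only_up) + len(self.b_only_down)
                + len(self.shared_concordant) + len(self.shared_discordant))

    @property
    def pct_a_exclusive(self) -> int:
        """Percent of line A's regulated genes not regulated in line B."""
        return phospho_fraction(len(self.a_only_up) + len(self.a_only_down), self.a_regulated)

    @property
    def pct_b_exclusive(self) -> int:
        return phospho_fraction(len(self.b_only_up) + len(self.b_only_down), self.b_regulated)


def compare_regulation(
    a_up: set[str], a_down: set[str], b_up: set[str], b_down: set[str],
    label_a: str = "A", label_b: str = "B",
) -> RegulationComparison:
    if a_up & a_down or b_up & b_down:
        raise ValueError("a gene cannot be both up- and down-regulated in one line")
    a_reg, b_reg = a_up | a_down, b_up | b_down
    shared = a_reg & b_reg
    concordant = (a_up & b_up) | (a_down & b_down)
    return RegulationComparison(
        a_only_up=frozenset(a_up - b_reg),
        a_only_down=frozenset(a_down - b_reg),
        b_only_up=frozenset(b_up - a_reg),
        b_only_down=frozenset(b_down - a_reg),
        shared_concordant=frozenset(concordant),
        shared_discordant=frozenset(shared - concordant),
        label_a=label_a,
        label_b=label_b,
    )
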