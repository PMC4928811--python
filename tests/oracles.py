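"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: cut points are found by
direct residue inspection, motif matches by per-position comparison against
explicit base sets, and BH adjustment by a literal transcription of the
step-up formula.
"""

from __future__ import annotations

import numpy as np


def brute_force_digest(sequence: str, residues: set[str], terminus: str,
                       max_missed: int) -> set[tuple[str, int, int, int]]:
    """All digestion peptides as (sequence, start, end, missed) tuples."""
    cuts = []
    for i in range(1, len(sequence)):
        if terminus == "C" and sequence[i - 1] in residues:
            cuts.append(i)
        elif terminus == "N" and sequence[i] in residues:
            cuts.append(i)
    bounds = [0] + cuts + [len(sequence)]
    out = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            missed = b - a - 1
            if missed <= max_missed:
                out.add((sequence[bounds[a]:bounds[b]], bounds[a], bounds[b], missed))
    return out


_IUPAC = {"R": "AG", "G": "G", "K": "GT", "T": "T", "S": "CG", "A": "A"}
_FORWARD = [set(_IUPAC[c]) for c in "RGKTSA"]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# a minus-strand half-site: the forward hexamer whose reverse complement
# reads RGKTSA, i.e. position i must complement the pattern at 5 - i
_REVERSE = [set(_COMP[b] for b in _FORWARD[5 - i]) for i in range(6)]


def naive_half_sites(sequence: str) -> set[tuple[int, str]]:
    """(pos, strand) of every half-site, by per-position base comparison."""
    hits = set()
    for i in range(len(sequence) - 5):
        window = sequence[i:i + 6]
        if all(b in allowed for b, allowed in zip(window, _FORWARD)):
            hits.add((i, "+"))
        if all(b in allowed for b, allowed in zip(window, _REVERSE)):
            hits.add((i, "-"))
    return hits


def naive_direct_repeats(sequence: str, spacings) -> set[tuple[int, int, int, str]]:
    """(left_pos, right_pos, spacing, strand) for every same-strand pair."""
    spacings = set(spacings)
    sites = naive_half_sites(sequence)
    out = set()
    for pos_a, strand_a in sites:
        for pos_b, strand_b in sites:
            if strand_a != strand_b or pos_b <= pos_a:
                continue
            gap = pos_b - pos_a - 6
            if gap in spacings:
                out.add((pos_a, pos_b, gap, strand_a))
    return out


def literal_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up, transcribed directly from the formula."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted_sorted[rank_from_top - 1] = running_min
    out = np.empty(m)
    for rank, i in enumerate(order):
        out[i] = min(adjusted_sorted[rank], 1.0)
    return out
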