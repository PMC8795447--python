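"""Phospho-motif scanning and positional association analysis.

Receptor intracellular segments (third intracellular loop, C-terminal tail)
are scanned for putative Ser/Thr phosphorylation sites and for four motif
grammars written over a two-letter alphabet: ``P`` matches a phosphorylatable
or phospho-mimicking residue {S, T, D, E}; ``X`` matches any residue.  The
grammars are the clusters PPP and PXPP and the patterns PXPXXP and PXXPXXP.

Each match is summarised by its relative position within the segment
(0 = N-terminal end, 1 = C-terminal end) and dichotomised at the 0.25/0.75
breakpoints into central vs peripheral.  Association between position
category and kinase-selectivity group is tested with Fisher's exact test on
the pooled 2×2 occurrence table.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import (
    AssociationResult,
    ConfigurationError,
    DataError,
    MotifHit,
    STANDARD_AA,
    SegmentRecord,
)

__all__ = [
    "GRAMMARS",
    "P_RESIDUES",
    "scan_sites",
    "scan_pattern",
    "scan_motifs",
    "relative_position",
    "categorize",
    "scan_segment",
    "build_contingency",
    "fisher_exact",
    "group_summary",
]

P_RESIDUES = frozenset("STDE")
ST_RESIDUES = frozenset("ST")

GRAMMARS = {
    "PPP": "PPP",
    "PXPP": "PXPP",
    "PXPXXP": "PXPXXP",
    "PXXPXXP": "PXXPXXP",
}


def _check_sequence(seq: str, who: str = "sequence") -> None:
    for i, aa in enumerate(seq):
        if aa not in STANDARD_AA:
            raise DataError(f"{who}: invalid residue {aa!r} at position {i}")


def scan_sites(segment: SegmentRecord | str) -> list[int]:
    """0-based positions of putative phosphorylation sites (Ser or Thr only).

    Asp/Glu can stand in for a phosphorylated residue inside a motif but are
    not themselves sites.
    """
    seq = segment if isinstance(segment, str) else segment.sequence
    _check_sequence(seq)
    return [i for i, aa in enumerate(seq) if aa in ST_RESIDUES]


def scan_pattern(seq: str, pattern: str) -> list[int]:
    """All 0-based start indices where ``pattern`` matches (overlaps included)."""
    L, m = len(seq), len(pattern)
    hits = []
    for s in range(L - m + 1):
        ok = True
        for k, slot in enumerate(pattern):
            if slot == "P" and seq[s + k] not in P_RESIDUES:
                ok = False
                break
        if ok:
            hits.append(s)
    return hits


def _greedy_nonoverlapping(starts: list[int], m: int) -> list[int]:
    out: list[int] = []
    for s in starts:
        if not out or s >= out[-1] + m:
            out.append(s)
    return out


def scan_motifs(
    segment: SegmentRecord | str,
    motif: str,
    overlapping: bool = True,
) -> list[int]:
    """Start indices of one grammar's matches in a segment.

    With ``overlapping=False`` a left-to-right greedy non-overlapping subset
    is returned instead (sensitivity-analysis mode).
    """
    if motif not in GRAMMARS:
        raise ConfigurationError(f"unknown motif grammar {motif!r}")
    seq = segment if isinstance(segment, str) else segment.sequence
    _check_sequence(seq)
    pattern = GRAMMARS[motif]
    if len(seq) < len(pattern):
        return []
    starts = scan_pattern(seq, pattern)
    if not overlapping:
        starts = _greedy_nonoverlapping(starts, len(pattern))
    return starts


def relative_position(
    start: int, segment_len: int, one_based: bool = False
) -> float:
    """Relative position of a match within its segment, in [0, 1].

    Default convention: 0-based index of the first matched residue divided by
    (L − 1), so 0 is the segment's N-terminal end and 1 its C-terminal end.
    ``one_based`` switches to (index + 1)/L.
    """
    if segment_len < 1:
        raise ValueError("segment length must be >= 1")
    if not (0 <= start < segment_len):
        raise ValueError(f"start {start} out of range for length {segment_len}")
    if one_based:
        return (start + 1) / segment_len
    if segment_len == 1:
        return 0.0
    return start / (segment_len - 1)


def categorize(
    rel_pos: float,
    lower: float = 0.25,
    upper: float = 0.75,
    boundary_central: bool = True,
) -> str:
    """Dichotomise a relative position into central vs peripheral.

    Positions between the breakpoints are central; the breakpoints themselves
    are assigned central by default (configurable).
    """
    if not (0.0 <= rel_pos <= 1.0):
        raise ValueError(f"relative position {rel_pos} outside [0, 1]")
    if boundary_central:
        return "central" if lower <= rel_pos <= upper else "peripheral"
    return "central" if lower < rel_pos < upper else "peripheral"


def scan_segment(
    segment: SegmentRecord,
    motif: str,
    overlapping: bool = True,
    one_based: bool = False,
    boundary_central: bool = True,
) -> list[MotifHit]:
    """Full per-segment scan: matches with relative positions and categories."""
    hits = []
    L = len(segment.sequence)
    for start in scan_motifs(segment, motif, overlapping=overlapping):
        rp = relative_position(start, L, one_based=one_based)
        hits.append(
            MotifHit(
                receptor_id=segment.receptor_id,
                segment_kind=segment.segment_kind,
                motif=motif,
                start=start,
                relative_position=rp,
                category=categorize(rp, boundary_central=boundary_central),
                group_label=segment.group_label,
                receptor_class=segment.receptor_class,
            )
        )
    return hits


def build_contingency(
    hits: Iterable[MotifHit],
    motif: str,
    group_pair: tuple,
    by: str = "group_label",
) -> np.ndarray:
    """2×2 occurrence table: rows central/peripheral, columns the two groups.

    Units are motif occurrences pooled across the receptors of each group
    (the dot-plot granularity); ``by`` may alternatively be
    ``"receptor_class"`` to tabulate against the class A/B split.
    """
    table = np.zeros((2, 2), dtype=int)
    for h in hits:
        if h.motif != motif:
            continue
        key = getattr(h, by)
        if key not in group_pair:
            continue
        row = 0 if h.category == "central" else 1
        col = group_pair.index(key)
        table[row, col] += 1
    if table.sum() == 0:
        raise DataError("empty contingency table: no motif occurrences in either group")
    if (table.sum(axis=0) == 0).any():
        empty = group_pair[int(np.argmax(table.sum(axis=0) == 0))]
        raise DataError(f"no motif occurrences in group {empty!r}")
    return table


def fisher_exact(table: Sequence[Sequence[int]]) -> AssociationResult:
    """Two-sided Fisher exact test on a 2×2 table.

    Conditional on fixed margins, the two-sided p-value sums the
    hypergeometric point probabilities of every table whose probability does
    not exceed the observed table's (relative tie tolerance 1e-7).  The odds
    ratio is the sample odds ratio a·d / b·c (infinite when b·c = 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DataError("Fisher test requires a 2×2 table")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise DataError("contingency entries must be non-negative integers")
    a, b, c, d = (int(x) for x in t.ravel())
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or min(r1, c1) < 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        # a degenerate margin: only one table is possible
        if n == 0:
            raise DataError("empty contingency table")
        p = 1.0
    else:
        kmin = max(0, r1 + c1 - n)
        kmax = min(r1, c1)
        support = np.arange(kmin, kmax + 1)
        pmf = hypergeom.pmf(support, n, r1, c1)
        p_obs = hypergeom.pmf(a, n, r1, c1)
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
        p = min(1.0, p)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return AssociationResult(
        contingency=((a, b), (c, d)), odds_ratio=odds, p_two_sided=p
    )


def group_summary(hits: Iterable[MotifHit], segments: Iterable[SegmentRecord]):
    """Plot-ready summaries: per-group/per-class abundance and positions.

    Returns a dict with:

    * ``counts`` — per (motif, group): receptor-segment count, occurrence
      count, occurrences per segment;
    * ``positions`` — per (motif, group): relative-position list and median;
    * ``class_pies`` — fraction of each selectivity group within receptor
      class A and B.
    """
    hits = list(hits)
    segments = list(segments)
    seg_by_group: dict = {}
    for s in segments:
        seg_by_group.setdefault(s.group_label, set()).add((s.receptor_id, s.segment_kind))
    counts_rows, pos_rows = [], []
    keys = sorted({(h.motif, h.group_label) for h in hits})
    for motif, group in keys:
        sel = [h for h in hits if h.motif == motif and h.group_label == group]
        n_segments = len(seg_by_group.get(group, ())) or 1
        positions = sorted(h.relative_position for h in sel)
        counts_rows.append(
            {
                "motif": motif,
                "group": group,
                "n_segments": len(seg_by_group.get(group, ())),
                "n_occurrences": len(sel),
                "occurrences_per_segment": len(sel) / n_segments,
            }
        )
        pos_rows.append(
            {
                "motif": motif,
                "group": group,
                "positions": positions,
                "median_position": float(np.median(positions)) if positions else float("nan"),
            }
        )
    class_rows = []
    for cls in sorted({s.receptor_class for s in segments}):
        members = [s for s in segments if s.receptor_class == cls]
        total = len(members)
        for group in sorted({s.group_label for s in segments}):
            k = sum(1 for s in members if s.group_label == group)
            class_rows.append(
                {
                    "receptor_class": cls,
                    "group": group,
                    "n": k,
                    "fraction": k / total if total else float("nan"),
                }
            )
    return {
        "counts": pd.DataFrame(counts_rows),
        "positions": pd.DataFrame(pos_rows),
        "class_pies": pd.DataFrame(class_rows),
    }
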