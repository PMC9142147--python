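"""Genomic intervals and overlap queries.

All coordinates are 0-based half-open throughout the package; GTF input is
converted on read. Strand is one of ``+``, ``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome name; must exist in whatever genome the caller declares.
    start, end : int
        0-based half-open coordinates, ``start < end``.
    strand : str
        ``+``, ``-`` or ``.``.
    id : str
        Free-form identifier (BED name column).
    score : float
        BED score column; carries RPK for decoded segments.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor of the arithmetic mean: deterministic for even lengths
        return (self.start + self.end) // 2

    def replace(self, **kw) -> "GenomicInterval":
        return replace(self, **kw)


def gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Distance between two intervals: 0 when they overlap or abut,
    otherwise the non-negative separation start2 - end1."""
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_frac_of_a: float = 0.0,
    max_gap: int = 0,
    stranded: bool = False,
) -> list[tuple[int, int]]:
    """Report pairs (i, j) with overlap(a_i, b_j) >= min_frac_of_a * len(a_i)
    and gap(a_i, b_j) <= max_gap.

    The fraction condition only bites when ``min_frac_of_a > 0``; with
    ``min_frac_of_a == 0`` any pair within ``max_gap`` qualifies (gap 0 means
    touching or overlapping). Strand-blind unless ``stranded``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if not a or not b:
        return []
    pairs: list[tuple[int, int]] = []
    # sweep per chromosome using sorted starts of b
    by_chrom: dict[str, list[int]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append(j)
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda j: b[j].start)
        starts = np.array([b[j].start for j in idx])
        ends = np.array([b[j].end for j in idx])
        for i, ai in enumerate(a):
            if ai.chrom != chrom:
                continue
            lo = ai.start - max_gap
            hi = ai.end + max_gap
            # candidates: b.start <= hi (sorted) and b.end >= lo (checked below)
            k_hi = int(np.searchsorted(starts, hi, side="right"))
            for k in np.nonzero(ends[:k_hi] >= lo)[0]:
                j = idx[int(k)]
                bj = b[j]
                if stranded and ai.strand != bj.strand:
                    continue
                ov = overlap_len(ai, bj)
                g = gap(ai, bj)
                if g > max_gap:
                    continue
                if min_frac_of_a > 0 and ov < min_frac_of_a * len(ai):
                    continue
                pairs.append((i, j))
    return sorted(pairs)


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0, stranded: bool = True
) -> list[GenomicInterval]:
    """Transitive single-linkage merge of intervals whose gap is <= max_gap.

    Merging is per chromosome (and per strand when ``stranded``); merged
    records span min(start)..max(end) and concatenate member ids with ','.
    Idempotent and order-independent.
    """
    if not intervals:
        return []
    keyed: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        keyed.setdefault(key, []).append(iv)
    out: list[GenomicInterval] = []
    for key, ivs in keyed.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        cur = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start - max(x.end for x in cur) <= max_gap:
                cur.append(iv)
            else:
                out.append(_merge_group(cur, stranded))
                cur = [iv]
        out.append(_merge_group(cur, stranded))
    out.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand))
    return out


def _merge_group(group: list[GenomicInterval], stranded: bool) -> GenomicInterval:
    ids = ",".join(sorted({g.id for g in group if g.id != "."})) or "."
    strands = {g.strand for g in group}
    strand = strands.pop() if len(strands) == 1 else "."
    return GenomicInterval(
        chrom=group[0].chrom,
        start=min(g.start for g in group),
        end=max(g.end for g in group),
        strand=strand,
        id=ids,
        score=float(sum(g.score for g in group)),
    )
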