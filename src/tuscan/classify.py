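"""Classification of decoded segments into the final TU annotation.

Segments are first matched to annotated protein-coding/lincRNA genes
(>=20% of the segment inside the gene body on the same strand, plus >=1 bp
exon overlap); all segments of one gene merge into a single TU. The rest
are ncRNAs: they are filtered for an open promoter (+-1 kb of TSS hitting
an accessibility peak), merged across 1-bin gaps, and sorted into uaRNA /
conRNA / asRNA / incRNA by the geometry of their TSS relative to the
nearest opposite-strand mRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, gap, merge_intervals, overlap_len
from .io import Gene

NCRNA_CLASSES = ("uaRNA", "conRNA", "asRNA", "incRNA")
TU_CLASSES = ("mRNA", "lincRNA") + NCRNA_CLASSES


@dataclass
class TranscriptionUnit:
    """A classified transcription unit.

    ``gene_id`` is set for mRNA/lincRNA only. ``tss`` follows the strand:
    start on + and end on -.
    """

    interval: GenomicInterval
    cls: str
    rpk: float
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in TU_CLASSES and self.cls != "ncRNA":
            raise ValueError(f"unknown TU class {self.cls!r}")
        if self.cls in ("mRNA", "lincRNA") and self.gene_id is None:
            raise ValueError("mRNA/lincRNA TU requires a gene_id")
        if self.cls in NCRNA_CLASSES and self.gene_id is not None:
            raise ValueError("ncRNA TU must not carry a gene_id")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end

    @property
    def id(self) -> str:
        return self.interval.id


def assign_gene_class(
    segments: list[GenomicInterval],
    genes: list[Gene],
    min_frac: float = 0.2,
) -> tuple[list[TranscriptionUnit], list[GenomicInterval]]:
    """Split segments into gene-linked TUs and candidate ncRNAs.

    A segment joins a gene when, on the same strand, at least ``min_frac``
    of its length lies within the gene body AND it overlaps an annotated
    exon. A segment qualifying for several genes goes to the one with the
    larger body overlap; ties break toward the gene with the nearer TSS,
    then the lower coordinate. All segments of one gene merge into a single
    TU spanning min(start)..max(end); segment RPKs combine length-weighted.
    """
    assigned: dict[str, list[GenomicInterval]] = {}
    ncrna: list[GenomicInterval] = []
    gene_by_id = {g.gene_id: g for g in genes}
    for seg in segments:
        best: tuple | None = None
        for g in genes:
            giv = g.interval
            if giv.chrom != seg.chrom or giv.strand != seg.strand:
                continue
            ov = overlap_len(seg, giv)
            if ov < min_frac * len(seg):
                continue
            if not any(overlap_len(seg, ex) > 0 for ex in g.exons):
                continue
            tss_dist = abs(((seg.start + seg.end) // 2) - g.tss)
            key = (-ov, tss_dist, giv.start)
            if best is None or key < best[0]:
                best = (key, g.gene_id)
        if best is None:
            ncrna.append(seg)
        else:
            assigned.setdefault(best[1], []).append(seg)

    tus: list[TranscriptionUnit] = []
    for gid, segs in assigned.items():
        g = gene_by_id[gid]
        start = min(s.start for s in segs)
        end = max(s.end for s in segs)
        length_kb = (end - start) / 1000.0
        # midpoint counts recovered from member RPKs, re-expressed over the span
        total_mid = sum(s.score * (len(s) / 1000.0) for s in segs)
        rpk = total_mid / length_kb
        cls = "lincRNA" if g.biotype == "lincRNA" else "mRNA"
        iv = GenomicInterval(
            segs[0].chrom, start, end, segs[0].strand, id=gid, score=round(rpk, 3)
        )
        tus.append(TranscriptionUnit(iv, cls, rpk, gene_id=gid))
    tus.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return tus, ncrna


def filter_by_open_promoter(
    tus: list[TranscriptionUnit],
    open_regions: list[GenomicInterval],
    promoter_halfwidth: int = 1000,
) -> list[TranscriptionUnit]:
    """Keep TUs whose promoter (TSS +- halfwidth, half-open) intersects at
    least one open-chromatin region by >= 1 bp. A region abutting the
    promoter edge does not count."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in open_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    kept = []
    for tu in tus:
        lo = max(0, tu.tss - promoter_halfwidth)
        hi = tu.tss + promoter_halfwidth
        regions = by_chrom.get(tu.interval.chrom, [])
        if any(min(hi, r.end) - max(lo, r.start) > 0 for r in regions):
            kept.append(tu)
    return kept


def threshold_from_openness(
    tus: list[TranscriptionUnit],
    open_regions: list[GenomicInterval],
    promoter_halfwidth: int = 1000,
) -> float:
    """Optimize the minimal-expression RPK cutoff from promoter openness,
    partitioning TUs into open- vs closed-promoter groups first (see
    :func:`youden_threshold` for the decision rule)."""
    open_rpks, closed_rpks = split_by_open_promoter(
        tus, open_regions, promoter_halfwidth
    )
    return youden_threshold(open_rpks, closed_rpks)


def youden_threshold(open_rpks: np.ndarray, closed_rpks: np.ndarray) -> float:
    """Optimize the minimal-expression RPK cutoff from promoter openness.

    Finds the threshold t maximizing Youden's J = P(open >= t) - P(closed
    >= t) on the log-RPK scale and returns the geometric midpoint of the
    optimal interval. With indistinguishable groups the common median is
    returned with a degeneracy warning.
    """
    open_rpks = np.asarray(open_rpks, dtype=float)
    closed_rpks = np.asarray(closed_rpks, dtype=float)
    if len(open_rpks) < 10 or len(closed_rpks) < 10:
        raise ValueError(
            "need >=10 TUs per openness group; use the fixed default threshold"
        )
    lo_ = np.log(open_rpks)
    lc = np.log(closed_rpks)
    values = np.unique(np.concatenate([lo_, lc]))
    if len(values) == 1:
        warnings.warn("degenerate RPK distributions: single value")
        return float(np.exp(values[0]))
    # candidate cuts between consecutive distinct values
    mids = (values[:-1] + values[1:]) / 2
    j = np.array(
        [np.mean(lo_ >= m) - np.mean(lc >= m) for m in mids]
    )
    if j.max() <= 0:
        warnings.warn("openness groups indistinguishable; returning common median")
        return float(np.median(np.concatenate([open_rpks, closed_rpks])))
    best = np.nonzero(np.isclose(j, j.max()))[0]
    # contiguous optimal runs: take the midpoint of the widest optimal interval
    k = best[np.argmax(values[best + 1] - values[best])]
    return float(np.exp((values[k] + values[k + 1]) / 2))


def split_by_open_promoter(
    tus: list[TranscriptionUnit],
    open_regions: list[GenomicInterval],
    promoter_halfwidth: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """RPK vectors of TUs with open vs closed promoters (threshold input)."""
    open_set = {
        id(t) for t in filter_by_open_promoter(tus, open_regions, promoter_halfwidth)
    }
    open_rpks = np.array([t.rpk for t in tus if id(t) in open_set])
    closed_rpks = np.array([t.rpk for t in tus if id(t) not in open_set])
    return open_rpks, closed_rpks


def merge_close_ncrna(
    ncrnas: list[GenomicInterval], max_gap: int = 200
) -> list[GenomicInterval]:
    """Transitively merge same-strand ncRNA segments with gap <= max_gap
    (one bin by default). Idempotent and order-independent."""
    merged = merge_intervals(ncrnas, max_gap=max_gap, stranded=True)
    out = []
    for i, iv in enumerate(merged):
        out.append(iv.replace(id=iv.id if iv.id != "." else f"ncRNA_{i:05d}"))
    return out


def classify_ncrna(
    ncrnas: list[GenomicInterval],
    mrna_tus: list[TranscriptionUnit],
    near: int = 1000,
) -> list[TranscriptionUnit]:
    """Sort ncRNAs into uaRNA / conRNA / asRNA / incRNA.

    Rules apply to ncRNAs on the opposite strand of an mRNA whose body,
    extended ``near`` bp upstream, contains the ncRNA TSS; the mRNA with the
    nearest TSS governs. With d the TSS-to-TSS offset in the sense gene's
    orientation (positive = downstream): d < -near or d >= near falls
    through, -near < d < 0 is uaRNA, 0 <= d < near is conRNA, d > near is
    asRNA. Everything else is incRNA.
    """
    out = []
    for nc in ncrnas:
        tss_nc = nc.start if nc.strand == "+" else nc.end
        cls = "incRNA"
        best_dist = None
        for m in mrna_tus:
            miv = m.interval
            if miv.chrom != nc.chrom or miv.strand == nc.strand or miv.strand == ".":
                continue
            if miv.strand == "+":
                in_scope = (miv.start - near) <= tss_nc < miv.end
                d = tss_nc - m.tss
            else:
                in_scope = miv.start < tss_nc <= (miv.end + near)
                d = m.tss - tss_nc
            if not in_scope:
                continue
            tss_dist = abs(tss_nc - m.tss)
            if best_dist is not None and tss_dist >= best_dist:
                continue
            best_dist = tss_dist
            if d > near:
                cls = "asRNA"
            elif -near < d < 0:
                cls = "uaRNA"
            elif 0 <= d < near:
                cls = "conRNA"
            else:  # d == near or d <= -near: outside the quoted strict bounds
                cls = "incRNA"
        rpk = nc.score
        out.append(TranscriptionUnit(nc, cls, rpk))
    return out
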