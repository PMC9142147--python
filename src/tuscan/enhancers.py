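"""Enhancer annotation from TF-occupancy peaks, accessibility and eRNAs.

Putative eRNAs are asRNA/incRNA TUs lying more than 1 kb from any
promoter-related TU (mRNA, uaRNA, conRNA), merged strand-blind within 1 kb.
TF peaks are then partitioned: peaks outside open chromatin are dropped
("closed"); open peaks within 1 kb of an eRNA are transcribed enhancers;
open peaks overlapping an mRNA TU are mRNA-associated; the remaining open
peaks are nontranscribed enhancers. Superenhancer (SE) membership is
annotated against a supplied SE interval set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .classify import TranscriptionUnit
from .intervals import GenomicInterval, gap, merge_intervals, overlap_len

CATEGORIES = ("transcribed", "mrna", "nontranscribed", "closed")

PROMOTER_CLASSES = ("mRNA", "uaRNA", "conRNA")
ERNA_SOURCE_CLASSES = ("asRNA", "incRNA")


@dataclass
class EnhancerLocus:
    """A merged putative-eRNA locus. ``members`` maps member TU id ->
    strand; the locus interval is strand-blind."""

    interval: GenomicInterval
    members: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.interval.id


@dataclass
class EnhancerSite:
    """A TF-occupancy peak annotated with openness, transcription and SE
    membership. ``sensitivity`` is filled by the kinetics module."""

    peak: GenomicInterval
    summit: int
    open: bool = False
    category: str = "closed"
    erna_ids: list[str] = field(default_factory=list)
    se_id: str | None = None
    sensitivity: str | None = None

    @property
    def transcribed(self) -> bool:
        return bool(self.erna_ids)

    @property
    def id(self) -> str:
        return self.peak.id


def call_putative_ernas(
    tus: list[TranscriptionUnit],
    promoter_distance: int = 1000,
    merge_gap: int = 1000,
) -> list[EnhancerLocus]:
    """Annotate putative eRNA loci from classified TUs.

    Start from asRNA and incRNA; drop any within ``promoter_distance`` bp
    (strand-blind edge-to-edge, <=) of an mRNA/uaRNA/conRNA TU; merge the
    survivors strand-blind within ``merge_gap``. Output is invariant to
    input order (loci are coordinate-sorted and renamed).
    """
    promoter_like = [t.interval for t in tus if t.cls in PROMOTER_CLASSES]
    candidates = [t for t in tus if t.cls in ERNA_SOURCE_CLASSES]
    survivors = []
    for t in candidates:
        too_close = any(
            p.chrom == t.interval.chrom and gap(t.interval, p) <= promoter_distance
            for p in promoter_like
        )
        if not too_close:
            survivors.append(t)
    strands = {t.id: t.interval.strand for t in survivors}
    merged = merge_intervals(
        [t.interval for t in survivors], max_gap=merge_gap, stranded=False
    )
    loci = []
    for i, iv in enumerate(merged):
        member_ids = [m for m in iv.id.split(",") if m != "."]
        locus_iv = iv.replace(id=f"eRNA_{i:05d}", strand=".")
        loci.append(
            EnhancerLocus(locus_iv, {m: strands.get(m, ".") for m in member_ids})
        )
    return loci


def classify_binding_sites(
    peaks: list[tuple[GenomicInterval, int | None]],
    open_regions: list[GenomicInterval],
    ernas: list[EnhancerLocus],
    mrna_tus: list[TranscriptionUnit],
    max_gap: int = 1000,
) -> list[EnhancerSite]:
    """Partition TF peaks into transcribed / mRNA / nontranscribed / closed.

    The partition is exhaustive and disjoint with precedence
    eRNA > mRNA > nontranscribed among open peaks. eRNA proximity is
    edge-to-edge (0 when overlapping) from the ChIP peak.
    """
    sites = []
    for peak, summit in peaks:
        if summit is None:
            warnings.warn(f"peak {peak.id} lacks a summit; using the midpoint")
            summit = peak.midpoint
        is_open = any(
            r.chrom == peak.chrom and overlap_len(peak, r) > 0 for r in open_regions
        )
        site = EnhancerSite(peak=peak, summit=summit, open=is_open)
        if not is_open:
            site.category = "closed"
            sites.append(site)
            continue
        linked = [
            e.id
            for e in ernas
            if e.interval.chrom == peak.chrom and gap(peak, e.interval) <= max_gap
        ]
        if linked:
            site.category = "transcribed"
            site.erna_ids = sorted(linked)
        elif any(
            t.interval.chrom == peak.chrom and overlap_len(peak, t.interval) > 0
            for t in mrna_tus
            if t.cls == "mRNA"
        ):
            site.category = "mrna"
        else:
            site.category = "nontranscribed"
        sites.append(site)
    return sites


def annotate_se(
    sites: list[EnhancerSite], se_intervals: list[GenomicInterval]
) -> pd.DataFrame:
    """Set ``se_id`` on sites overlapping an SE interval (>= 1 bp); sites
    outside SEs are typical enhancers (se_id None). Returns a per-SE summary
    with member counts by category."""
    rows = []
    for site in sites:
        site.se_id = None
        for se in se_intervals:
            if se.chrom == site.peak.chrom and overlap_len(site.peak, se) > 0:
                site.se_id = se.id
                break
    for se in se_intervals:
        members = [s for s in sites if s.se_id == se.id]
        rows.append(
            {
                "se_id": se.id,
                "n_sites": len(members),
                "n_transcribed": sum(1 for s in members if s.category == "transcribed"),
                "n_mrna": sum(1 for s in members if s.category == "mrna"),
                "n_nontranscribed": sum(
                    1 for s in members if s.category == "nontranscribed"
                ),
            }
        )
    return pd.DataFrame(rows)


def nearest_active_gene(
    summit_chrom: str,
    summit_pos: int,
    mrna_tus: list[TranscriptionUnit],
) -> tuple[str | None, int | None]:
    """Nearest transcribed gene by |summit - gene TSS|; ties go to the
    lower-coordinate TSS. Returns (None, None) on an empty chromosome."""
    best: tuple[int, int, str] | None = None
    for t in mrna_tus:
        if t.interval.chrom != summit_chrom:
            continue
        d = abs(summit_pos - t.tss)
        key = (d, t.tss, t.gene_id or t.id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[0]


def sites_to_table(sites: list[EnhancerSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "peak_id": s.id,
                "chrom": s.peak.chrom,
                "start": s.peak.start,
                "end": s.peak.end,
                "summit": s.summit,
                "open": s.open,
                "category": s.category,
                "erna_ids": ",".join(s.erna_ids) or ".",
                "se_id": s.se_id or ".",
                "sensitivity": s.sensitivity or ".",
            }
        )
    return pd.DataFrame(rows)
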