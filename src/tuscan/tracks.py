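"""Binned, strand-specific coverage built from fragment midpoints.

The genome is cut into consecutive fixed-size bins (200 bp by default) and
each fragment contributes one count to the bin containing its midpoint, on
its own strand. A pseudo-count is then added to every bin so that the
segmentation emissions never see empty bins; raw (pseudo-count-free) counts
remain available for RPK computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval


@dataclass
class CoverageTrack:
    """Per-chromosome, per-strand binned midpoint counts for one sample
    (or a pool of samples).

    ``data[(chrom, strand)]`` holds the augmented counts (raw + pseudo);
    use :meth:`raw` for pseudo-count-free values.
    """

    genome: dict[str, int]
    bin_size: int = 200
    pseudo_count: int = 1
    sample_id: str = "pooled"
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.genome.items():
            n = -(-length // self.bin_size)  # ceil
            for strand in ("+", "-"):
                key = (chrom, strand)
                if key not in self.data:
                    self.data[key] = np.full(n, self.pseudo_count, dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return list(self.genome)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[(chrom, "+")])

    def counts(self, chrom: str, strand: str) -> np.ndarray:
        """Augmented counts (raw + pseudo_count)."""
        return self.data[(chrom, strand)]

    def raw(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)] - self.pseudo_count

    def total_fragments(self) -> int:
        return int(sum(self.raw(c, s).sum() for c in self.chroms for s in "+-"))

    def raw_count_in(self, iv: GenomicInterval) -> int:
        """Raw midpoint count whose bins fall entirely inside [start, end).

        Bins are attributed by their start: bin i covers [i*b, (i+1)*b)."""
        b = self.bin_size
        lo = -(-iv.start // b)  # first bin fully inside
        hi = iv.end // b
        if iv.strand in ("+", "-"):
            return int(self.raw(iv.chrom, iv.strand)[lo:hi].sum())
        return int(
            self.raw(iv.chrom, "+")[lo:hi].sum() + self.raw(iv.chrom, "-")[lo:hi].sum()
        )


def fragments_to_coverage(
    fragments: Sequence[GenomicInterval],
    genome: dict[str, int],
    bin_size: int = 200,
    pseudo_count: int = 1,
    sample_id: str = "pooled",
) -> CoverageTrack:
    """Bin fragment midpoints into a strand-specific coverage track.

    When pooling several samples, concatenate their fragment lists first —
    midpoints are pooled before binning.
    """
    track = CoverageTrack(
        genome=dict(genome),
        bin_size=bin_size,
        pseudo_count=pseudo_count,
        sample_id=sample_id,
    )
    mids: dict[tuple[str, str], list[int]] = {}
    for f in fragments:
        if f.strand not in ("+", "-"):
            raise ValueError(f"fragment {f.id} is unstranded")
        if f.chrom not in genome:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        m = f.midpoint
        if m >= genome[f.chrom]:
            raise ValueError(
                f"fragment midpoint {m} beyond end of {f.chrom} ({genome[f.chrom]})"
            )
        mids.setdefault((f.chrom, f.strand), []).append(m)
    for (chrom, strand), positions in mids.items():
        bins = np.asarray(positions, dtype=np.int64) // bin_size
        track.data[(chrom, strand)] += np.bincount(
            bins, minlength=track.n_bins(chrom)
        ).astype(np.int64)
    return track


def coverage_from_frames(
    frames,
    genome: dict[str, int],
    bin_size: int = 200,
    pseudo_count: int = 1,
    sample_id: str = "pooled",
) -> CoverageTrack:
    """Pooled coverage from fragment DataFrames (chrom/start/end/strand).

    Vectorized equivalent of :func:`fragments_to_coverage` for the large
    fragment tables the simulator produces; midpoints are pooled across all
    frames before binning.
    """
    import pandas as pd

    track = CoverageTrack(
        genome=dict(genome),
        bin_size=bin_size,
        pseudo_count=pseudo_count,
        sample_id=sample_id,
    )
    for df in frames:
        if len(df) == 0:
            continue
        mids = ((df["start"].values + df["end"].values) // 2).astype(np.int64)
        for chrom in genome:
            on_c = df["chrom"].values == chrom
            if (mids[on_c] >= genome[chrom]).any():
                raise ValueError(f"fragment midpoint beyond end of {chrom}")
            for strand in "+-":
                sel = on_c & (df["strand"].values == strand)
                if not sel.any():
                    continue
                bins = mids[sel] // bin_size
                track.data[(chrom, strand)] += np.bincount(
                    bins, minlength=track.n_bins(chrom)
                ).astype(np.int64)
    return track


def count_midpoints(
    frames: dict[str, "pd.DataFrame"],
    features: Sequence[GenomicInterval],
    stranded: bool = False,
) -> "pd.DataFrame":
    """Feature x sample midpoint counts (HTSeq-style interval counting).

    A fragment is counted for a feature when its midpoint falls inside the
    feature interval; with ``stranded`` the fragment strand must match a
    stranded feature (unstranded features count both strands).
    """
    import pandas as pd

    fids = [f.id for f in features]
    out = pd.DataFrame(0, index=fids, columns=list(frames), dtype=np.int64)
    for sid, df in frames.items():
        if len(df) == 0:
            continue
        mids = ((df["start"].values + df["end"].values) // 2).astype(np.int64)
        chroms = df["chrom"].values
        strands = df["strand"].values
        sorted_mids: dict[tuple[str, str], np.ndarray] = {}
        for chrom in pd.unique(chroms):
            for strand in "+-":
                sel = (chroms == chrom) & (strands == strand)
                sorted_mids[(chrom, strand)] = np.sort(mids[sel])
        col = np.empty(len(features), dtype=np.int64)
        for i, f in enumerate(features):
            use = (
                [f.strand]
                if stranded and f.strand in ("+", "-")
                else ["+", "-"]
            )
            n = 0
            for strand in use:
                arr = sorted_mids.get((f.chrom, strand))
                if arr is not None and len(arr):
                    n += int(
                        np.searchsorted(arr, f.end, "left")
                        - np.searchsorted(arr, f.start, "left")
                    )
            col[i] = n
        out[sid] = col
    return out


def per_bp_coverage(
    fragments: Sequence[GenomicInterval],
    chrom: str,
    start: int,
    end: int,
    stranded_to: str | None = None,
) -> np.ndarray:
    """Per-base-pair fragment midpoint coverage over a window (for boundary
    refinement and metagene profiles)."""
    out = np.zeros(end - start, dtype=float)
    for f in fragments:
        if f.chrom != chrom:
            continue
        if stranded_to is not None and f.strand != stranded_to:
            continue
        m = f.midpoint
        if start <= m < end:
            out[m - start] += 1
    return out
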