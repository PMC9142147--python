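"""Readers and writers for the interchange formats.

Formats: BED3/BED6 (+ narrowPeak-style summit column), GTF (gene/exon
features), strand-split bedGraph, counts TSV, sample-sheet TSV, spike-in
TSV, JASPAR PFM text and FASTA. Coordinates are converted to the package's
0-based half-open convention on read (GTF is 1-based inclusive on disk).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


class FormatError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------- BED


def read_bed(path, genome: dict[str, int] | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals.

    ``genome`` (chrom -> length) enables chromosome validation when given.
    Malformed lines raise :class:`FormatError` with the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from e
            if start >= end:
                raise FormatError(f"{path}:{ln}: start must be < end")
            if genome is not None and chrom not in genome:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_peaks(path, genome: dict[str, int] | None = None) -> list[tuple[GenomicInterval, int | None]]:
    """Read peaks with an optional narrowPeak-style summit offset (col 10).

    Returns (interval, absolute summit position or None).
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if genome is not None and chrom not in genome:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            summit = None
            if len(parts) >= 10 and parts[9] not in (".", "-1", ""):
                summit = start + int(parts[9])
            out.append((GenomicInterval(chrom, start, end, strand, name, score), summit))
    return out


def write_peaks(peaks: Iterable[tuple[GenomicInterval, int | None]], path) -> None:
    with open(path, "w") as fh:
        for iv, summit in peaks:
            off = "." if summit is None else str(summit - iv.start)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{iv.score:g}\t{iv.strand}"
                f"\t.\t.\t.\t{off}\n"
            )


# ---------------------------------------------------------------- GTF


@dataclass
class Gene:
    gene_id: str
    interval: GenomicInterval
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end


def _gtf_attrs(s: str) -> dict[str, str]:
    out = {}
    for item in s.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> list[Gene]:
    """Read gene and exon features from a GTF (1-based inclusive on disk)."""
    genes: dict[str, Gene] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            a = _gtf_attrs(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{ln}: missing gene_id")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand, gid)
            if feature == "gene":
                genes[gid] = Gene(gid, iv, a.get("gene_biotype", "protein_coding"))
            else:
                exons.setdefault(gid, []).append(iv)
    for gid, g in genes.items():
        g.exons = sorted(exons.get(gid, []), key=lambda e: e.start)
    return sorted(genes.values(), key=lambda g: (g.interval.chrom, g.interval.start))


def write_gtf(genes: Iterable[Gene], path, source: str = "tuscan") -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------- bedGraph


def write_bedgraph(track, path_plus, path_minus) -> None:
    """Write a binned CoverageTrack as one bedGraph per strand (raw counts)."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for chrom in track.chroms:
                vals = track.raw(chrom, strand)
                bs = track.bin_size
                L = track.genome[chrom]
                for i, v in enumerate(vals):
                    if v:
                        fh.write(f"{chrom}\t{i * bs}\t{min((i + 1) * bs, L)}\t{v:g}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            out.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return out


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.strip())
    return {k: "".join(v).upper() for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- JASPAR PFM


def read_jaspar(path) -> list[tuple[str, np.ndarray]]:
    """Read JASPAR 2020-style PFM text.

    Returns (motif_id, 4 x w count matrix in A,C,G,T row order) per motif.
    Accepts both the bracketed ``A [ 1 2 3 ]`` and plain 4-row layouts.
    """
    motifs = []
    name = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush():
        if name is None:
            return
        if set(rows) != set(order):
            raise FormatError(f"motif {name}: expected rows A,C,G,T, got {sorted(rows)}")
        w = {len(v) for v in rows.values()}
        if len(w) != 1:
            raise FormatError(f"motif {name}: ragged matrix")
        motifs.append((name, np.array([rows[b] for b in order], dtype=float)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = {}
            else:
                base, _, rest = line.partition(" ")
                base = base.strip()
                if base not in order or name is None:
                    raise FormatError(f"unexpected PFM line: {line!r}")
                nums = rest.replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
    flush()
    return motifs


def write_jaspar(motifs: Sequence[tuple[str, np.ndarray]], path) -> None:
    with open(path, "w") as fh:
        for name, mat in motifs:
            fh.write(f">{name}\n")
            for base, row in zip("ACGT", mat):
                fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------- tables


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: feature_id index + one integer column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "assay", "time_h", "phase", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def read_spike_counts(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "spike_count"} <= set(df.columns):
        raise FormatError("spike-in TSV needs sample_id and spike_count columns")
    return df.set_index("sample_id")["spike_count"]
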