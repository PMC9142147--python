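"""PWM scanning with exact score-distribution p-values.

A position frequency matrix is turned into a log-odds matrix against a
background model, discretized onto an integer score grid, and the exact
null distribution of the total score under the background is built by
dynamic programming (convolution of per-position score histograms). The
p-value of an observed window score is the tail probability of that exact
distribution — the same construction FIMO uses — so a window is a hit iff
p(score) <= the p-value threshold (1e-4 by default). Both strands are
scanned; the reverse strand gets its own exact distribution, which matters
only for asymmetric backgrounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_GRANULARITY = 1000


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class PWM:
    """A position weight matrix with background model and log-odds scoring.

    ``counts`` is 4 x w in A,C,G,T row order (counts or frequencies);
    ``background`` a positive 4-vector summing to 1 (uniform by default);
    ``pseudocount`` is distributed by background weight before the
    frequency normalization.
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x w (A,C,G,T)")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1) > 1e-6:
            raise ValueError("background must be positive and sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        freq = (self.counts + self.pseudocount * self.background[:, None]) / (
            col + self.pseudocount
        )
        return freq

    def log_odds(self) -> np.ndarray:
        return np.log2(self.frequencies() / self.background[:, None])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.counts, axis=0))

    def reverse_complement(self) -> "PWM":
        rc = self.counts[::-1, ::-1]
        return PWM(
            motif_id=self.motif_id,
            counts=rc,
            background=self.background,
            pseudocount=self.pseudocount,
        )


@dataclass
class ScoreDistribution:
    """Integer-discretized log-odds scores with their exact null tail.

    ``int_scores`` is the 4 x w integer score matrix (offset so the minimum
    per column is handled exactly); ``tail[s]`` = P(total integer score >= s)
    under the background model; ``eps`` is the discretization granularity.
    """

    int_scores: np.ndarray
    tail: np.ndarray
    eps: float
    degenerate: bool = False

    def score_of(self, idx: np.ndarray) -> int:
        """Total integer score of a window given base indices (len w)."""
        w = self.int_scores.shape[1]
        return int(self.int_scores[idx, np.arange(w)].sum())

    def pvalue(self, int_score: int) -> float:
        s = int_score - self.offset_min
        s = max(0, min(s, len(self.tail) - 1))
        return float(self.tail[s])

    @property
    def offset_min(self) -> int:
        return int(self.int_scores.min(axis=0).sum())


def score_distribution(
    pwm: PWM, granularity: int = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact null distribution of the discretized log-odds score by DP.

    Scores are mapped to integers at eps = (max score - min score) /
    granularity and per-position histograms are convolved under the
    background; a zero-information matrix (flat log-odds) is flagged
    degenerate — its tail is identically 1, so no threshold below 1 is
    reachable.
    """
    lo = pwm.log_odds()
    span = lo.max(axis=0).sum() - lo.min(axis=0).sum()
    if span <= 0:
        warnings.warn(f"motif {pwm.motif_id}: zero-information matrix")
        ints = np.zeros_like(lo, dtype=np.int64)
        return ScoreDistribution(ints, np.ones(1), eps=1.0, degenerate=True)
    eps = span / granularity
    ints = np.rint(lo / eps).astype(np.int64)
    mins = ints.min(axis=0)
    maxs = ints.max(axis=0)
    size = int((maxs - mins).sum()) + 1
    pdf = np.zeros(size)
    pdf[0] = 1.0
    used = 0
    for j in range(pwm.width):
        nxt = np.zeros(size)
        for b in range(4):
            off = int(ints[b, j] - mins[j])
            nxt[off : off + used + 1] += pwm.background[b] * pdf[: used + 1]
        pdf = nxt
        used += int(maxs[j] - mins[j])
    tail = np.cumsum(pdf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(ints, tail, eps=eps)


@dataclass
class MotifHit:
    offset: int
    strand: str
    score: float
    p: float


_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def scan_window(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    granularity: int = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan one sequence with a PWM on both strands.

    Reports a hit at every offset/strand whose exact null p-value is <=
    ``p_threshold``; offsets with an N inside the motif window are skipped.
    Scores are reported in log2-odds units (discretized grid x eps).
    """
    w = pwm.width
    if w > len(sequence):
        warnings.warn(
            f"motif {pwm.motif_id} (w={w}) longer than sequence ({len(sequence)} bp)"
        )
        return []
    dists = {"+": score_distribution(pwm, granularity)}
    dists["-"] = score_distribution(pwm.reverse_complement(), granularity)
    enc = _encode(sequence)
    hits: list[MotifHit] = []
    for strand in "+-":
        dist = dists[strand]
        if dist.degenerate:
            continue
        for off in range(len(sequence) - w + 1):
            idx = enc[off : off + w]
            if np.any(idx < 0):
                continue
            s = dist.score_of(idx)
            p = dist.pvalue(s)
            if p <= p_threshold:
                hits.append(
                    MotifHit(offset=off, strand=strand, score=s * dist.eps, p=p)
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def percent_occurrence(
    regions_by_class: dict[str, list[tuple[str, int]]],
    genome_seqs: dict[str, str],
    pwm: PWM,
    halfwidth: int = 500,
    p_threshold: float = 1e-4,
) -> dict[str, float]:
    """Percent of summit-centred windows containing >= 1 motif hit, per class.

    ``regions_by_class`` maps a class label to (chrom, summit) anchors;
    windows are summit +- halfwidth, clipped at chromosome ends.
    """
    out = {}
    for cls, anchors in regions_by_class.items():
        if not anchors:
            raise ValueError(f"class {cls!r} has no regions")
        n_hit = 0
        for chrom, summit in anchors:
            seq = genome_seqs[chrom]
            lo = max(0, summit - halfwidth)
            hi = min(len(seq), summit + halfwidth)
            if scan_window(seq[lo:hi], pwm, p_threshold):
                n_hit += 1
        out[cls] = 100.0 * n_hit / len(anchors)
    return out
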