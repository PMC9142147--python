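"""Time-course kinetics: clustering, sensitivity taxonomy, SE-gene pairing,
enrichment tests, metagene profiles and replicate-consensus peaks.

Features are summarized as z-scored trajectories of replicate-merged,
size-factor-normalized counts over the depletion time course. Downregulated
genes split into early/late groups by k-means; enhancers are sorted into
the sensitivity taxonomy from their eRNA and accessibility differential
calls:

* transcribed enhancers — sensitive (eRNA down and accessibility down),
  insensitive (eRNA down, accessibility not down), independent (eRNA not
  down);
* nontranscribed enhancers — sensitive iff accessibility is called down at
  the final depletion time point, else insensitive.

"Down" means called down at padj < 0.01 in at least one depletion contrast
(union over time points) unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .enhancers import EnhancerSite, nearest_active_gene
from .classify import TranscriptionUnit
from .intervals import GenomicInterval


# ------------------------------------------------------- trajectories


def merged_profiles(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    times: list[float],
    assay: str,
    phase: str = "depletion",
) -> pd.DataFrame:
    """Replicate-merged (summed) normalized counts, features x time points."""
    cols = {}
    m = meta.loc[list(norm_counts.columns)]
    for t in times:
        sel = (m["time_h"] == t) & (m["assay"] == assay) & (m["phase"] == phase)
        samples = list(m.index[sel])
        if not samples:
            raise ValueError(f"no {assay} samples at {t} h ({phase})")
        cols[t] = norm_counts[samples].sum(axis=1)
    return pd.DataFrame(cols)


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row z-score transform; constant rows become all-zero (flagged by a
    warning) rather than NaN."""
    vals = profiles.values.astype(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = sd.ravel() == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profiles z-scored to zero")
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=profiles.index, columns=profiles.columns)


# ------------------------------------------------------- clustering


@dataclass
class ClusterResult:
    labels: pd.Series  # feature -> {"early", "late"}
    centers: pd.DataFrame  # label x time mean z-trajectory
    composition: pd.DataFrame | None = None  # first-sig-time share per label


def cluster_early_late(
    z: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    first_sig_time: pd.Series | None = None,
    crossing: float = -0.5,
) -> ClusterResult:
    """k-means clustering of z-scored trajectories into early/late groups.

    The cluster whose mean trajectory first crosses ``crossing`` at the
    earlier time point is labelled "early". When ``first_sig_time`` (hours
    of first significant call per feature) is given, the per-cluster
    composition of first-significant time points is reported as well.
    """
    from sklearn.cluster import KMeans

    if len(z) < 2 * k:
        raise ValueError(f"need at least {2*k} features for k={k}")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(z.values)
    raw = pd.Series(km.labels_, index=z.index)
    centers = pd.DataFrame(km.cluster_centers_, columns=z.columns)
    if len(centers.drop_duplicates()) < k:
        warnings.warn("degenerate clustering: identical cluster centres")

    def first_crossing(row: np.ndarray) -> float:
        hit = np.nonzero(row <= crossing)[0]
        return float(hit[0]) if len(hit) else np.inf

    cross = centers.apply(lambda r: first_crossing(r.values), axis=1)
    order = cross.sort_values(kind="stable").index  # earliest crossing first
    names = ["early", "late"] + [f"cluster{i}" for i in range(2, k)]
    name_of = {c: names[i] for i, c in enumerate(order)}
    labels = raw.map(name_of)
    centers.index = [name_of[i] for i in centers.index]
    composition = None
    if first_sig_time is not None:
        df = pd.DataFrame({"label": labels, "t": first_sig_time.reindex(labels.index)})
        composition = (
            df.groupby("label")["t"].value_counts(normalize=True).unstack(fill_value=0.0)
        )
    return ClusterResult(labels=labels, centers=centers, composition=composition)


def first_down_time(results: dict[float, pd.DataFrame]) -> pd.Series:
    """Hours of the earliest contrast in which each feature is called down
    (NaN when never called down)."""
    times = sorted(results)
    idx = results[times[0]].index
    out = pd.Series(np.nan, index=idx)
    for t in reversed(times):
        down = results[t]["call"] == "down"
        out[down[down].index] = t
    return out


def down_in_any(results: dict[float, pd.DataFrame]) -> pd.Series:
    """Boolean per feature: called down in >= 1 contrast (union rule)."""
    times = sorted(results)
    idx = results[times[0]].index
    acc = pd.Series(False, index=idx)
    for t in times:
        acc |= results[t]["call"].reindex(idx, fill_value="ns") == "down"
    return acc


# ------------------------------------------------------- sensitivity


def classify_sensitivity_transcribed(
    sites: list[EnhancerSite],
    erna_results: dict[float, pd.DataFrame],
    atac_results: dict[float, pd.DataFrame],
) -> pd.Series:
    """Sensitivity taxonomy at transcribed enhancers.

    sensitive = eRNA down and accessibility down; insensitive = eRNA down,
    accessibility not down; independent = eRNA not down. Sites absent from
    a result table count as unchanged there (with a warning).
    """
    erna_down = down_in_any(erna_results)
    atac_down = down_in_any(atac_results)
    labels = {}
    missing = 0
    for site in sites:
        if site.category != "transcribed":
            continue
        e_down = False
        for eid in site.erna_ids:
            if eid in erna_down.index:
                e_down = e_down or bool(erna_down[eid])
            else:
                missing += 1
        if site.id in atac_down.index:
            a_down = bool(atac_down[site.id])
        else:
            missing += 1
            a_down = False
        if e_down and a_down:
            lab = "sensitive"
        elif e_down:
            lab = "insensitive"
        else:
            lab = "independent"
        site.sensitivity = lab
        labels[site.id] = lab
    if missing:
        warnings.warn(f"{missing} feature lookups missing from result tables; treated as unchanged")
    return pd.Series(labels, name="sensitivity")


def classify_sensitivity_nontranscribed(
    sites: list[EnhancerSite],
    atac_results: dict[float, pd.DataFrame],
    final_time: float = 15.0,
) -> pd.Series:
    """Nontranscribed-enhancer taxonomy: sensitive iff accessibility is
    called down at the final depletion time point."""
    res = atac_results[final_time]
    labels = {}
    for site in sites:
        if site.category != "nontranscribed":
            continue
        down = site.id in res.index and res.loc[site.id, "call"] == "down"
        lab = "sensitive" if down else "insensitive"
        site.sensitivity = lab
        labels[site.id] = lab
    return pd.Series(labels, name="sensitivity")


# ------------------------------------------------------- SE-gene pairs


@dataclass
class SEGenePair:
    se_id: str
    gene_id: str
    distance: int
    fold_changes: dict[str, pd.Series] = field(default_factory=dict)


def fold_change_vectors(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    feature: str,
    times: list[float],
    assay: str,
    phase: str = "depletion",
) -> pd.Series:
    """Replicate-merged fold change relative to the 0 h time point (== 1 at 0 h)."""
    prof = merged_profiles(norm_counts.loc[[feature]], meta, times, assay, phase).iloc[0]
    base = prof[times[0]]
    if base == 0:
        return prof * np.nan
    return prof / base


def pair_se_genes(
    sites: list[EnhancerSite],
    se_intervals: list[GenomicInterval],
    erna_results: dict[float, pd.DataFrame],
    mrna_results: dict[float, pd.DataFrame],
    mrna_tus: list[TranscriptionUnit],
) -> list[SEGenePair]:
    """Pair transcriptionally downregulated SEs with their nearest
    transcribed genes; keep pairs whose gene is also called down.

    An SE is transcriptionally down iff >= 1 member eRNA is called down in
    any depletion contrast; the nearest gene is taken from the SE midpoint.
    SEs with no transcribed member are skipped.
    """
    erna_down = down_in_any(erna_results)
    gene_down = down_in_any(mrna_results)
    se_by_id = {se.id: se for se in se_intervals}
    pairs: list[SEGenePair] = []
    for se_id, se in se_by_id.items():
        members = [s for s in sites if s.se_id == se_id and s.category == "transcribed"]
        if not members:
            continue
        member_ernas = {e for s in members for e in s.erna_ids}
        se_down = any(bool(erna_down.get(e, False)) for e in member_ernas)
        if not se_down:
            continue
        gene_id, dist = nearest_active_gene(se.chrom, se.midpoint, mrna_tus)
        if gene_id is None:
            continue
        if not bool(gene_down.get(gene_id, False)):
            continue
        pairs.append(SEGenePair(se_id=se_id, gene_id=gene_id, distance=int(dist)))
    return pairs


# ------------------------------------------------------- enrichment


def fisher_enrichment(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> tuple[float, float]:
    """One-sided Fisher exact enrichment of a foreground set.

    ``k_fg`` of ``n_fg`` drawn features are successes, against ``k_bg``
    successes in the background population of ``n_bg``. Returns (sample
    odds ratio, upper-tail hypergeometric p = P(X >= k_fg)).
    """
    for name, v in (("k_fg", k_fg), ("n_fg", n_fg), ("k_bg", k_bg), ("n_bg", n_bg)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k_fg, n_fg, k_bg, n_bg = int(k_fg), int(n_fg), int(k_bg), int(n_bg)
    if k_fg > n_fg or k_bg > n_bg or n_fg > n_bg or k_fg > k_bg:
        raise ValueError("inconsistent contingency counts")
    p = float(hypergeom.sf(k_fg - 1, n_bg, k_bg, n_fg))
    a = k_fg
    b = n_fg - k_fg
    c = k_bg - k_fg
    d = (n_bg - n_fg) - c
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(odds), p


# ------------------------------------------------------- metagene


def metagene(
    fragments: list[GenomicInterval],
    anchors: list[tuple[str, int, str]],
    genome: dict[str, int],
    halfwidth: int = 2000,
    total_fragments: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor-centred average coverage profile in reads per million.

    ``anchors`` are (chrom, position, strand) triples — typically peak
    summits; minus-strand anchors are flipped so downstream is to the
    right. Positions outside the chromosome are masked, not zero-filled.
    Returns (matrix sites x positions, nan-mean profile), positions running
    from -halfwidth to +halfwidth - 1.
    """
    if total_fragments is None:
        total_fragments = len(fragments)
    scale = total_fragments / 1e6
    width = 2 * halfwidth
    mat = np.full((len(anchors), width), np.nan)
    mids: dict[str, np.ndarray] = {}
    for chrom in genome:
        pos = [f.midpoint for f in fragments if f.chrom == chrom]
        cov = np.zeros(genome[chrom])
        if pos:
            np.add.at(cov, np.asarray(pos), 1.0)
        mids[chrom] = cov
    for i, (chrom, center, strand) in enumerate(anchors):
        cov = mids.get(chrom)
        if cov is None:
            continue
        lo, hi = center - halfwidth, center + halfwidth
        c_lo, c_hi = max(lo, 0), min(hi, len(cov))
        window = np.full(width, np.nan)
        window[c_lo - lo : c_hi - lo] = cov[c_lo:c_hi]
        if strand == "-":
            window = window[::-1]
        mat[i] = window / scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    return mat, mean


def consensus_peaks(
    rep1: list[GenomicInterval], rep2: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Replicate-consensus peaks: rep1 peaks overlapping (>= 1 bp) at least
    one rep2 peak, reported with rep1 coordinates."""
    out = []
    for p in rep1:
        if any(
            q.chrom == p.chrom and min(p.end, q.end) - max(p.start, q.start) > 0
            for q in rep2
        ):
            out.append(p)
    return out
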