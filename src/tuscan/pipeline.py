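"""End-to-end orchestration: simulate -> annotate -> test -> classify -> report.

These functions operate on in-memory objects and are shared by the CLI and
by any script that wants the whole analysis on a synthetic dataset. Every
stage is deterministic given its inputs and the seeds in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as tc
from . import diffexp as dx
from . import enhancers as eh
from . import kinetics as kn
from . import segmentation as seg
from .config import PipelineConfig
from .intervals import GenomicInterval
from .io import Gene
from .simulate import (
    GroundTruth,
    SimConfig,
    SimulatedTimecourse,
    simulate_genome,
    simulate_timecourse,
)
from .tracks import CoverageTrack, coverage_from_frames, count_midpoints

# --------------------------------------------------------------- simulate


@dataclass
class SimBundle:
    cfg: SimConfig
    sequences: dict[str, str]
    genes: list[Gene]
    se_intervals: list[GenomicInterval]
    truth: GroundTruth
    tc: SimulatedTimecourse


def run_simulate(sim_cfg: SimConfig) -> SimBundle:
    sequences, genes, se_intervals, truth = simulate_genome(sim_cfg)
    timecourse = simulate_timecourse(sim_cfg, truth, genes)
    return SimBundle(sim_cfg, sequences, genes, se_intervals, truth, timecourse)


# --------------------------------------------------------------- annotate


@dataclass
class Annotation:
    model: seg.HmmModel
    segments: list[seg.Segment]
    refined: list[GenomicInterval]
    tus: list[tc.TranscriptionUnit]  # all retained TUs, classified
    mrna_tus: list[tc.TranscriptionUnit]
    erna_loci: list[eh.EnhancerLocus]
    min_rpk_used: float


def run_annotate(
    pcfg: PipelineConfig,
    genome: dict[str, int],
    tt_frames: dict[str, pd.DataFrame],
    genes: list[Gene],
    open_regions: list[GenomicInterval],
) -> Annotation:
    """Pooled segmentation of nascent-RNA coverage into a TU annotation.

    All samples are combined before binning; the two-state HMM is fitted on
    the pooled track, decoded per strand, segment borders are refined at
    base-pair resolution, and segments are classified and filtered.
    """
    track = coverage_from_frames(
        list(tt_frames.values()),
        genome,
        bin_size=pcfg.bin_size,
        pseudo_count=pcfg.pseudo_count,
    )
    model = seg.fit_hmm(
        track, max_iter=pcfg.hmm_max_iter, tol=pcfg.hmm_tol, nodes=pcfg.quadrature_nodes
    )
    segments = seg.decode(track, model, min_rpk=0.0, method=pcfg.decode_method)

    refined = refine_segments(
        segments, tt_frames, genome, pcfg.refine_window_bins, pcfg.bin_size
    )

    # re-apply the expression filter on refined coordinates
    def rpk_of(iv: GenomicInterval) -> float:
        return track.raw_count_in(iv) / (len(iv) / 1000.0)

    gene_tus, ncrna_segments = tc.assign_gene_class(
        refined, genes, min_frac=pcfg.gene_overlap_frac
    )
    ncrna_merged = tc.merge_close_ncrna(ncrna_segments, max_gap=pcfg.ncrna_merge_gap)
    ncrna_merged = [iv.replace(score=round(rpk_of(iv), 3)) for iv in ncrna_merged]
    ncrna_tus = tc.classify_ncrna(ncrna_merged, gene_tus, near=pcfg.ncrna_near)
    all_tus = gene_tus + ncrna_tus

    if pcfg.auto_threshold:
        min_rpk = tc.threshold_from_openness(
            all_tus, open_regions, pcfg.promoter_halfwidth
        )
    else:
        min_rpk = pcfg.min_rpk
    all_tus = [t for t in all_tus if t.rpk >= min_rpk]
    all_tus = tc.filter_by_open_promoter(
        all_tus, open_regions, pcfg.promoter_halfwidth
    )
    mrna_tus = [t for t in all_tus if t.cls == "mRNA"]
    erna_loci = eh.call_putative_ernas(
        all_tus,
        promoter_distance=pcfg.erna_promoter_distance,
        merge_gap=pcfg.erna_merge_gap,
    )
    return Annotation(
        model=model,
        segments=segments,
        refined=refined,
        tus=all_tus,
        mrna_tus=mrna_tus,
        erna_loci=erna_loci,
        min_rpk_used=min_rpk,
    )


def refine_segments(
    segments: list[seg.Segment],
    frames: dict[str, pd.DataFrame],
    genome: dict[str, int],
    window_bins: int = 4,
    bin_size: int = 200,
) -> list[GenomicInterval]:
    """Refine both borders of every segment on per-bp pooled midpoint
    coverage (all samples summed, per strand)."""
    perbp: dict[tuple[str, str], np.ndarray] = {
        (c, s): np.zeros(L) for c, L in genome.items() for s in "+-"
    }
    for df in frames.values():
        if len(df) == 0:
            continue
        mids = ((df["start"].values + df["end"].values) // 2).astype(np.int64)
        for (chrom, strand), cov in perbp.items():
            sel = (df["chrom"].values == chrom) & (df["strand"].values == strand)
            if sel.any():
                np.add.at(cov, mids[sel], 1.0)
    out = []
    for s in segments:
        iv = s.interval
        cov = perbp[(iv.chrom, iv.strand)]
        new_start = seg.refine_boundary(
            cov, iv.start, window_bins=window_bins, bin_size=bin_size
        )
        new_end = seg.refine_boundary(
            cov, iv.end, window_bins=window_bins, bin_size=bin_size
        )
        if new_end <= new_start:  # refinement collapsed a short segment
            new_start, new_end = iv.start, iv.end
        out.append(iv.replace(start=int(new_start), end=int(new_end)))
    return out


# --------------------------------------------------------------- truth features


@dataclass
class TruthFeatures:
    """Sites and eRNA loci taken directly from the generator's ground truth
    (used to exercise the downstream statistics independently of the
    segmentation stage)."""

    sites: list[eh.EnhancerSite]
    erna_loci: list[eh.EnhancerLocus]
    erna_counts: pd.DataFrame  # locus x tt sample (strands summed)


def truth_features(bundle: SimBundle) -> TruthFeatures:
    sites = []
    loci = []
    rows = {}
    tt_counts = bundle.tc.counts["tt"]
    for e in bundle.truth.enhancers:
        if not e.bound:
            continue
        site = eh.EnhancerSite(
            peak=e.peak_interval(),
            summit=e.summit,
            open=True,
            category="transcribed" if e.transcribed else "nontranscribed",
            erna_ids=[f"{e.peak_id}_locus"] if e.transcribed else [],
            se_id=e.se_id,
        )
        sites.append(site)
        if e.transcribed:
            iv = GenomicInterval(
                e.chrom,
                e.summit - bundle.cfg.erna_length,
                e.summit + bundle.cfg.erna_length,
                ".",
                f"{e.peak_id}_locus",
            )
            loci.append(
                eh.EnhancerLocus(iv, {f"{e.peak_id}_m": "-", f"{e.peak_id}_p": "+"})
            )
            rows[iv.id] = (
                tt_counts.loc[f"{e.peak_id}_m"] + tt_counts.loc[f"{e.peak_id}_p"]
            )
    erna_counts = pd.DataFrame(rows).T if rows else pd.DataFrame()
    return TruthFeatures(sites=sites, erna_loci=loci, erna_counts=erna_counts)


# --------------------------------------------------------------- differential


@dataclass
class DiffResults:
    mrna: dict[float, pd.DataFrame]
    erna: dict[float, pd.DataFrame]
    atac: dict[float, pd.DataFrame]
    mrna_cm: dx.CountMatrix
    erna_cm: dx.CountMatrix
    atac_cm: dx.CountMatrix
    anchors: list[str]


def run_diff(
    pcfg: PipelineConfig,
    bundle: SimBundle,
    erna_counts: pd.DataFrame,
    phase: str = "depletion",
    ref_time: float = 0.0,
) -> DiffResults:
    """Differential testing of every depletion time point against 0 h.

    Nascent-RNA features use median-of-ratios size factors computed on
    protein-coding genes; accessibility uses anchor-set factors computed on
    promoter peaks of expression-stable genes.
    """
    meta = bundle.tc.sample_sheet.set_index("sample_id")
    times = [t for t in bundle.cfg.time_points_depletion if t != ref_time]

    gene_ids = [g.gene_id for g in bundle.genes]
    tt = bundle.tc.counts["tt"]
    sf_tt = dx.size_factors_median_ratio(tt, gene_ids)

    mrna_cm = dx.CountMatrix(tt.loc[gene_ids], meta, sf_tt)
    mrna = dx.timecourse_tests(
        mrna_cm, "tt", times, ref_time, phase, padj_threshold=pcfg.padj_threshold
    )

    erna_cm = dx.CountMatrix(
        erna_counts, meta, sf_tt[erna_counts.columns] if len(erna_counts) else None
    )
    erna = (
        dx.timecourse_tests(
            erna_cm, "tt", times, ref_time, phase, padj_threshold=pcfg.padj_threshold
        )
        if len(erna_counts)
        else {t: pd.DataFrame(columns=["baseMean", "log2fc", "p", "padj", "call"]) for t in times}
    )

    # anchor set: promoter peaks of genes unchanged at every time point
    unchanged = set(gene_ids)
    for t, res in mrna.items():
        stable = res[
            (res["log2fc"].abs() < pcfg.anchor_log2fc)
            & (res["padj"] > pcfg.anchor_padj)
        ].index
        unchanged &= set(stable)
    anchors = [f"atac_pr_{gid}" for gid in sorted(unchanged)]
    atac = bundle.tc.counts["atac"]
    anchors = [a for a in anchors if a in atac.index]
    if not anchors:  # stability filter too strict at this depth
        import warnings

        warnings.warn(
            "no expression-stable anchor genes; using all promoter peaks"
        )
        anchors = [i for i in atac.index if i.startswith("atac_pr_")]
    sf_atac = dx.size_factors_median_ratio(atac, anchors)
    atac_cm = dx.CountMatrix(atac, meta, sf_atac)
    atac_res = dx.timecourse_tests(
        atac_cm, "atac", times, ref_time, phase, padj_threshold=pcfg.padj_threshold
    )
    return DiffResults(
        mrna=mrna,
        erna=erna,
        atac=atac_res,
        mrna_cm=mrna_cm,
        erna_cm=erna_cm,
        atac_cm=atac_cm,
        anchors=anchors,
    )


# --------------------------------------------------------------- classify


@dataclass
class ClassifyResults:
    sensitivity_transcribed: pd.Series
    sensitivity_nontranscribed: pd.Series
    pairs: list[kn.SEGenePair]
    cluster: kn.ClusterResult | None


def run_classify(
    pcfg: PipelineConfig,
    bundle: SimBundle,
    sites: list[eh.EnhancerSite],
    diff: DiffResults,
    mrna_tus: list[tc.TranscriptionUnit],
) -> ClassifyResults:
    # map atac results onto peak ids used by sites
    atac_results = {
        t: res.rename(index=lambda s: s.replace("atac_", "", 1))
        for t, res in diff.atac.items()
    }
    sens_t = kn.classify_sensitivity_transcribed(sites, diff.erna, atac_results)
    sens_nt = kn.classify_sensitivity_nontranscribed(
        sites, atac_results, final_time=pcfg.final_time
    )
    eh.annotate_se(sites, bundle.se_intervals)
    pairs = kn.pair_se_genes(
        sites, bundle.se_intervals, diff.erna, diff.mrna, mrna_tus
    )
    cluster = None
    down_genes = kn.down_in_any(diff.mrna)
    down_ids = list(down_genes[down_genes].index)
    if len(down_ids) >= 4:
        norm = diff.mrna_cm.normalized()
        prof = kn.merged_profiles(
            norm.loc[down_ids],
            diff.mrna_cm.meta,
            list(bundle.cfg.time_points_depletion),
            "tt",
        )
        z = kn.zscore_profiles(prof)
        cluster = kn.cluster_early_late(
            z,
            seed=pcfg.kmeans_seed,
            first_sig_time=kn.first_down_time(diff.mrna),
            crossing=pcfg.early_crossing,
        )
    return ClassifyResults(
        sensitivity_transcribed=sens_t,
        sensitivity_nontranscribed=sens_nt,
        pairs=pairs,
        cluster=cluster,
    )


# --------------------------------------------------------------- evaluation


def reciprocal_overlap_f1(
    predicted: list[GenomicInterval],
    true: list[GenomicInterval],
    min_frac: float = 0.5,
    stranded: bool = True,
) -> dict[str, float]:
    """Match predicted against true intervals at >= min_frac reciprocal
    overlap (of both lengths); returns precision/recall/F1 and the median
    absolute boundary error of matched pairs."""

    def matches(a: GenomicInterval, b: GenomicInterval) -> bool:
        if a.chrom != b.chrom:
            return False
        if stranded and a.strand != b.strand:
            return False
        ov = min(a.end, b.end) - max(a.start, b.start)
        return ov >= min_frac * len(a) and ov >= min_frac * len(b)

    matched_true: set[int] = set()
    matched_pred: set[int] = set()
    errors: list[float] = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(true):
            if j in matched_true:
                continue
            if matches(p, t):
                matched_pred.add(i)
                matched_true.add(j)
                errors.append(abs(p.start - t.start))
                errors.append(abs(p.end - t.end))
                break
    precision = len(matched_pred) / len(predicted) if predicted else 0.0
    recall = len(matched_true) / len(true) if true else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "median_boundary_error": float(np.median(errors)) if errors else float("nan"),
    }


def balanced_accuracy(true_labels: pd.Series, pred_labels: pd.Series) -> float:
    """Mean per-class recall over the classes present in the truth."""
    idx = true_labels.index.intersection(pred_labels.index)
    recalls = []
    for cls in sorted(true_labels.loc[idx].unique()):
        members = idx[true_labels.loc[idx] == cls]
        recalls.append(float((pred_labels.loc[members] == cls).mean()))
    return float(np.mean(recalls)) if recalls else float("nan")


def truth_pairs(bundle: SimBundle) -> set[tuple[str, str]]:
    """SE-gene pairs implied by the planted labels: an SE whose members lose
    eRNA, paired with its nearest transcribed gene when that gene is a
    planted downregulated gene (same geometry rule as the estimator)."""
    down_classes = {"sensitive", "insensitive"}
    mrna_truth = [
        tc.TranscriptionUnit(t, "mRNA", 0.0, gene_id=t.id)
        for t in bundle.truth.tu_intervals
        if bundle.truth.tu_classes[t.id] == "mRNA"
    ]
    out = set()
    for se in bundle.se_intervals:
        members = [e for e in bundle.truth.enhancers if e.se_id == se.id and e.transcribed]
        if not members:
            continue
        if not any(e.label in down_classes for e in members):
            continue
        gid, _ = eh.nearest_active_gene(se.chrom, se.midpoint, mrna_truth)
        if gid is None:
            continue
        if bundle.truth.gene_response.get(gid, "unchanged").endswith("down"):
            out.add((se.id, gid))
    return out
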