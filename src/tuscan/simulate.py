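"""Synthetic genome, annotation and multi-assay depletion/recovery time course.

The generator emulates the statistical structure of a TF-depletion
experiment read out by nascent-RNA sequencing, accessibility and TF
occupancy assays over a depletion time course (0-15 h) and a washout
recovery (4.5 and 9 h):

* genes carry uniform nascent-RNA signal over their body and a response
  class (early_down, late_down, early_up, late_up, unchanged);
* enhancers carry bidirectional eRNA signal as two divergent ~700 bp units
  around the summit, an accessibility peak, and (when bound) an occupancy
  peak whose expectation follows the chromatin-bound TF decay measured in
  the modelled experiment (100, 87.5, 50.5, 17.0, 7.0, 2.5 percent at
  0/3/6/9/12/15 h);
* enhancer sensitivity classes: "sensitive" loses eRNA with the occupancy
  decay and accessibility only from 9 h; "insensitive" loses eRNA but keeps
  accessibility; "independent" keeps both; "unbound" has no occupancy peak;
* counts are negative-binomial around the expected signal, a per-sample
  depth factor models library-size/efficiency variation, occupancy spike-in
  expectations are biologically constant, and low-rate uniform background
  fragments cover the whole genome so segmentation has noise to reject.

All randomness flows from ``SimConfig.rng_seed``; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import Gene

ENHANCER_CLASSES = ("sensitive", "insensitive", "independent", "unbound")
GENE_RESPONSES = ("early_down", "late_down", "early_up", "late_up", "unchanged")

# chromatin-bound TF fraction remaining at 3, 6, 9, 12, 15 h of depletion
DEFAULT_OCCUPANCY_DECAY = (0.875, 0.505, 0.170, 0.070, 0.025)

# accessibility at sensitive enhancers: delayed loss, starting at 9 h
DEFAULT_ATAC_DECAY_SENSITIVE = (1.0, 1.0, 1.0, 0.6, 0.3, 0.2)

# per-response multipliers over the depletion grid (0, 3, 6, 9, 12, 15 h)
GENE_MULTIPLIERS = {
    "early_down": (1.0, 0.8, 0.45, 0.25, 0.12, 0.10),
    "late_down": (1.0, 1.0, 1.0, 0.85, 0.50, 0.25),
    "early_up": (1.0, 1.3, 1.8, 2.2, 2.5, 2.5),
    "late_up": (1.0, 1.0, 1.0, 1.2, 1.8, 2.2),
    "unchanged": (1.0,) * 6,
}
# recovery multipliers (relative to the 0 h baseline) at 4.5 and 9 h washout
GENE_RECOVERY = {
    "early_down": (0.35, 0.65),
    "late_down": (0.50, 0.80),
    "early_up": (2.3, 2.0),
    "late_up": (2.0, 1.7),
    "unchanged": (1.0, 1.0),
}
ERNA_RECOVERY = {"sensitive": (0.10, 0.20), "insensitive": (0.05, 0.10)}
ATAC_RECOVERY_SENSITIVE = (0.80, 0.95)

# SoxOct-composite position frequency matrix (synthetic, consensus
# CTTTGTTATGCAAAT: a Sox HMG box site directly abutting an octamer site)
SOXOCT_CONSENSUS = "CTTTGTTATGCAAAT"
SOXOCT_ID = "SoxOct_composite"


def soxoct_pfm(strength: int = 85, total: int = 100) -> np.ndarray:
    """Counts matrix for the planted composite motif (4 x 15, A,C,G,T)."""
    w = len(SOXOCT_CONSENSUS)
    off = (total - strength) / 3.0
    mat = np.full((4, w), off)
    for j, b in enumerate(SOXOCT_CONSENSUS):
        mat["ACGT".index(b), j] = strength
    return mat


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment."""

    genome_length: list[int] = field(default_factory=lambda: [2_000_000])
    n_genes: int = 50
    n_enhancers: int = 40
    class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.35, 0.15)
    time_points_depletion: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)
    time_points_recovery: tuple[float, ...] = (4.5, 9.0)
    replicates: int = 2
    occupancy_decay: tuple[float, ...] = DEFAULT_OCCUPANCY_DECAY
    atac_decay_sensitive: tuple[float, ...] = DEFAULT_ATAC_DECAY_SENSITIVE
    nb_dispersion: float = 0.05
    seq_depth: float = 60.0  # expected nascent-RNA fragments per kb of gene at 0 h (scale)
    erna_depth: float = 150.0  # expected fragments per eRNA unit at 0 h (scale)
    atac_depth: float = 200.0  # expected accessibility fragments per peak at 0 h
    chip_depth: float = 300.0  # expected occupancy fragments per bound peak at 0 h
    spike_in_depth: float = 5000.0  # expected spike-in fragments per occupancy sample
    background_rate: float = 2.0  # background fragments per kb per strand per sample
    depth_sd: float = 0.15  # log-sd of the per-sample depth factor
    nontranscribed_fraction: float = 0.3
    n_se: int = 8
    se_members: int = 2
    erna_length: int = 700
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        decay = list(self.occupancy_decay)
        if any(not (0 <= d <= 1) for d in decay):
            raise ValueError("occupancy_decay must lie in [0, 1]")
        if any(b > a for a, b in zip(decay, decay[1:])):
            raise ValueError("occupancy_decay must be non-increasing")
        if len(decay) != len(self.time_points_depletion) - 1:
            raise ValueError(
                "occupancy_decay needs one fraction per post-0 h depletion time point"
            )

    def erna_decay(self) -> tuple[float, ...]:
        return (1.0,) + tuple(self.occupancy_decay)


@dataclass
class SimEnhancer:
    peak_id: str
    chrom: str
    summit: int
    label: str  # sensitivity class (ground truth)
    transcribed: bool
    se_id: str | None = None

    @property
    def bound(self) -> bool:
        return self.label != "unbound"

    def peak_interval(self, half: int = 150) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.summit - half, self.summit + half, ".", self.peak_id
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    genome: dict[str, int]
    tu_intervals: list[GenomicInterval]  # id carries feature id, score = 0
    tu_classes: dict[str, str]  # feature id -> {mRNA, eRNA}
    enhancers: list[SimEnhancer]
    gene_response: dict[str, str]
    se_intervals: list[GenomicInterval]
    motif_placements: dict[str, list[tuple[str, int, str]]]
    gene_rates: dict[str, float] = field(default_factory=dict)
    erna_rates: dict[str, float] = field(default_factory=dict)
    atac_rates: dict[str, float] = field(default_factory=dict)
    chip_rates: dict[str, float] = field(default_factory=dict)

    @property
    def enhancer_labels(self) -> dict[str, str]:
        return {e.peak_id: e.label for e in self.enhancers}

    @property
    def se_membership(self) -> dict[str, str]:
        return {e.peak_id: e.se_id for e in self.enhancers if e.se_id is not None}

    def to_json(self, path) -> None:
        doc = {
            "genome": self.genome,
            "tu_intervals": [
                [t.chrom, t.start, t.end, t.strand, self.tu_classes[t.id], t.id]
                for t in self.tu_intervals
            ],
            "enhancer_labels": self.enhancer_labels,
            "enhancer_transcribed": {e.peak_id: e.transcribed for e in self.enhancers},
            "gene_response": self.gene_response,
            "se_membership": self.se_membership,
            "motif_placements": self.motif_placements,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


class SizingError(ValueError):
    """The requested features do not fit in the requested genome."""


def _allocate(n: int, proportions: dict[str, float] | list[float]) -> list[int]:
    """Largest-remainder allocation of n items to proportions (deterministic)."""
    if isinstance(proportions, dict):
        props = list(proportions.values())
    else:
        props = list(proportions)
    raw = [p * n for p in props]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


# ---------------------------------------------------------------- genome


def simulate_genome(cfg: SimConfig):
    """Lay out genes, enhancers and superenhancer clusters on random sequence.

    Returns (sequences, genes, se_intervals, truth). Genes are single-exon,
    non-overlapping, strand-alternating blocks with generous margins;
    superenhancers are clusters of >= 2 enhancers placed next to a gene that
    is forced early_down (the planted SE-controlled genes); every sensitive
    or insensitive enhancer carries one planted SoxOct-composite instance at
    its summit. Raises :class:`SizingError` naming the first feature that
    does not fit.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    chroms = {f"chr{i+1}": L for i, L in enumerate(cfg.genome_length)}

    # --- enhancer classes (largest-remainder; deterministic order, then shuffled)
    class_counts = _allocate(cfg.n_enhancers, list(cfg.class_mix))
    labels = [c for c, k in zip(ENHANCER_CLASSES, class_counts) for _ in range(k)]
    rng.shuffle(labels)

    # SE membership comes from eRNA-losing (sensitive/insensitive) enhancers
    pool = [i for i, l in enumerate(labels) if l in ("sensitive", "insensitive")]
    pool += [i for i, l in enumerate(labels) if l == "independent"]
    n_se = min(cfg.n_se, len(pool) // max(cfg.se_members, 2), cfg.n_genes)
    se_slots = [pool[i * cfg.se_members : (i + 1) * cfg.se_members] for i in range(n_se)]
    in_se = {i for slot in se_slots for i in slot}

    # nontranscribed sites among non-SE sensitive/insensitive enhancers
    nt_candidates = [
        i
        for i, l in enumerate(labels)
        if l in ("sensitive", "insensitive") and i not in in_se
    ]
    n_nt = int(round(cfg.nontranscribed_fraction * len(nt_candidates)))
    nontranscribed = set(nt_candidates[:n_nt])

    # --- gene responses; SE-adjacent genes are early_down by construction
    response_mix = {
        "early_down": 0.25,
        "late_down": 0.15,
        "early_up": 0.05,
        "late_up": 0.05,
        "unchanged": 0.50,
    }
    resp_counts = dict(zip(GENE_RESPONSES, _allocate(cfg.n_genes, response_mix)))
    se_gene_ids = [f"g{i+1:04d}" for i in range(n_se)]
    for gid in se_gene_ids:
        resp_counts["early_down"] -= 1
    if resp_counts["early_down"] < 0:
        resp_counts["unchanged"] += resp_counts["early_down"]
        resp_counts["early_down"] = 0
    rest = [r for r, k in resp_counts.items() for _ in range(max(k, 0))]
    rng.shuffle(rest)
    gene_response = {gid: "early_down" for gid in se_gene_ids}
    for i in range(n_se, cfg.n_genes):
        gene_response[f"g{i+1:04d}"] = rest[i - n_se] if i - n_se < len(rest) else "unchanged"

    # --- blocks: (kind, payload, span)
    GENE_MARGIN, ENH_MARGIN, SE_SPACING = 4000, 3000, 4000
    blocks = []
    gene_lengths = rng.integers(4000, 12001, cfg.n_genes)
    gene_strands = ["+" if i % 2 == 0 else "-" for i in range(cfg.n_genes)]
    enh_order = list(range(cfg.n_enhancers))
    standalone = [i for i in enh_order if i not in in_se]
    for s, slot in enumerate(se_slots):
        gid = se_gene_ids[s]
        glen = int(gene_lengths[s])
        span = (
            GENE_MARGIN
            + len(slot) * SE_SPACING
            + 8000  # SE-to-gene spacer
            + glen
            + GENE_MARGIN
        )
        blocks.append(("se", (f"se{s+1:02d}", slot, gid, glen, gene_strands[s]), span))
    for i in range(n_se, cfg.n_genes):
        glen = int(gene_lengths[i])
        blocks.append(("gene", (f"g{i+1:04d}", glen, gene_strands[i]), glen + 2 * GENE_MARGIN))
    for i in standalone:
        blocks.append(("enh", i, cfg.erna_length * 2 + 2 * ENH_MARGIN))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # --- place blocks chromosome by chromosome
    genes: list[Gene] = []
    enhancers: dict[int, SimEnhancer] = {}
    se_intervals: list[GenomicInterval] = []
    chrom_names = list(chroms)
    ci, cursor = 0, 1000
    for kind, payload, span in blocks:
        while ci < len(chrom_names) and cursor + span + 1000 > chroms[chrom_names[ci]]:
            ci += 1
            cursor = 1000
        if ci >= len(chrom_names):
            name = {
                "se": f"superenhancer {payload[0]}",
                "gene": f"gene {payload[0]}",
                "enh": f"enhancer e{payload+1:04d}" if isinstance(payload, int) else "?",
            }[kind]
            raise SizingError(f"genome too small to place {name}")
        chrom = chrom_names[ci]
        if kind == "gene":
            gid, glen, strand = payload
            start = cursor + GENE_MARGIN
            iv = GenomicInterval(chrom, start, start + glen, strand, gid)
            genes.append(Gene(gid, iv, "protein_coding", [iv]))
        elif kind == "enh":
            idx = payload
            summit = cursor + ENH_MARGIN + cfg.erna_length
            enhancers[idx] = SimEnhancer(
                peak_id=f"e{idx+1:04d}",
                chrom=chrom,
                summit=summit,
                label=labels[idx],
                transcribed=(idx not in nontranscribed),
            )
        else:  # SE cluster + its target gene
            se_id, slot, gid, glen, strand = payload
            pos = cursor + GENE_MARGIN
            summits = []
            for idx in slot:
                summit = pos + SE_SPACING // 2
                enhancers[idx] = SimEnhancer(
                    peak_id=f"e{idx+1:04d}",
                    chrom=chrom,
                    summit=summit,
                    label=labels[idx],
                    transcribed=True,
                    se_id=se_id,
                )
                summits.append(summit)
                pos += SE_SPACING
            se_intervals.append(
                GenomicInterval(
                    chrom, min(summits) - 1000, max(summits) + 1000, ".", se_id
                )
            )
            gstart = pos + 8000
            iv = GenomicInterval(chrom, gstart, gstart + glen, strand, gid)
            genes.append(Gene(gid, iv, "protein_coding", [iv]))
        cursor += span
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))

    # --- sequence with planted composite motifs
    seqs = {}
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    for chrom, L in chroms.items():
        seqs[chrom] = rng.integers(0, 4, L)
    motif_placements: dict[str, list[tuple[str, int, str]]] = {}
    consensus_idx = np.array(["ACGT".index(b) for b in SOXOCT_CONSENSUS])
    comp = np.array([3, 2, 1, 0])
    for e in sorted(enhancers.values(), key=lambda x: x.peak_id):
        if e.label not in ("sensitive", "insensitive"):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        planted = consensus_idx if strand == "+" else comp[consensus_idx[::-1]]
        off = e.summit - len(planted) // 2
        seqs[e.chrom][off : off + len(planted)] = planted
        motif_placements[e.peak_id] = [(SOXOCT_ID, off, strand)]
    sequences = {
        chrom: base_arr[arr].tobytes().decode() for chrom, arr in seqs.items()
    }

    # --- ground-truth transcription units
    tu_intervals: list[GenomicInterval] = []
    tu_classes: dict[str, str] = {}
    for g in genes:
        tu_intervals.append(g.interval)
        tu_classes[g.gene_id] = "mRNA"
    for e in sorted(enhancers.values(), key=lambda x: x.peak_id):
        if not e.transcribed:
            continue
        minus = GenomicInterval(
            e.chrom, e.summit - cfg.erna_length, e.summit, "-", f"{e.peak_id}_m"
        )
        plus = GenomicInterval(
            e.chrom, e.summit, e.summit + cfg.erna_length, "+", f"{e.peak_id}_p"
        )
        for unit in (minus, plus):
            tu_intervals.append(unit)
            tu_classes[unit.id] = "eRNA"

    truth = GroundTruth(
        genome=dict(chroms),
        tu_intervals=tu_intervals,
        tu_classes=tu_classes,
        enhancers=sorted(enhancers.values(), key=lambda x: x.peak_id),
        gene_response=gene_response,
        se_intervals=se_intervals,
        motif_placements=motif_placements,
    )
    # baseline rates (drawn once; shared by all samples)
    for g in genes:
        truth.gene_rates[g.gene_id] = float(
            cfg.seq_depth * np.exp(rng.normal(0.0, 0.5))
        )
    for e in truth.enhancers:
        if e.transcribed:
            for suffix in ("_m", "_p"):
                truth.erna_rates[e.peak_id + suffix] = float(
                    cfg.erna_depth * np.exp(rng.normal(0.0, 0.4))
                )
        truth.atac_rates[f"atac_{e.peak_id}"] = float(
            cfg.atac_depth * np.exp(rng.normal(0.0, 0.3))
        )
        if e.bound:
            truth.chip_rates[f"chip_{e.peak_id}"] = float(
                cfg.chip_depth * np.exp(rng.normal(0.0, 0.3))
            )
    for g in genes:
        truth.atac_rates[f"atac_pr_{g.gene_id}"] = float(
            cfg.atac_depth * 1.5 * np.exp(rng.normal(0.0, 0.3))
        )
    return sequences, genes, se_intervals, truth


# ---------------------------------------------------------------- signals


def _erna_multiplier(cfg: SimConfig, label: str, time: float, phase: str) -> float:
    if label in ("independent", "unbound"):
        return 1.0
    if phase == "recovery":
        i = list(cfg.time_points_recovery).index(time)
        return ERNA_RECOVERY[label][i]
    i = list(cfg.time_points_depletion).index(time)
    return cfg.erna_decay()[i]


def _atac_multiplier(cfg: SimConfig, label: str, time: float, phase: str) -> float:
    if label != "sensitive":
        return 1.0
    if phase == "recovery":
        i = list(cfg.time_points_recovery).index(time)
        return ATAC_RECOVERY_SENSITIVE[i]
    i = list(cfg.time_points_depletion).index(time)
    return cfg.atac_decay_sensitive[i]


def _chip_multiplier(cfg: SimConfig, time: float) -> float:
    i = list(cfg.time_points_depletion).index(time)
    return ([1.0] + list(cfg.occupancy_decay))[i]


def _gene_multiplier(cfg: SimConfig, response: str, time: float, phase: str) -> float:
    if phase == "recovery":
        i = list(cfg.time_points_recovery).index(time)
        return GENE_RECOVERY[response][i]
    i = list(cfg.time_points_depletion).index(time)
    return GENE_MULTIPLIERS[response][i]


def nb_draws(rng: np.random.Generator, mean, alpha: float, size=None):
    """NB(mean, dispersion alpha) counts; Poisson in the alpha -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


@dataclass
class SimulatedTimecourse:
    sample_sheet: pd.DataFrame
    fragments: dict[str, pd.DataFrame]  # sample_id -> chrom/start/end/strand
    spike_counts: pd.Series
    counts: dict[str, pd.DataFrame]  # assay -> features x samples (realized)
    expected: dict[str, pd.DataFrame]  # assay -> expected NB means (with depth)
    features: dict[str, list[GenomicInterval]]  # assay -> count features
    open_regions: list[GenomicInterval]
    chip_peaks: list[tuple[GenomicInterval, int]]
    depth_factors: pd.Series | None = None

    def fragment_intervals(self, sample_id: str) -> list[GenomicInterval]:
        df = self.fragments[sample_id]
        return [
            GenomicInterval(c, int(s), int(e), st)
            for c, s, e, st in zip(df.chrom, df.start, df.end, df.strand)
        ]


def simulate_timecourse(
    cfg: SimConfig, truth: GroundTruth, genes: list[Gene]
) -> SimulatedTimecourse:
    """Draw NB counts and fragment positions for every sample of the grid.

    Assays: ``tt`` (nascent RNA; depletion + recovery), ``atac``
    (accessibility; depletion + recovery) and ``chip`` (occupancy with
    spike-ins; depletion only).
    """
    rng = np.random.default_rng(cfg.rng_seed + 1_000_003)
    sheet_rows = []
    grids = {
        "tt": [("depletion", t) for t in cfg.time_points_depletion]
        + [("recovery", t) for t in cfg.time_points_recovery],
        "atac": [("depletion", t) for t in cfg.time_points_depletion]
        + [("recovery", t) for t in cfg.time_points_recovery],
        "chip": [("depletion", t) for t in cfg.time_points_depletion],
    }
    for assay, grid in grids.items():
        for phase, t in grid:
            for rep in range(1, cfg.replicates + 1):
                sid = f"{assay}_{phase[:3]}_{t:g}h_r{rep}"
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "assay": assay,
                        "time_h": t,
                        "phase": phase,
                        "replicate": rep,
                    }
                )
    sheet = pd.DataFrame(sheet_rows)
    depth = pd.Series(
        np.exp(rng.normal(0.0, cfg.depth_sd, len(sheet))),
        index=sheet.sample_id,
        name="depth_factor",
    )

    enh_by_id = {e.peak_id: e for e in truth.enhancers}
    gene_by_id = {g.gene_id: g for g in genes}

    # ---- features per assay
    features: dict[str, list[GenomicInterval]] = {"tt": [], "atac": [], "chip": []}
    for g in genes:
        features["tt"].append(g.interval)
    erna_units = {
        t.id: t for t in truth.tu_intervals if truth.tu_classes[t.id] == "eRNA"
    }
    features["tt"] += list(erna_units.values())
    open_regions: list[GenomicInterval] = []
    for g in genes:
        tss = g.tss
        iv = GenomicInterval(
            g.interval.chrom, max(0, tss - 300), tss + 300, ".", f"atac_pr_{g.gene_id}"
        )
        features["atac"].append(iv)
        open_regions.append(iv)
    chip_peaks: list[tuple[GenomicInterval, int]] = []
    for e in truth.enhancers:
        iv = GenomicInterval(
            e.chrom, e.summit - 300, e.summit + 300, ".", f"atac_{e.peak_id}"
        )
        features["atac"].append(iv)
        open_regions.append(iv)
        if e.bound:
            peak = e.peak_interval()
            features["chip"].append(peak.replace(id=f"chip_{e.peak_id}"))
            chip_peaks.append((peak, e.summit))

    # ---- expected means per assay
    def expected_mean(assay: str, fid: str, phase: str, t: float) -> float:
        if assay == "tt":
            if fid in truth.gene_rates:
                g = gene_by_id[fid]
                base = truth.gene_rates[fid] * (len(g.interval) / 1000.0)
                return base * _gene_multiplier(
                    cfg, truth.gene_response[fid], t, phase
                )
            base = truth.erna_rates[fid]
            label = enh_by_id[fid.rsplit("_", 1)[0]].label
            return base * _erna_multiplier(cfg, label, t, phase)
        if assay == "atac":
            base = truth.atac_rates[fid]
            if fid.startswith("atac_pr_"):
                return base  # promoter accessibility held stable
            e = enh_by_id[fid[len("atac_") :]]
            return base * _atac_multiplier(cfg, e.label, t, phase)
        base = truth.chip_rates[fid]
        return base * _chip_multiplier(cfg, t)

    counts: dict[str, pd.DataFrame] = {}
    expected: dict[str, pd.DataFrame] = {}
    for assay in grids:
        fids = [f.id for f in features[assay]]
        samples = sheet[sheet.assay == assay]
        exp = np.zeros((len(fids), len(samples)))
        for j, (_, row) in enumerate(samples.iterrows()):
            d = depth[row.sample_id]
            for i, fid in enumerate(fids):
                exp[i, j] = expected_mean(assay, fid, row.phase, row.time_h) * d
        cnt = nb_draws(rng, exp, cfg.nb_dispersion)
        counts[assay] = pd.DataFrame(
            cnt, index=fids, columns=list(samples.sample_id)
        )
        expected[assay] = pd.DataFrame(
            exp, index=fids, columns=list(samples.sample_id)
        )

    # ---- spike-ins for the occupancy assay (biologically constant)
    chip_samples = list(sheet[sheet.assay == "chip"].sample_id)
    spike = pd.Series(
        nb_draws(
            rng,
            np.array([cfg.spike_in_depth * depth[s] for s in chip_samples]),
            cfg.nb_dispersion,
        ),
        index=chip_samples,
        name="spike_count",
    )

    # ---- fragments
    feature_lookup = {assay: {f.id: f for f in features[assay]} for assay in grids}
    fragments: dict[str, pd.DataFrame] = {}
    for _, row in sheet.iterrows():
        sid = row.sample_id
        assay = row.assay
        rows_c, rows_s, rows_e, rows_st = [], [], [], []

        def emit(chrom, mids, strands):
            lengths = rng.integers(150, 251, len(mids))
            starts = np.maximum(mids - lengths // 2, 0)
            ends = starts + lengths
            hi = truth.genome[chrom]
            ends = np.minimum(ends, hi)
            starts = np.minimum(starts, ends - 1)
            rows_c.append(np.full(len(mids), chrom, dtype=object))
            rows_s.append(starts)
            rows_e.append(ends)
            rows_st.append(strands)

        cnt = counts[assay][sid]
        for fid, n in cnt.items():
            n = int(n)
            if n == 0:
                continue
            f = feature_lookup[assay][fid]
            if assay == "chip":
                e = enh_by_id[fid[len("chip_") :]]
                mids = np.clip(
                    np.rint(rng.normal(e.summit, 60, n)).astype(np.int64),
                    f.start,
                    f.end - 1,
                )
                strands = np.where(rng.random(n) < 0.5, "+", "-")
            elif assay == "atac":
                mids = rng.integers(f.start, f.end, n)
                strands = np.where(rng.random(n) < 0.5, "+", "-")
            else:
                mids = rng.integers(f.start, f.end, n)
                strands = np.full(n, f.strand)
            emit(f.chrom, mids, strands)
        # uniform background on both strands
        for chrom, L in truth.genome.items():
            for strand in "+-":
                n_bg = rng.poisson(
                    cfg.background_rate * (L / 1000.0) * depth[sid]
                )
                if n_bg:
                    mids = rng.integers(200, L - 200, n_bg)
                    emit(chrom, mids, np.full(n_bg, strand))
        if rows_c:
            df = pd.DataFrame(
                {
                    "chrom": np.concatenate(rows_c),
                    "start": np.concatenate(rows_s).astype(np.int64),
                    "end": np.concatenate(rows_e).astype(np.int64),
                    "strand": np.concatenate(rows_st),
                }
            )
        else:
            df = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        df = df.sort_values(["chrom", "start", "end", "strand"], kind="stable")
        fragments[sid] = df.reset_index(drop=True)

    return SimulatedTimecourse(
        sample_sheet=sheet,
        fragments=fragments,
        spike_counts=spike,
        counts=counts,
        expected=expected,
        features=features,
        open_regions=open_regions,
        chip_peaks=chip_peaks,
        depth_factors=depth,
    )


# ---------------------------------------------------------------- writers


def write_dataset(outdir, cfg: SimConfig, sequences, genes, se_intervals, truth, tc):
    """Write the full synthetic dataset as plain-text interchange files."""
    from pathlib import Path

    from . import io as tio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(sequences, out / "genome.fa")
    tio.write_gtf(genes, out / "annotation.gtf")
    tio.write_bed(se_intervals, out / "superenhancers.bed")
    tio.write_bed(tc.open_regions, out / "open_regions.bed")
    tio.write_peaks(tc.chip_peaks, out / "chip_peaks.bed")
    truth.to_json(out / "ground_truth.json")
    tc.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    tc.spike_counts.rename("spike_count").reset_index().rename(
        columns={"index": "sample_id"}
    ).to_csv(out / "spike_counts.tsv", sep="\t", index=False)
    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for sid, df in tc.fragments.items():
        bed = df.copy()
        bed["name"] = "."
        bed["score"] = 0
        bed[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            frag_dir / f"{sid}.bed", sep="\t", index=False, header=False
        )
    for assay, df in tc.counts.items():
        tio.write_counts(df, out / f"counts_{assay}.tsv")
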