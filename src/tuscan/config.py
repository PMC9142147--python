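"""Single validated configuration document for the pipeline.

All scalar thresholds live here: bin size and pseudo-count for coverage,
the minimal-expression RPK cutoff (fixed 26.5 or optimized from promoter
openness), promoter half-width, ncRNA/eRNA merge gaps, the adjusted-p
threshold for differential calls, the motif window and p-value threshold,
and the seeds of every stochastic stage. Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml


@dataclass
class PipelineConfig:
    # coverage / segmentation
    bin_size: int = 200
    pseudo_count: int = 1
    min_rpk: float = 26.5
    auto_threshold: bool = False  # derive min_rpk from promoter openness
    hmm_max_iter: int = 50
    hmm_tol: float = 1e-3
    quadrature_nodes: int = 64
    decode_method: str = "viterbi"
    refine_window_bins: int = 4
    # TU classification
    gene_overlap_frac: float = 0.2
    promoter_halfwidth: int = 1000
    ncrna_merge_gap: int = 200
    ncrna_near: int = 1000
    # enhancers
    erna_promoter_distance: int = 1000
    erna_merge_gap: int = 1000
    enhancer_max_gap: int = 1000
    # differential testing
    padj_threshold: float = 0.01
    anchor_log2fc: float = 0.25
    anchor_padj: float = 0.5
    # kinetics
    kmeans_seed: int = 0
    kmeans_restarts: int = 25
    early_crossing: float = -0.5
    final_time: float = 15.0
    # motifs
    motif_halfwidth: int = 500
    motif_p_threshold: float = 1e-4
    motif_granularity: int = 1000
    # metagene
    metagene_halfwidth: int = 2000
    # simulation seed (SimConfig carries the full generator parameters)
    sim_seed: int = 1

    def __post_init__(self) -> None:
        checks = [
            (self.bin_size > 0, "bin_size must be positive"),
            (self.pseudo_count >= 0, "pseudo_count must be >= 0"),
            (self.min_rpk >= 0, "min_rpk must be >= 0"),
            (0 < self.padj_threshold < 1, "padj_threshold must be in (0, 1)"),
            (0 < self.motif_p_threshold < 1, "motif_p_threshold must be in (0, 1)"),
            (0 < self.gene_overlap_frac <= 1, "gene_overlap_frac must be in (0, 1]"),
            (self.promoter_halfwidth >= 0, "promoter_halfwidth must be >= 0"),
            (self.decode_method in ("viterbi", "posterior"), "bad decode_method"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**doc)
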