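import numpy as np
import pytest

from tuscan import pipeline as pl
from tuscan.config import PipelineConfig
from tuscan.simulate import SimConfig


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study: 2 Mb, 50 genes, 40 enhancers, seed 1."""
    return pl.run_simulate(SimConfig())


@pytest.fixture(scope="session")
def default_annotation(default_bundle):
    pcfg = PipelineConfig()
    tt_frames = {
        sid: df
        for sid, df in default_bundle.tc.fragments.items()
        if sid.startswith("tt_")
    }
    return pl.run_annotate(
        pcfg,
        default_bundle.truth.genome,
        tt_frames,
        default_bundle.genes,
        default_bundle.tc.open_regions,
    )


@pytest.fixture(scope="session")
def default_diff(default_bundle):
    tf = pl.truth_features(default_bundle)
    diff = pl.run_diff(PipelineConfig(), default_bundle, tf.erna_counts)
    return tf, diff


def random_intervals(rng, n, chrom="chr1", span=100_000, max_len=2_000, strand_choices=("+", "-", ".")):
    from tuscan.intervals import GenomicInterval

    out = []
    for i in range(n):
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        strand = strand_choices[int(rng.integers(len(strand_choices)))]
        out.append(GenomicInterval(chrom, start, start + length, strand, f"iv{i}"))
    return out
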