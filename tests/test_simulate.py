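"""The synthetic-data generator: determinism, planted structure, signal model."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from tuscan import pipeline as pl
from tuscan.simulate import (
    DEFAULT_OCCUPANCY_DECAY,
    SOXOCT_CONSENSUS,
    SimConfig,
    SizingError,
    nb_draws,
    simulate_genome,
    simulate_timecourse,
    write_dataset,
)

SMALL = dict(genome_length=[600_000], n_genes=12, n_enhancers=10, rng_seed=7)


class TestConfigValidation:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="class_mix"):
            SimConfig(class_mix=(0.5, 0.5, 0.5, 0.0))

    def test_occupancy_decay_monotone(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SimConfig(occupancy_decay=(0.5, 0.9, 0.2, 0.1, 0.05))

    def test_default_decay_follows_measured_chromatin_fractions(self):
        assert SimConfig().occupancy_decay == DEFAULT_OCCUPANCY_DECAY == (
            0.875,
            0.505,
            0.170,
            0.070,
            0.025,
        )


class TestSimulateGenome:
    def test_empty_case(self):
        cfg = SimConfig(genome_length=[100_000], n_genes=0, n_enhancers=0)
        seqs, genes, ses, truth = simulate_genome(cfg)
        assert genes == [] and ses == [] and truth.tu_intervals == []
        assert len(seqs["chr1"]) == 100_000

    def test_degenerate_mix_all_sensitive(self):
        cfg = SimConfig(
            genome_length=[2_000_000],
            n_genes=5,
            n_enhancers=20,
            class_mix=(1.0, 0.0, 0.0, 0.0),
        )
        _, _, _, truth = simulate_genome(cfg)
        labels = truth.enhancer_labels
        assert len(labels) == 20
        assert set(labels.values()) == {"sensitive"}

    def test_sizing_error_names_feature(self):
        cfg = SimConfig(genome_length=[30_000], n_genes=10, n_enhancers=5)
        with pytest.raises(SizingError, match="too small"):
            simulate_genome(cfg)

    def test_genes_non_overlapping_same_strand(self):
        cfg = SimConfig(**SMALL)
        _, genes, _, _ = simulate_genome(cfg)
        by_strand = {}
        for g in genes:
            by_strand.setdefault((g.interval.chrom, g.interval.strand), []).append(g.interval)
        for ivs in by_strand.values():
            ivs.sort(key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_bound_enhancers_carry_planted_composite_motif(self):
        cfg = SimConfig(**SMALL)
        seqs, _, _, truth = simulate_genome(cfg)
        from tuscan.motifs import revcomp

        for e in truth.enhancers:
            if e.label in ("sensitive", "insensitive"):
                placements = truth.motif_placements[e.peak_id]
                (motif_id, off, strand), = placements
                found = seqs[e.chrom][off : off + len(SOXOCT_CONSENSUS)]
                if strand == "-":
                    found = revcomp(found)
                assert found == SOXOCT_CONSENSUS

    def test_se_clusters_at_least_two_members_within_12_5_kb(self):
        cfg = SimConfig(**SMALL, n_se=2)
        _, _, ses, truth = simulate_genome(cfg)
        membership = truth.se_membership
        for se in ses:
            members = [e for e in truth.enhancers if membership.get(e.peak_id) == se.id]
            assert len(members) >= 2
            span = max(e.summit for e in members) - min(e.summit for e in members)
            assert span <= 12_500


class TestDeterminism:
    def test_outputs_byte_identical(self, tmp_path):
        cfg = SimConfig(**SMALL)

        def run(subdir):
            seqs, genes, ses, truth = simulate_genome(cfg)
            tc = simulate_timecourse(cfg, truth, genes)
            out = tmp_path / subdir
            write_dataset(out, cfg, seqs, genes, ses, truth, tc)
            digests = {}
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    digests[str(p.relative_to(out))] = hashlib.md5(
                        p.read_bytes()
                    ).hexdigest()
            return digests

        assert run("a") == run("b")


class TestTimecourseSignalModel:
    @pytest.fixture(scope="class")
    def sim(self):
        cfg = SimConfig(**SMALL)
        seqs, genes, ses, truth = simulate_genome(cfg)
        tc = simulate_timecourse(cfg, truth, genes)
        return cfg, truth, tc

    def _expected_ratio(self, tc, assay, fid, t):
        exp = tc.expected[assay]
        d = tc.depth_factors
        s0 = [c for c in exp.columns if f"_dep_0h_r1" in c][0]
        st = [c for c in exp.columns if f"_dep_{t:g}h_r1" in c][0]
        return (exp.loc[fid, st] / d[st]) / (exp.loc[fid, s0] / d[s0])

    def test_independent_erna_flat_at_15h(self, sim):
        cfg, truth, tc = sim
        indep = [e for e in truth.enhancers if e.label == "independent" and e.transcribed]
        assert indep, "fixture must contain an independent transcribed enhancer"
        ratio = self._expected_ratio(tc, "tt", indep[0].peak_id + "_p", 15.0)
        assert ratio == pytest.approx(1.0)

    def test_occupancy_expectation_at_9h(self, sim):
        cfg, truth, tc = sim
        bound = [e for e in truth.enhancers if e.bound]
        ratio = self._expected_ratio(tc, "chip", f"chip_{bound[0].peak_id}", 9.0)
        assert ratio == pytest.approx(0.170)

    def test_sensitive_enhancer_keeps_accessibility_until_9h(self, sim):
        cfg, truth, tc = sim
        sens = [e for e in truth.enhancers if e.label == "sensitive"]
        assert sens, "fixture must contain a sensitive enhancer"
        fid = f"atac_{sens[0].peak_id}"
        assert self._expected_ratio(tc, "atac", fid, 6.0) == pytest.approx(1.0)
        assert self._expected_ratio(tc, "atac", fid, 9.0) < 1.0

    def test_insensitive_keeps_accessibility_loses_erna(self, sim):
        cfg, truth, tc = sim
        ins = [e for e in truth.enhancers if e.label == "insensitive" and e.transcribed]
        assert ins, "fixture must contain an insensitive transcribed enhancer"
        e = ins[0]
        assert self._expected_ratio(tc, "atac", f"atac_{e.peak_id}", 15.0) == pytest.approx(1.0)
        assert self._expected_ratio(tc, "tt", e.peak_id + "_p", 15.0) == pytest.approx(0.025)

    def test_erna_signal_bidirectional(self, sim):
        cfg, truth, tc = sim
        e = next(x for x in truth.enhancers if x.transcribed)
        frags = tc.fragments["tt_dep_0h_r1"]
        mids = (frags.start + frags.end) // 2
        left = (
            (frags.chrom == e.chrom)
            & (mids >= e.summit - cfg.erna_length)
            & (mids < e.summit)
        )
        right = (
            (frags.chrom == e.chrom)
            & (mids >= e.summit)
            & (mids < e.summit + cfg.erna_length)
        )
        assert (frags.strand[left] == "-").sum() > 20
        assert (frags.strand[right] == "+").sum() > 20

    def test_spike_expectation_constant_over_time(self, sim):
        cfg, truth, tc = sim
        d = tc.depth_factors
        corrected = tc.spike_counts / d[tc.spike_counts.index]
        # all chip samples share the biological expectation
        assert corrected.std() / corrected.mean() < 0.25

    def test_unbound_enhancers_have_no_occupancy_peak(self, sim):
        cfg, truth, tc = sim
        unbound = {e.peak_id for e in truth.enhancers if not e.bound}
        peak_ids = {p.id for p, _ in tc.chip_peaks}
        assert unbound.isdisjoint(peak_ids)

    def test_mean_recovery_across_features(self, default_bundle):
        tc = default_bundle.tc
        obs = np.concatenate([tc.counts[a].values.ravel() for a in tc.counts])
        exp = np.concatenate([tc.expected[a].values.ravel() for a in tc.expected])
        assert len(obs) >= 500
        ratio = obs.sum() / exp.sum()
        assert 0.95 <= ratio <= 1.05


class TestNbDraws:
    def test_poisson_limit_replicate_cv(self):
        rng = np.random.default_rng(0)
        mean = 10_000.0
        draws = nb_draws(rng, np.full(1000, mean), alpha=0.0)
        cv = draws.std() / draws.mean()
        assert cv < 0.05

    def test_dispersion_inflates_variance(self):
        rng = np.random.default_rng(1)
        a = nb_draws(rng, np.full(5000, 100.0), alpha=0.0)
        b = nb_draws(rng, np.full(5000, 100.0), alpha=0.3)
        assert b.var() > 2 * a.var()


class TestGroundTruthJson:
    def test_serialization_complete(self, tmp_path, default_bundle):
        path = tmp_path / "truth.json"
        default_bundle.truth.to_json(path)
        doc = json.loads(path.read_text())
        assert set(doc) == {
            "genome",
            "tu_intervals",
            "enhancer_labels",
            "enhancer_transcribed",
            "gene_response",
            "se_membership",
            "motif_placements",
        }
        assert len(doc["enhancer_labels"]) == default_bundle.cfg.n_enhancers
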