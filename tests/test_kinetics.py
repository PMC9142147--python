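"""Clustering, sensitivity taxonomy, pairing, enrichment and metagenes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tuscan.enhancers import EnhancerSite
from tuscan.intervals import GenomicInterval
from tuscan.kinetics import (
    cluster_early_late,
    consensus_peaks,
    down_in_any,
    first_down_time,
    fisher_enrichment,
    metagene,
    zscore_profiles,
)

TIMES = [0.0, 3.0, 6.0, 9.0, 12.0, 15.0]


def planted_trajectories(seed=0, n_per=200, noise=0.3):
    """Two trajectory prototypes (synthesis dropping at 6 h vs at 12 h),
    planted on the z-score scale with additive noise."""
    rng = np.random.default_rng(seed)
    early = np.array([1.0, 1.0, 0.15, 0.1, 0.1, 0.1])
    late = np.array([1.0, 1.0, 1.0, 1.0, 0.15, 0.1])
    rows, labels = [], []
    for proto, label in ((early, "early"), (late, "late")):
        z = (proto - proto.mean()) / proto.std()
        for _ in range(n_per):
            rows.append(z + rng.normal(0, noise, 6))
            labels.append(label)
    df = pd.DataFrame(rows, columns=TIMES, index=[f"f{i}" for i in range(2 * n_per)])
    return zscore_profiles(df), pd.Series(labels, index=df.index)


class TestClusterEarlyLate:
    def test_recovers_planted_groups(self):
        z, truth = planted_trajectories(seed=0)
        res = cluster_early_late(z, seed=0)
        acc = (res.labels == truth).mean()
        assert acc >= 0.95

    def test_order_invariant_partition(self):
        z, _ = planted_trajectories(seed=1)
        res1 = cluster_early_late(z, seed=0)
        shuffled = z.sample(frac=1.0, random_state=3)
        res2 = cluster_early_late(shuffled, seed=0)
        assert (res2.labels.reindex(res1.labels.index) == res1.labels).all()

    def test_identical_features_degenerate_warning(self):
        df = pd.DataFrame(np.ones((10, 6)), columns=TIMES)
        with pytest.warns(UserWarning):
            cluster_early_late(zscore_profiles(df), seed=0)

    def test_too_few_features_errors(self):
        df = zscore_profiles(pd.DataFrame(np.random.default_rng(0).normal(size=(3, 6)), columns=TIMES))
        with pytest.raises(ValueError):
            cluster_early_late(df, k=2, seed=0)

    def test_composition_reported(self):
        z, truth = planted_trajectories(seed=2, n_per=50)
        fst = pd.Series(
            np.where(truth == "early", 6.0, 12.0), index=truth.index
        )
        res = cluster_early_late(z, seed=0, first_sig_time=fst)
        assert res.composition is not None
        # early cluster dominated by 6 h first-significant calls
        assert res.composition.loc["early", 6.0] > 0.8


class TestSensitivityRules:
    def _site(self, pid, category="transcribed", ernas=("e1",)):
        return EnhancerSite(
            GenomicInterval("chr1", 100, 400, ".", pid),
            250,
            True,
            category,
            list(ernas),
        )

    def _results(self, calls):
        # calls: {feature: [call at each time]}
        out = {}
        for i, t in enumerate([3.0, 15.0]):
            out[t] = pd.DataFrame(
                {
                    "baseMean": 100.0,
                    "log2fc": 0.0,
                    "p": 1.0,
                    "padj": 1.0,
                    "call": {f: c[i] for f, c in calls.items()},
                }
            )
        return out

    def test_down_down_is_sensitive(self):
        from tuscan.kinetics import classify_sensitivity_transcribed

        s = self._site("p1")
        labels = classify_sensitivity_transcribed(
            [s],
            self._results({"e1": ["ns", "down"]}),
            self._results({"p1": ["down", "ns"]}),
        )
        assert labels["p1"] == "sensitive" and s.sensitivity == "sensitive"

    def test_erna_down_accessibility_up_is_insensitive(self):
        from tuscan.kinetics import classify_sensitivity_transcribed

        labels = classify_sensitivity_transcribed(
            [self._site("p1")],
            self._results({"e1": ["down", "down"]}),
            self._results({"p1": ["up", "up"]}),
        )
        assert labels["p1"] == "insensitive"

    def test_erna_stable_is_independent_even_if_accessibility_down(self):
        from tuscan.kinetics import classify_sensitivity_transcribed

        labels = classify_sensitivity_transcribed(
            [self._site("p1")],
            self._results({"e1": ["ns", "ns"]}),
            self._results({"p1": ["down", "down"]}),
        )
        assert labels["p1"] == "independent"

    def test_missing_site_treated_unchanged_with_warning(self):
        from tuscan.kinetics import classify_sensitivity_transcribed

        with pytest.warns(UserWarning, match="missing"):
            labels = classify_sensitivity_transcribed(
                [self._site("p1", ernas=("absent",))],
                self._results({"e1": ["down", "down"]}),
                self._results({"p1": ["ns", "ns"]}),
            )
        assert labels["p1"] == "independent"

    def test_nontranscribed_final_time_rule(self):
        from tuscan.kinetics import classify_sensitivity_nontranscribed

        stable = self._site("p1", category="nontranscribed", ernas=())
        falling = self._site("p2", category="nontranscribed", ernas=())
        res = self._results({"p1": ["ns", "ns"], "p2": ["ns", "down"]})
        labels = classify_sensitivity_nontranscribed([stable, falling], res, final_time=15.0)
        assert labels["p1"] == "insensitive" and labels["p2"] == "sensitive"

    def test_labels_partition_universe(self, default_bundle, default_diff):
        from tuscan import pipeline as pl
        from tuscan.classify import TranscriptionUnit
        from tuscan.config import PipelineConfig

        tf, diff = default_diff
        mrna_tus = [
            TranscriptionUnit(t, "mRNA", 0.0, gene_id=t.id)
            for t in default_bundle.truth.tu_intervals
            if default_bundle.truth.tu_classes[t.id] == "mRNA"
        ]
        res = pl.run_classify(PipelineConfig(), default_bundle, tf.sites, diff, mrna_tus)
        n_t = sum(1 for s in tf.sites if s.category == "transcribed")
        n_nt = sum(1 for s in tf.sites if s.category == "nontranscribed")
        assert len(res.sensitivity_transcribed) == n_t
        assert len(res.sensitivity_nontranscribed) == n_nt
        assert set(res.sensitivity_transcribed.unique()) <= {
            "sensitive",
            "insensitive",
            "independent",
        }
        assert set(res.sensitivity_nontranscribed.unique()) <= {"sensitive", "insensitive"}


class TestDownHelpers:
    def test_union_and_first_time(self):
        res = {
            3.0: pd.DataFrame({"call": ["ns", "down"]}, index=["a", "b"]),
            15.0: pd.DataFrame({"call": ["down", "ns"]}, index=["a", "b"]),
        }
        down = down_in_any(res)
        assert down["a"] and down["b"]
        fst = first_down_time(res)
        assert fst["a"] == 15.0 and fst["b"] == 3.0


class TestPairSeGenes:
    def test_pair_rules(self, default_bundle, default_diff):
        from tuscan import pipeline as pl
        from tuscan.classify import TranscriptionUnit
        from tuscan.kinetics import down_in_any, pair_se_genes

        tf, diff = default_diff
        mrna_tus = [
            TranscriptionUnit(t, "mRNA", 0.0, gene_id=t.id)
            for t in default_bundle.truth.tu_intervals
            if default_bundle.truth.tu_classes[t.id] == "mRNA"
        ]
        from tuscan.enhancers import annotate_se

        annotate_se(tf.sites, default_bundle.se_intervals)
        pairs = pair_se_genes(
            tf.sites, default_bundle.se_intervals, diff.erna, diff.mrna, mrna_tus
        )
        gene_down = down_in_any(diff.mrna)
        for p in pairs:
            assert bool(gene_down[p.gene_id])  # only down genes are kept

    def test_fold_change_is_one_at_time_zero(self, default_bundle, default_diff):
        from tuscan.kinetics import fold_change_vectors

        tf, diff = default_diff
        norm = diff.mrna_cm.normalized()
        fc = fold_change_vectors(
            norm, diff.mrna_cm.meta, norm.index[0], TIMES, "tt"
        )
        assert fc[0.0] == pytest.approx(1.0)


class TestFisher:
    def test_zero_successes_upper_tail_is_one(self):
        _, p = fisher_enrichment(0, 10, 50, 100)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_rejects_non_integers(self):
        with pytest.raises(ValueError):
            fisher_enrichment(1.5, 10, 50, 100)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n_bg = int(rng.integers(5, 25))
            k_bg = int(rng.integers(1, n_bg + 1))
            n_fg = int(rng.integers(1, n_bg + 1))
            k_fg = int(rng.integers(0, min(k_bg, n_fg) + 1))
            # enumerate all draws of n_fg items from the background
            hits = 0
            total = 0
            for combo in itertools.combinations(range(n_bg), n_fg):
                total += 1
                k = sum(1 for c in combo if c < k_bg)
                if k >= k_fg:
                    hits += 1
            _, p = fisher_enrichment(k_fg, n_fg, k_bg, n_bg)
            assert p == pytest.approx(hits / total, rel=1e-9)

    def test_no_overflow_at_large_population(self):
        _, p = fisher_enrichment(600, 1000, 500_000, 1_000_000)
        assert 0.0 <= p <= 1.0 and math.isfinite(p)


class TestMetagene:
    GENOME = {"chr1": 100_000}

    def test_rpm_arithmetic_at_delta_peak(self):
        frags = [GenomicInterval("chr1", 50_000 - 100, 50_000 + 100, "+")] * 10
        mat, mean = metagene(
            frags, [("chr1", 50_000, "+")], self.GENOME, halfwidth=2000,
            total_fragments=1_000_000,
        )
        assert mean[2000] == pytest.approx(10.0)  # 10 reads -> 10 RPM
        assert np.nansum(mean) == pytest.approx(10.0)

    def test_anchor_order_irrelevant(self):
        rng = np.random.default_rng(1)
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 200, "+")
            for s in rng.integers(0, 90_000, 500)
        ]
        anchors = [("chr1", int(p), "+") for p in rng.integers(5_000, 90_000, 20)]
        _, m1 = metagene(frags, anchors, self.GENOME)
        _, m2 = metagene(frags, anchors[::-1], self.GENOME)
        np.testing.assert_allclose(m1, m2)

    def test_mean_matches_per_site_extraction(self):
        rng = np.random.default_rng(2)
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 200, "+")
            for s in rng.integers(0, 90_000, 300)
        ]
        anchors = [("chr1", int(p), "+") for p in rng.integers(5_000, 90_000, 10)]
        mat, mean = metagene(frags, anchors, self.GENOME, halfwidth=500)
        cov = np.zeros(100_000)
        for f in frags:
            cov[(f.start + f.end) // 2] += 1
        rows = [cov[p - 500 : p + 500] for _, p, _ in anchors]
        expected = np.mean(rows, axis=0) / (len(frags) / 1e6)
        np.testing.assert_allclose(mean, expected)

    def test_minus_strand_anchor_flipped(self):
        frags = [GenomicInterval("chr1", 50_900, 51_100, "+")] * 3  # +1 kb of anchor
        _, plus = metagene(frags, [("chr1", 50_000, "+")], self.GENOME)
        _, minus = metagene(frags, [("chr1", 50_000, "-")], self.GENOME)
        assert plus[3000] > 0 and minus[999] > 0


class TestConsensusPeaks:
    def _peaks(self, spans):
        return [GenomicInterval("chr1", s, e, ".", f"p{i}") for i, (s, e) in enumerate(spans)]

    def test_disjoint_sets_empty(self):
        assert consensus_peaks(self._peaks([(0, 100)]), self._peaks([(200, 300)])) == []

    def test_identical_sets_all_retained(self):
        a = self._peaks([(0, 100), (500, 700)])
        assert consensus_peaks(a, a) == a

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = self._peaks([(int(s), int(s) + 300) for s in rng.integers(0, 50_000, 40)])
        b = self._peaks([(int(s), int(s) + 300) for s in rng.integers(0, 50_000, 40)])
        got = consensus_peaks(a, b)
        expected = [
            p
            for p in a
            if any(min(p.end, q.end) - max(p.start, q.start) > 0 for q in b)
        ]
        assert got == expected
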