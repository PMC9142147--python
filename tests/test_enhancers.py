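"""Enhancer annotation: eRNA calling, peak partitioning, SE membership."""

import numpy as np
import pytest

from tuscan.classify import TranscriptionUnit
from tuscan.enhancers import (
    annotate_se,
    call_putative_ernas,
    classify_binding_sites,
    nearest_active_gene,
)
from tuscan.intervals import GenomicInterval


def tu(start, end, cls, strand="+", gid=None, chrom="chr1", name=None):
    iv = GenomicInterval(chrom, start, end, strand, name or f"{cls}_{start}")
    return TranscriptionUnit(iv, cls, 50.0, gene_id=gid)


class TestCallPutativeErnas:
    def test_promoter_proximal_excluded(self):
        inc = tu(10_000, 10_700, "incRNA")
        gene = tu(11_600, 20_000, "mRNA", gid="g1")  # 900 bp gap
        assert call_putative_ernas([inc, gene]) == []

    def test_distal_retained(self):
        inc = tu(10_000, 10_700, "incRNA")
        gene = tu(12_000, 20_000, "mRNA", gid="g1")  # 1300 bp gap
        loci = call_putative_ernas([inc, gene])
        assert len(loci) == 1

    def test_divergent_pair_merges_strand_blind(self):
        a = tu(10_000, 10_700, "incRNA", strand="-")
        b = tu(11_500, 12_200, "incRNA", strand="+")  # 800 bp apart
        loci = call_putative_ernas([a, b])
        assert len(loci) == 1
        assert set(loci[0].members.values()) == {"+", "-"}

    def test_order_invariant(self):
        rng = np.random.default_rng(3)
        tus = []
        for i, s in enumerate(rng.integers(0, 200_000, 60)):
            cls = ["incRNA", "asRNA"][i % 2]
            strand = "+" if i % 3 else "-"
            tus.append(tu(int(s), int(s) + 600, cls, strand=strand, name=f"n{i}"))
        fwd = call_putative_ernas(tus)
        rev = call_putative_ernas(tus[::-1])
        assert [(l.interval.start, l.interval.end) for l in fwd] == [
            (l.interval.start, l.interval.end) for l in rev
        ]

    def test_matches_single_linkage_clustering(self):
        rng = np.random.default_rng(4)
        starts = np.sort(rng.integers(0, 300_000, 80))
        tus = [tu(int(s), int(s) + 500, "incRNA", name=f"n{i}") for i, s in enumerate(starts)]
        loci = call_putative_ernas(tus)
        # brute-force single linkage at gap <= 1000
        clusters = 1
        for prev, nxt in zip(starts[:-1], starts[1:]):
            if (nxt - (prev + 500)) > 1000:
                clusters += 1
        assert len(loci) == clusters


def make_peak(start, end, pid, summit=None):
    iv = GenomicInterval("chr1", start, end, ".", pid)
    return (iv, summit if summit is not None else (start + end) // 2)


class TestClassifyBindingSites:
    OPEN = [GenomicInterval("chr1", 0, 100_000)]

    def _ernas(self, *spans):
        from tuscan.enhancers import EnhancerLocus

        return [
            EnhancerLocus(GenomicInterval("chr1", s, e, ".", f"eRNA_{i}"), {})
            for i, (s, e) in enumerate(spans)
        ]

    def test_open_peak_near_erna_is_transcribed(self):
        peaks = [make_peak(10_000, 10_300, "p1")]
        sites = classify_binding_sites(peaks, self.OPEN, self._ernas((10_800, 11_500)), [])
        assert sites[0].category == "transcribed"
        assert sites[0].erna_ids == ["eRNA_0"]

    def test_closed_peak_excluded(self):
        peaks = [make_peak(200_000, 200_300, "p1")]
        sites = classify_binding_sites(peaks, self.OPEN, [], [])
        assert sites[0].category == "closed" and not sites[0].open

    def test_mrna_overlap_class(self):
        peaks = [make_peak(10_000, 10_300, "p1")]
        gene = tu(10_200, 20_000, "mRNA", gid="g1")
        sites = classify_binding_sites(peaks, self.OPEN, [], [gene])
        assert sites[0].category == "mrna"

    def test_erna_precedence_over_mrna(self):
        peaks = [make_peak(10_000, 10_300, "p1")]
        gene = tu(10_200, 20_000, "mRNA", gid="g1")
        sites = classify_binding_sites(
            peaks, self.OPEN, self._ernas((10_400, 11_000)), [gene]
        )
        assert sites[0].category == "transcribed"

    def test_partition_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(5)
        peaks = [
            make_peak(int(s), int(s) + 300, f"p{i}")
            for i, s in enumerate(rng.integers(0, 250_000, 100))
        ]
        open_r = [GenomicInterval("chr1", 0, 120_000)]
        ernas = self._ernas(*[(int(s), int(s) + 700) for s in rng.integers(0, 250_000, 20)])
        genes = [tu(int(s), int(s) + 8000, "mRNA", gid=f"g{i}") for i, s in enumerate(rng.integers(0, 250_000, 10))]
        sites = classify_binding_sites(peaks, open_r, ernas, genes)
        assert len(sites) == len(peaks)
        from collections import Counter

        counts = Counter(s.category for s in sites)
        assert sum(counts.values()) == len(peaks)
        assert set(counts) <= {"transcribed", "mrna", "nontranscribed", "closed"}

    def test_missing_summit_defaults_to_midpoint(self):
        peaks = [(GenomicInterval("chr1", 100, 300, ".", "p1"), None)]
        with pytest.warns(UserWarning, match="summit"):
            sites = classify_binding_sites(peaks, self.OPEN, [], [])
        assert sites[0].summit == 200

    def test_simulation_class_counts_match_truth(self, default_bundle, default_annotation):
        bundle = default_bundle
        peaks = [(p, s) for p, s in bundle.tc.chip_peaks]
        open_r = bundle.tc.open_regions
        sites = classify_binding_sites(
            peaks, open_r, default_annotation.erna_loci, default_annotation.mrna_tus
        )
        truth_t = sum(1 for e in bundle.truth.enhancers if e.bound and e.transcribed)
        truth_nt = sum(1 for e in bundle.truth.enhancers if e.bound and not e.transcribed)
        got_t = sum(1 for s in sites if s.category == "transcribed")
        got_nt = sum(1 for s in sites if s.category == "nontranscribed")
        assert got_t == truth_t
        assert got_nt == truth_nt
        # every unbound enhancer is absent from the peak universe
        unbound = {e.peak_id for e in bundle.truth.enhancers if not e.bound}
        assert unbound.isdisjoint({s.id for s in sites})


class TestAnnotateSe:
    def test_membership_and_summary(self):
        from tuscan.enhancers import EnhancerSite

        se = [GenomicInterval("chr1", 10_000, 20_000, ".", "se1")]
        sites = [
            EnhancerSite(GenomicInterval("chr1", 11_000, 11_300, ".", "p1"), 11_150, True, "transcribed", ["e1"]),
            EnhancerSite(GenomicInterval("chr1", 12_000, 12_300, ".", "p2"), 12_150, True, "transcribed", ["e2"]),
            EnhancerSite(GenomicInterval("chr1", 13_000, 13_300, ".", "p3"), 13_150, True, "nontranscribed"),
            EnhancerSite(GenomicInterval("chr1", 14_000, 14_300, ".", "p4"), 14_150, True, "nontranscribed"),
            EnhancerSite(GenomicInterval("chr1", 50_000, 50_300, ".", "p5"), 50_150, True, "transcribed", ["e3"]),
        ]
        summary = annotate_se(sites, se)
        assert sites[0].se_id == "se1" and sites[4].se_id is None
        row = summary.iloc[0]
        assert (row.n_transcribed, row.n_mrna, row.n_nontranscribed) == (2, 0, 2)


class TestNearestActiveGene:
    GENES = [
        tu(10_000, 20_000, "mRNA", gid="gA"),  # TSS 10 000
        tu(30_000, 40_000, "mRNA", gid="gB"),  # TSS 30 000
    ]

    def test_summit_at_tss(self):
        gid, d = nearest_active_gene("chr1", 10_000, self.GENES)
        assert (gid, d) == ("gA", 0)

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        gid, d = nearest_active_gene("chr1", 20_000, self.GENES)
        assert (gid, d) == ("gA", 10_000)

    def test_empty_chromosome_sentinel(self):
        assert nearest_active_gene("chrX", 5_000, self.GENES) == (None, None)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        genes = [
            tu(int(s), int(s) + 5_000, "mRNA", gid=f"g{i}", strand=("+" if i % 2 else "-"))
            for i, s in enumerate(rng.integers(0, 500_000, 40))
        ]
        for summit in rng.integers(0, 500_000, 25):
            gid, d = nearest_active_gene("chr1", int(summit), genes)
            brute = min(
                (abs(int(summit) - g.tss), g.tss, g.gene_id) for g in genes
            )
            assert (gid, d) == (brute[2], brute[0])
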