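# Methods

This note documents the models, estimators and numerical choices behind
`tuscan`, and what the synthetic-data generator does and does not emulate.

## Genome segmentation

Coverage is summarized per strand as fragment-midpoint counts in
consecutive 200 bp bins (all samples pooled; a pseudo-count of 1 is added
to every bin for the emission model, and removed again for any RPK
computation). The bin counts are modelled by a two-state hidden Markov
chain with Poisson–log-normal (PLN) emissions: in state *s* a bin count is
Poisson(λ) with log λ ~ N(μ_s, σ_s²). The PLN marginal is over-dispersed
and heavy-tailed, which is essential for nascent-RNA coverage — a plain
Poisson HMM fragments highly expressed gene bodies because their bin-count
variance far exceeds the mean. State 1 ("transcribed") is, by convention,
the state with the larger marginal mean exp(μ + σ²/2); the fit reorders
states to enforce this.

**Emission marginal.** The PLN pmf has no closed form. It is evaluated by
adaptive Gauss–Hermite quadrature: for each count *k* the integrand's mode
x̂ (solving k − e^x − (x−μ)/σ² = 0) is found by Newton iteration and the
64-node Hermite grid is centred at x̂ and scaled to the local curvature
(e^x̂ + 1/σ²)^(−1/2). A fixed grid at (μ, σ) loses accuracy as soon as *k*
pulls the posterior away from the prior; the adaptive grid is accurate to
near machine precision across counts and σ (the suite checks it against
10⁵-step numeric integration at 1e-8), remains finite for counts up to
10⁶, and reduces cleanly to the Poisson pmf as σ → 0.

**Fitting.** Baum–Welch with a scaled forward–backward pass. Transition
and initial-state updates are the standard closed forms; the emission
M-step has no closed form and is solved by Nelder–Mead on (μ, log σ) with
a generalized-EM guard (parameters are kept when the optimizer fails to
improve), so the log-likelihood is non-decreasing across iterations.
Initialization is k-means (k = 2) on log counts, σ = 0.5, self-transition
0.99: reproducible and scale-free. Fitting stops when |Δ log L| < 1e-3
(default) or after 50 iterations. All-constant coverage converges
immediately and is flagged degenerate.

**Decoding and refinement.** Viterbi by default (posterior > 0.5 decoding
is available behind a flag). Maximal runs of state 1 become segments;
segments below the minimal expression (RPK, computed from raw midpoint
counts without pseudo-counts) are dropped. Segment borders are then
sharpened on per-bp pooled midpoint coverage: within the four bins centred
on each initial border, the changepoint minimizing the SSE of the best
two-level step function is selected, ties broken toward the initial
border and then toward the lower coordinate.

## TU classification

A segment joins an annotated gene when, on the same strand, at least 20 %
of its length lies inside the gene body *and* it overlaps an annotated
exon; all segments of one gene merge into a single TU. A segment
qualifying for several genes goes to the larger body overlap, ties to the
nearer TSS (a determinism rule, not a biological claim). Remaining
segments are ncRNA: same-strand ncRNAs one bin (200 bp) or closer are
merged; TUs whose promoter (TSS ± 1 kb, half-open) misses every
accessibility peak are removed; and TUs below the minimal RPK are removed.

The default minimal RPK is 26.5. Because that cutoff was originally
derived by optimization, the package also offers `threshold_from_openness`:
the RPK threshold maximizing Youden's J for discriminating open- from
closed-promoter TUs on the log-RPK scale, returning the geometric midpoint
of the optimal interval (the J objective is this package's choice of
decision rule; on two well-separated log-normal RPK groups with equal
spread it recovers the equal-likelihood crossing of the two densities).

ncRNA classes follow TSS geometry relative to mRNAs on the opposite
strand. With *d* the TSS-to-TSS offset in the sense gene's orientation
(positive = downstream): uaRNA for −1 kb < d < 0, conRNA for 0 ≤ d < 1 kb,
asRNA for d > 1 kb, incRNA otherwise. The rules only apply when the ncRNA
TSS lies within the mRNA body extended 1 kb upstream — without that scope
bound, any distal ncRNA would become the asRNA of some far-away gene. The
inequalities are strict, so d exactly +1 kb falls through to incRNA. When
several mRNAs qualify, the nearest TSS governs.

## Enhancer annotation

Putative eRNAs start from asRNA and incRNA; any unit within 1 kb
(edge-to-edge, strand-blind) of a promoter-related TU (mRNA, uaRNA,
conRNA) is dropped, and the survivors are merged strand-blind within 1 kb.
TF-occupancy peaks partition with precedence eRNA > mRNA > nontranscribed:
peaks not overlapping open chromatin are "closed" and leave the analysis;
open peaks within 1 kb of an eRNA locus are transcribed enhancers; open
peaks overlapping an mRNA TU are mRNA-associated; the rest are
nontranscribed enhancers. Distances anchor on the ChIP peak edges
(0 when overlapping) — the permissive reading; summit anchoring is a
one-line change at the call site. SE membership is a ≥1 bp overlap with a
supplied superenhancer interval; sites outside SEs are typical enhancers.

## Normalization and differential testing

Size factors are median-of-ratios on an anchor feature set: factor_j =
median over anchors of count_ij / (geometric mean of feature i across
samples), anchors with any zero excluded, the median taken on the ratio
scale. Nascent-RNA features anchor on protein-coding genes; accessibility
anchors on promoter peaks of expression-stable genes (|log2FC| < 0.25 and
padj > 0.5 at every depletion time point — if no gene survives that
filter, all promoter peaks are used, with a warning). Occupancy samples
are scaled by spike-in totals, factor_j = total_j / min_k total_k.

Each time point is tested against 0 h with a two-group NB exact test on
size-factor-normalized group sums: the sum of n iid NB(q, α) counts is
NB(nq, α/n), and conditional on the total the p-value sums the
probabilities of all splits no more likely than the observed one. This is
a deliberate, self-contained approximation to a GLM-based Wald test;
individual feature calls need not match heavier machinery, and the suite
pins down its distributional behaviour instead (null rejection rate,
near-uniform null p in the small-dispersion limit, power on planted
4-fold drops).

**Dispersion.** Per feature, a moment estimate α̂ = max(0, (s² − m̄)/m̄²)
with s² the pooled within-group variance, shrunk toward a mean–dispersion
trend α_tr(m) = a₀ + a₁/m fitted by least squares on the *unclipped*
moment estimates (fitting on clipped values biases the trend upward near
the Poisson limit). The shrinkage weight is precision-dependent
(empirical-Bayes): w = τ²/(τ² + sd_i²), with sd_i ≈ α_tr + 1/m̄ the
approximate sampling sd of a two-replicate moment estimate and τ² the
excess between-feature variance of the estimates around the trend. With
two replicates per group the estimates carry one degree of freedom per
group and their noise dominates; a fixed-weight blend passes that noise
straight into the test and visibly inflates the null rejection rate,
whereas the adaptive weight collapses homogeneous data onto the trend
while retaining per-feature signal when dispersions genuinely vary.

BH adjustment is applied within each contrast; calls use padj < 0.01. The
log2 fold change is log2((m̄_t + 0.5)/(m̄_0 + 0.5)) on normalized means. A
feature with zero counts in both groups gets p = 1. PCA uses
log2(count/size factor + 1) on the 500 most variable features, centred,
via SVD, with each component's sign fixed so its largest-magnitude loading
is positive.

## Kinetics and the sensitivity taxonomy

Trajectories are replicate-merged (summed) normalized counts per time
point, z-scored per feature (constant features become all-zero with a
warning). k-means uses 25 restarts with a fixed seed; the cluster whose
mean trajectory first crosses z = −0.5 at the earlier time point is
"early" — a heuristic standing in for labelling clusters by inspection.

"Down" for classification means called down in at least one depletion
contrast (the union rule). Transcribed enhancers: sensitive = eRNA down
and accessibility down; insensitive = eRNA down, accessibility not down;
independent = eRNA not down regardless of accessibility. Nontranscribed
enhancers: sensitive iff accessibility is down at the final (15 h)
depletion time point. Sites missing from a result table count as
unchanged, with a warning.

SE–gene pairing: an SE is transcriptionally down iff ≥1 member eRNA is
down; its partner is the nearest transcribed gene from the SE midpoint
(|summit − TSS|, ties to the lower coordinate); pairs whose gene is not
down are dropped. Fold-change vectors are replicate-merged normalized
counts relative to 0 h (≡ 1 at 0 h).

Fisher enrichment is the upper-tail hypergeometric probability
P(X ≥ k_fg) with the background population including the foreground;
the reported odds ratio is the sample (cross-product) odds ratio.
Metagene profiles are per-bp midpoint coverage around anchors in reads
per million, minus-strand anchors flipped, out-of-chromosome positions
masked rather than zero-filled.

## Motif scanning

A PFM becomes a log2-odds matrix against the background (uniform by
default, pseudocount 0.1 distributed by background weight), discretized
onto an integer grid at 1/1000 of the total score range. The exact null
distribution of the integer score is built by convolving per-position
histograms under the background; a window is a hit iff the tail
probability of its integer score is ≤ 1e-4 (the conventional scanning
default). The discretized DP is bit-for-bit identical to enumerating all
4^w words because every probability involved is a dyadic rational under
the uniform background. Both strands are scanned; the reverse strand gets
its own distribution (identical under a symmetric background). Windows
containing N at a motif position are skipped; a zero-information matrix is
flagged degenerate and can never produce hits. Percent occurrence per
region class is the fraction of summit ± 500 bp windows with ≥1 hit.

## The synthetic-data generator

The generator plants a study whose statistical structure matches what the
downstream analysis assumes, with full ground truth:

* **Layout.** Single-exon genes (4–12 kb, alternating strands) and
  enhancers are placed as shuffled blocks with ≥3–4 kb margins on random
  sequence; superenhancers are clusters of ≥2 enhancers 4 kb apart, placed
  ~10 kb from a gene that is forced early-downregulated (the planted
  SE-controlled genes). Sensitive and insensitive enhancers carry one
  SoxOct-composite consensus instance at the summit, on a random strand.
* **Classes.** Enhancers are sensitive / insensitive / independent /
  unbound by a largest-remainder allocation of the configured mix
  (default 0.25/0.25/0.35/0.15); a configurable fraction (default 0.3) of
  non-SE sensitive/insensitive sites is nontranscribed — bound peaks
  without eRNA, needed to exercise the nontranscribed taxonomy. Unbound
  enhancers are transcribed but have no occupancy peak.
* **Signals.** Gene signal is uniform over the body; eRNA signal is two
  divergent 700 bp units (the field's median eRNA length) around the
  summit. Occupancy and eRNA at sensitive/insensitive enhancers follow the
  measured chromatin-bound TF decay (100/87.5/50.5/17.0/7.0/2.5 % at
  0–15 h); accessibility at sensitive enhancers decays late
  (1/1/1/0.6/0.3/0.2), encoding the delayed accessibility loss, and
  recovers strongly after washout (0.8/0.95 at 4.5/9 h) while eRNA
  recovers only weakly (0.1/0.2) — the generator's depiction of partial
  recovery. Early-down genes drop from 3–6 h, late-down from 12 h.
* **Counts.** Feature counts are NB(mean = rate × multiplier × per-sample
  depth factor, dispersion α = 0.05 by default; Poisson when α → 0).
  Depth factors are log-normal (sd 0.15) and apply to everything in a
  sample, including spike-ins, whose biological expectation is constant.
  Low-rate uniform background fragments (2 per kb per strand per sample)
  cover the genome so segmentation has noise to reject. Fragment lengths
  are uniform 150–250 bp; midpoints are uniform within the feature
  (Gaussian around the summit for occupancy).
* **Determinism.** Everything derives from one seed; identical
  configurations write byte-identical files.

**What it does not emulate** — and hence what passing tests do not show
about real data: realistic sequence composition and mappability, GC and
fragment-length biases, PCR duplicates, multi-exon splicing structure,
overlapping or nested genes, chromatin-state heterogeneity, and
biological variability beyond NB dispersion. Recovery scores on this
generator certify the pipeline's logic, not its field performance.

## Problem sizes and seeds

The test suite and the acceptance script use: a 2 Mb genome with 50 genes
and 40 enhancers for segmentation recovery; a 6 Mb genome with 80 genes
and 400 enhancers (balanced class mix, ~100 per class) for
sensitivity-classification recovery; 5 000-feature 2 vs 2 null and power
simulations for test calibration; 200 + 200 planted z-scale trajectories
(drop at 6 h vs 12 h, noise sd 0.3) for clustering; and ≤10-bin toys for
the exact-decoding and enumeration oracles. The near-Poisson calibration
check runs at mean 400, where the exact test's discreteness atoms
(≈ (2/πT)^(1/2) at total T) are well below the tolerance being tested.
All stochastic stages take explicit seeds.

## Known limitations

* The NB exact test supports exactly two groups; no GLM designs, fold-
  change shrinkage, outlier filtering or independent filtering.
* Segmentation is strictly two-state; closely spaced same-strand TUs
  separated by shallow dips may fuse (the ncRNA merge step is tuned for
  this direction, not the reverse).
* The eRNA/peak linkage is purely positional (1 kb); no signal-weighted
  assignment.
* Blacklist filtering is available only as an optional BED input.
* `overlap` and the nearest-gene scan are O(n·m) per chromosome pair with
  a sorted-start cutoff — fine at annotation scale (10⁴–10⁵ intervals),
  not tuned for whole-genome base-pair interval joins.
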