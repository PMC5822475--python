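# Methods

## Scope and data model

All coordinates are 0-based half-open; GFF3 input is converted at the
parsing boundary and a TSS position `p` is the interval `[p, p+1)`.
Coverage is held as dense per-base arrays per chromosome (stranded tracks
hold a +/− pair); overlapping bedGraph records are summed, which is also
how replicates are merged by addition. These conventions are fixed so that
no module ever reinterprets coordinates. Inputs are assumed to be already
aligned and reduced to per-nucleotide 5′-end counts; alignment, duplicate
handling and peak calling from raw reads are out of scope.

## Normalization and thresholding

Spike-in normalization is the double geometric mean: `N_ti =
R_ti / gm_i(R_ti)` per transcript, `S_i = gm_t(N_ti)` per replicate.
Transcript rows containing any zero are excluded (a zero makes the row
geometric mean degenerate); if no all-positive row exists the computation
fails loudly rather than guessing. The scheme's two invariants —
row-geomean(N) = 1 and ∏S_i = 1 — are asserted in tests to 1e-9.

The per-nucleotide calling threshold defaults to the operating point of
9 normalized reads per nucleotide per replicate. A derivation path is also
provided: a genome-wide Poisson background with rate = total normalized
signal / effective genome size (non-zero positions unless a size is
given), returning the smallest integer count at which expected false
positive nucleotides / observed nucleotides falls below the target FDR
(default 0.05), maximized over replicates. The Poisson background is a
modelling choice — the count distribution is overdispersed in real data,
so the derived cutoff is approximate and the override is the default.

## Cluster calling

A nucleotide qualifies only when it meets the threshold in **every**
replicate. Qualifying nucleotides at most `chain_dist` (default 5 nt)
apart are chained into one cluster — equivalently, clusters are the
connected components of the |Δpos| ≤ chain_dist graph, computed by a
sorted gap scan and verified in tests against an O(n²) connected-
components oracle. Cluster signal is the replicate-summed normalized count
at member nucleotides; width spans first to last member (so internal
sub-threshold gaps are counted into the width); the summit is the
max-signal member with ties broken leftmost for determinism; summit_prop
is the signal fraction within ±2 nt of the summit. Strands are processed
independently end-to-end.

## Catalog statistics

* **Shape Index**: SI = 2 + Σ p_i log2 p_i with p_i over member
  nucleotides only (not the full span); zero-signal members are excluded
  from the sum; zero-total clusters are an error. SI ≤ 2 always, with
  equality iff a single nucleotide carries all signal.
* **Shape classes**: single (width 1), peaked (width < 12 nt), broad
  (width ≥ 12 nt and top-nucleotide fraction > 0.5), weak (width ≥ 12 nt
  otherwise). Width exactly 12 is assigned to the broad/weak side so
  "peaked" stays strictly below 12. Width-1 clusters are kept as their own
  class because the published class fractions are quoted among TSSs
  broader than one nucleotide.
* **Pausing Index**: cluster signal / gene RPKM, with RPKM over the gene
  span on the gene's strand from pooled replicates. RPKM = 0 yields an
  undefined-flagged PI; the record is retained but excluded from quantile
  partitions.
* **obsTSS/nuTSS assignment**: same-strand overlap with any annotated
  first exon makes a cluster an obsTSS; overlap with several genes is
  resolved to the nearest first-exon 5′ end from the cluster summit. The
  dominant TSS per gene is the record whose summit nucleotide carries the
  most signal (5′-most on ties).
* **Quantile partition**: rank-based near-equal bins, ties split by stable
  input order, so the partition is invariant under monotone relabeling.

## Motif scanning

Motifs are data, not code: a packaged table of named IUPAC consensi with
strand-oriented windows relative to the TSS (TATA −50..0; INR/TCT
−25..+25; DPE/MTE/PB/DCE 0..+50; GAGA/DRE/E-box and other distal elements
−250..0 or −100..0). Only the TATA window is anchored by an external
expectation; the others are declared defaults that users can override with
their own table. Scoring slides the consensus over the window sequence,
keeps offsets with ≤ 4 mismatches (IUPAC-aware), and scores each as a
log-odds sum against background using a PWM in which the consensus bases
share probability 0.97 (degenerate codes split it equally; fully
degenerate columns are uniform). TSSs without any qualifying offset are
floor-imputed with the motif's minimum detected score before z-scoring
(Z = (X − μ)/σ per motif), which preserves each column's minimum by
construction. Scores are not comparable to any external scanner's absolute
values; only their ranking and z-scores are used. TSS-by-motif profiles
are clustered agglomeratively (Euclidean, complete linkage, default k = 3)
over TSSs whose dominant peak exceeds 100 normalized reads.

## Directionality

Sense fraction is sense/(sense+antisense) 5′ signal in a ±200 nt window,
undefined when the window is empty. Pairing: each TSS's nearest
neighbouring TSS (summit distance, same chromosome) is found; opposite-
strand pairs become candidates, which are accepted greedily by increasing
distance so each TSS joins at most one pair and the result is independent
of input order and symmetric under genome mirroring. Geometry is divergent
when the minus-strand member lies to the left of the plus-strand member
(transcription outward), convergent otherwise. A pair is retained when
|summit distance| ≤ 200 nt and every base between the summits has ATAC
signal ≥ `ndr_floor` — the operational reading of "one continuous shared
NDR", with the floor defaulting to the genome-wide median of nonzero ATAC
signal so it adapts to the track's depth. Divergent obsTSS pairs of
distinct genes are bidirectional promoters. Group ATAC contrasts use
Wilcoxon rank-sum tests with BH adjustment.

## Chromatin classification

PTM profiles are log2((ChIP + 1)/(input + 1)) window sums (±200 nt) for
H3K4me1, H3K4me3, H3K27ac, H3K36me3. Ward/Euclidean hierarchical
clustering is cut at every k in 2..15; k is chosen as the smallest
candidate whose WSS reduction to k+1, relative to the total sum of
squares, falls below 0.1. Normalizing by the total rather than the current
WSS matters: with well-separated classes the current-WSS ratio stays large
long past the elbow because splitting a tight cluster still halves its own
small WSS. Labels come from centroid rules — a mark is "high" when its
centroid exceeds the across-cluster median by 0.5 log2 units; K4me3-high →
TSS-like, else K36me3-high → Coding, else K4me1 and K27ac high →
Enhancer-like, else Featureless.

The elongation decision (downstream vs. upstream stranded RNA-seq reads in
200 nt windows) uses a two-sided exact binomial test against 0.5 with BH
adjustment and a signed −log10(adjusted p). This replaces a two-window
negative-binomial contrast: with one observation per window per TSS there
is no dispersion to estimate, and conditioning on the window total gives
an exact test with the same decision structure (direction + adjusted
significance).

The enhancer-overlap null re-places every feature uniformly at random
(chromosome drawn proportional to length, position uniform; a
same-chromosome mode is available), and the empirical p-value uses the
add-one rule so it is never zero and is valid (stochastically ≥ uniform
under the null). No mappability or blacklist exclusion is applied. The
presence metaplot binarizes signal per base in a ±2 kb window, averages
per 10 nt bin across anchors, and divides by the group's median bin value
(pseudocount 1/(n·bin) when the median is zero).

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes,
with full ground truth: genes on a ≥ 2-chromosome gap-free genome placed
on a round-robin slot layout (2.5 kb spacing); per-gene shape archetypes
(peaked 5 nt with ≥ 80 % of signal within ±2 nt of the summit; broad 15 nt
with 55 % in the top nucleotide; weak 15 nt with 20 %) mixed 0.8/0.1/0.1
by default; paused genes (25 %) with 3× initiation and 0.15× elongation;
divergent pairs at 60–180 nt spacing and convergent pairs at 100–200 nt
(convergent wider, matching the observed ordering) inside planted ATAC
NDRs; novel TSSs in four chromatin classes with mark-specific ChIP
enrichment; enhancers of which half carry a planted eRNA start; and
spike-ins with per-replicate true factors of geometric mean 1.

Counts are negative binomial around the archetype expectation (variance
μ + αμ², dispersion α = 0.05 by default); at α = 0 the emitted counts
equal the analytic expectation exactly, which the recovery tests exploit.
Antisense signal is 5 % of each gene's output spread over a 400 nt
upstream window on the opposite strand — thin enough that no single
antisense nucleotide approaches the calling threshold, while keeping the
planted sense fraction ≥ 0.9. The generator does **not** simulate
sequence-level biases, mappability, PCR artefacts, overlapping genes,
within-gene alternative promoters, or cell-type heterogeneity, so passing
recovery tests demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artefact of real libraries. The
optional genome sequence is uniform random ACGT: motif scores computed on
it exercise the scanning code but carry no biological signal.

## Problem sizes and numerical choices

The test suite and demo run at desk scale by design: genomes of 0.7–1.6 Mb
across two chromosomes, 120–400 genes, 2 replicates, 90–330 planted pairs
and novel TSSs, 200–999 permutation trials in tests (5000 in the pipeline
default, matching the published operating point). Geometric means are
computed in log space; z-scores use population (ddof = 0) standard
deviations with zero-variance columns mapped to Z = 0 and flagged;
permutation p-values use the (1+k)/(n+1) rule; empirical-FDR and KS checks
run ≥ 20 replicates / ≥ 200 simulated datasets. Subsampling uses a
multivariate hypergeometric draw (marginals method) and therefore requires
integer counts. All randomness flows from explicit seeds; hierarchical
clustering, tie-breaks and greedy pairing are deterministic.

## Known limitations

* The FDR→threshold derivation is a Poisson approximation; only the
  9-read operating point itself is exact.
* Motif log-odds values depend on the declared consensus-probability
  (0.97) and window defaults; they are rankings, not calibrated energies.
* The shared-NDR criterion is a per-base floor, a deliberately simple
  stand-in for visual contiguity judgements; heavily fragmented ATAC data
  will need a tuned `ndr_floor`.
* The elbow rule exposes its fraction (0.1) because "simultaneously
  minimize distance and cluster number" admits many formalizations; fixed
  k is always available.
* Genome-wide counts from the original larval study (cluster totals,
  class percentages) require the real sequencing data and are not
  reproduced here.
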