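# tssprofiler

Transcription-start-site (TSS) profiling from capped-RNA 5′-end counts.

Nascent-RNA 5′-end assays (Start-seq and relatives) record, at single-
nucleotide resolution, where RNA polymerase II initiates. `tssprofiler`
turns those per-nucleotide stranded counts — together with spike-in counts,
nuclear RNA-seq, ATAC-seq, histone-PTM ChIP coverage and a gene annotation —
into an annotated TSS catalog: called TSS clusters, promoter shape and
pausing statistics, divergent/convergent initiation pairs, chromatin-state
classes for novel start sites, and a permutation test for enhancer-RNA
overlap. It is aimed at regulatory-genomics analysts working in compact
genomes (the defaults reflect *Drosophila*-scale data), and ships a
synthetic-data generator with full ground truth so every stage is testable
without any sequencing data.

## The statistics at the core

**Spike-in normalization.** For raw counts $R_{ti}$ of spike-in transcript
$t$ in replicate $i$, each row is divided by its geometric mean across
replicates, $N_{ti} = R_{ti} / \mathrm{gm}_i(R_{ti})$, and the replicate
score is $S_i = \mathrm{gm}_t(N_{ti})$. By construction
$\mathrm{gm}_i(N_{ti}) = 1$ per transcript and $\prod_i S_i = 1$.
Per-nucleotide counts are divided by $S_i$ before thresholding.

**Cluster calling.** A nucleotide qualifies when its normalized count meets
the threshold (default 9 reads/nt) in *every* replicate; qualifying
nucleotides within the chaining distance (default 5 nt) are connected into
one cluster. Each cluster carries its summit (max-signal nucleotide),
secondary/tertiary peaks, width, and the fraction of signal within ±2 nt of
the summit.

**Shape Index.** $SI = 2 + \sum_{i=1}^{N} p_i \log_2 p_i$ over member
nucleotides, with $p_i$ the fraction of cluster signal at nucleotide $i$.
$SI = 2$ means perfectly focused initiation; a uniform $N$-nt cluster
scores $2 - \log_2 N$. Clusters are also classed as *single* (1 nt),
*peaked* (< 12 nt), *broad* (≥ 12 nt, > 50 % of signal in the top
nucleotide) or *weak* (≥ 12 nt otherwise).

**Pausing Index.** $PI$ = normalized 5′-end cluster signal / gene-body
RNA-seq RPKM; high values indicate promoter-proximal pausing.

**Directionality.** Sense fraction of 5′ reads in a ±200 nt window;
opposite-strand TSSs whose nearest neighbour is each other are paired,
classified divergent (outward) or convergent (inward), and retained when
the summits are ≤ 200 nt apart inside one continuous ATAC
nucleosome-depleted region. Divergent obsTSS/obsTSS pairs of distinct genes
are bidirectional promoters.

**Chromatin classes.** Novel TSSs are profiled by log2 ChIP/input
enrichment of H3K4me1, H3K4me3, H3K27ac and H3K36me3 in ±200 nt windows,
Ward-clustered with the cluster count chosen by a within-group
sum-of-squares elbow over k = 2..15, and labelled TSS-like / Coding /
Enhancer-like / Featureless from centroid rules. Productive elongation is
tested per TSS (downstream vs. upstream stranded RNA-seq reads, exact
binomial test, Benjamini–Hochberg adjusted). Enhancer overlap is scored
against a uniform-shuffle null with empirical
$p = (1 + \#\{\text{null} \ge \text{obs}\}) / (n + 1)$.

## Worked example

```python
import collections
import numpy as np
from tssprofiler import (
    SimulationConfig, generate_dataset, assign_clusters, call_clusters,
    compute_spikein_factors, normalize_counts, shape_index, classify_shape,
)
from tssprofiler.directionality import find_pairs
from tssprofiler.chromatin_class import ptm_enrichment, cluster_nutss, label_clusters

ds = generate_dataset(SimulationConfig(seed=1))
factors = compute_spikein_factors(ds.spikeins)
print("replicate scores S_i:", np.round(factors.S.to_numpy(), 4))

clusters = call_clusters(normalize_counts(ds.startseq, factors), threshold=9.0, chain_dist=5)
records = assign_clusters(clusters, ds.first_exons)
print("clusters:", len(clusters), dict(collections.Counter(r.category for r in records)))

wide = [r for r in records if r.category == "obsTSS" and r.cluster.width > 1]
print("shape classes (width > 1):", dict(collections.Counter(classify_shape(r.cluster) for r in wide)))
print("median SI:", round(np.median([shape_index(r.cluster) for r in wide]), 3))

pairs = find_pairs(records, ds.atac)
print("TSS pairs:", dict(collections.Counter(p.pair_class for p in pairs)))

nutss = [r for r in records if r.category == "nuTSS"]
solution = cluster_nutss(ptm_enrichment(nutss, ds.chip, ds.chip_input), range(2, 16))
print("PTM clusters: k =", solution.k, "->", sorted(set(label_clusters(solution).values())))
```

prints

```
replicate scores S_i: [0.9612 1.0403]
clusters: 210 {'obsTSS': 120, 'nuTSS': 90}
shape classes (width > 1): {'peaked': 94, 'broad': 15, 'weak': 11}
median SI: 0.688
TSS pairs: {'divergent': 7, 'bidirectional_promoter': 8, 'convergent': 8}
PTM clusters: k = 4 -> ['Coding', 'Enhancer-like', 'Featureless', 'TSS-like']
```

The two replicate scores bracket 1 (their product is exactly 1); all 120
planted gene TSSs are recovered as obsTSSs and the 90 planted novel starts
as nuTSSs; the recovered shape-class counts track the generator's
0.8/0.1/0.1 peaked/broad/weak mixture; the 23 planted pairs come back with
their planted geometries; and the elbow finds exactly the four planted
chromatin classes.

The same run is available from the shell:

```sh
tssprofiler demo --seed 1 --outdir demo_out
```

which writes the generated inputs, every stage's TSV, and a
`run_manifest.json` with per-stage checksums (re-running with the same seed
is byte-identical).

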