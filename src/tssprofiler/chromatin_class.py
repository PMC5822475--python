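"""Histone-PTM classification of novel TSSs, elongation testing and
enhancer-overlap permutation testing.

Novel TSSs (nuTSSs) are profiled by ChIP/input enrichment for four marks
(H3K4me1, H3K4me3, H3K27ac, H3K36me3) in a ±200 nt window, clustered
hierarchically (Ward linkage on log2 enrichment) with the number of
clusters chosen by a within-group-sum-of-squares elbow over k = 2..15, and
labelled by a centroid rule: H3K4me3-high clusters are TSS-like,
H3K36me3-high (without K4me3) are Coding, H3K4me1+H3K27ac-high (without
K4me3) are Enhancer-like, and clusters with no mark high are Featureless.

Productive elongation is tested per TSS as downstream vs. upstream stranded
RNA-seq reads (200 nt windows) with an exact binomial test against the
library-balanced proportion, BH-adjusted across TSSs.

Enhancer overlap is assessed against a shuffled null: each trial re-places
every feature uniformly on the genome (chromosome drawn proportional to its
length) and the empirical p-value is (1 + #{null >= observed}) / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .genomic_io import CoverageTrack, GenomicInterval
from .tss_catalog import TSSRecord, window_signal

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3")
DEFAULT_PTM_WINDOW = 200
DEFAULT_K_RANGE = range(2, 16)
DEFAULT_ELBOW_FRACTION = 0.1
DEFAULT_PERMUTATIONS = 5000
SEMANTIC_LABELS = ("TSS-like", "Coding", "Enhancer-like", "Featureless")


def ptm_enrichment(
    nutss: list[TSSRecord],
    chip_tracks: dict[str, CoverageTrack],
    input_track: CoverageTrack,
    window: int = DEFAULT_PTM_WINDOW,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2((chip + pc) / (input + pc)) per mark in the TSS ±window window."""
    if window <= 0:
        raise ValueError("window must be positive")
    missing = [m for m in MARKS if m not in chip_tracks]
    if missing:
        raise KeyError(f"missing ChIP tracks: {', '.join(missing)}")
    rows = []
    for r in nutss:
        inp = window_signal(input_track, r.chrom, r.summit, r.strand, window, window)
        row = {}
        for mark in MARKS:
            chip = window_signal(chip_tracks[mark], r.chrom, r.summit, r.strand, window, window)
            with np.errstate(divide="ignore"):
                row[mark] = np.log2((chip + pseudocount) / (inp + pseudocount))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(MARKS))


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1-based cluster ids
    centroids: pd.DataFrame  # cluster x mark mean log2 enrichment
    wss: dict[int, float]  # within-group sum of squares per candidate k
    semantic: dict[int, str] | None = None


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def cluster_nutss(
    profiles: pd.DataFrame,
    k_range=DEFAULT_K_RANGE,
    elbow_fraction: float = DEFAULT_ELBOW_FRACTION,
    k: int | None = None,
) -> ClusterSolution:
    """Ward hierarchical clustering with WSS-elbow selection of k.

    k is the smallest candidate whose WSS reduction to k+1, relative to the
    total sum of squares (WSS at k = 1), falls below ``elbow_fraction`` —
    past the elbow, finer partitions explain almost no additional variance.
    Pass ``k`` to fix the cluster count instead.
    """
    ks = sorted(k_range)
    X = profiles.to_numpy(dtype=float)
    if ks[0] < 2 or ks[-1] >= len(X):
        raise ValueError(f"k_range must lie within [2, {len(X) - 1}]")
    L = linkage(X, method="ward", metric="euclidean")
    labels_by_k = {kk: fcluster(L, t=kk, criterion="maxclust") for kk in ks}
    wss = {kk: _wss(X, labels_by_k[kk]) for kk in ks}
    total_ss = _wss(X, np.ones(len(X), dtype=int))
    if k is None:
        k = ks[-1]
        if total_ss > 0:
            for kk in ks[:-1]:
                if (wss[kk] - wss[kk + 1]) / total_ss < elbow_fraction:
                    k = kk
                    break
        else:
            k = ks[0]
    labels = labels_by_k[k] if k in labels_by_k else fcluster(L, t=k, criterion="maxclust")
    centroids = profiles.groupby(labels).mean()
    centroids.index.name = "cluster"
    return ClusterSolution(k=k, labels=labels, centroids=centroids, wss=wss)


def label_clusters(solution: ClusterSolution, margin: float = 0.5) -> dict[int, str]:
    """Semantic labels from centroid log2 enrichments.

    A mark is "high" in a cluster when its centroid exceeds the across-
    cluster median for that mark by ``margin`` log2 units.
    """
    cent = solution.centroids
    med = cent.median(axis=0)
    high = cent.gt(med + margin, axis=1)
    labels: dict[int, str] = {}
    for cl in cent.index:
        h = high.loc[cl]
        if h["H3K4me3"]:
            labels[cl] = "TSS-like"
        elif h["H3K36me3"]:
            labels[cl] = "Coding"
        elif h["H3K4me1"] and h["H3K27ac"]:
            labels[cl] = "Enhancer-like"
        else:
            labels[cl] = "Featureless"
    solution.semantic = labels
    return labels


def elongation_test(
    tss_list: list[TSSRecord],
    rna: CoverageTrack,
    window: int = DEFAULT_PTM_WINDOW,
    null_prop: float = 0.5,
) -> pd.DataFrame:
    """Downstream vs upstream stranded RNA-seq reads per TSS.

    Two-sided exact binomial test of the downstream count against
    ``null_prop`` of the window total; BH adjustment over all testable
    TSSs. ``signed_significance`` is -log10(adjusted p), positive when
    downstream-enriched. TSSs with zero total reads are flagged and not
    tested.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not rna.stranded:
        raise ValueError("elongation test requires a stranded RNA track")
    rows = []
    for r in tss_list:
        n = rna.genome[r.chrom]
        arr = rna.array(r.chrom, r.strand)
        if r.strand != "-":
            up = float(arr[max(r.summit - window, 0) : r.summit].sum())
            down = float(arr[r.summit + 1 : min(r.summit + 1 + window, n)].sum())
        else:
            up = float(arr[r.summit + 1 : min(r.summit + 1 + window, n)].sum())
            down = float(arr[max(r.summit - window, 0) : r.summit].sum())
        rows.append(dict(chrom=r.chrom, summit=r.summit, strand=r.strand,
                         downstream=down, upstream=up))
    table = pd.DataFrame(rows)
    pvals = np.full(len(table), np.nan)
    tested = np.zeros(len(table), dtype=bool)
    for i, row in table.iterrows():
        total = int(round(row.downstream + row.upstream))
        if total == 0:
            continue
        tested[i] = True
        res = stats.binomtest(int(round(row.downstream)), total, null_prop)
        pvals[i] = res.pvalue
    table["pvalue"] = pvals
    table["tested"] = tested
    adj = np.full(len(table), np.nan)
    if tested.any():
        adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    table["adj_pvalue"] = adj
    direction = np.sign(table.downstream - table.upstream).replace(0, 1)
    with np.errstate(divide="ignore"):
        table["signed_significance"] = direction * -np.log10(np.clip(adj, 1e-300, None))
    return table


@dataclass
class OverlapTest:
    observed: int
    null_counts: np.ndarray
    pvalue: float
    n_trials: int
    seed: int


def _target_masks(
    targets: list[GenomicInterval], genome: dict[str, int]
) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for t in targets:
        if t.chrom in masks:
            masks[t.chrom][t.start : t.end] = True
    return masks


def permutation_overlap_test(
    features: list[TSSRecord] | list[tuple[str, int]],
    targets: list[GenomicInterval],
    genome: dict[str, int],
    n: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    same_chromosome: bool = False,
) -> OverlapTest:
    """Observed feature-in-target count against a uniform-shuffle null.

    Each trial re-places every feature uniformly at random: the chromosome
    is drawn proportional to its length (or kept, with ``same_chromosome``)
    and the position uniformly within it. Empirical
    p = (1 + #{trial >= observed}) / (n + 1).
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not features or not targets:
        raise ValueError("features and targets must be non-empty")
    positions = [
        (f.chrom, f.summit) if isinstance(f, TSSRecord) else (f[0], int(f[1]))
        for f in features
    ]
    masks = _target_masks(targets, genome)
    observed = sum(1 for c, p in positions if masks[c][p])
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    m = len(positions)
    null_counts = np.zeros(n, dtype=int)
    if same_chromosome:
        feat_chrom_idx = np.array([chroms.index(c) for c, _ in positions])
        for t in range(n):
            count = 0
            for ci in feat_chrom_idx:
                pos = rng.integers(0, genome[chroms[ci]])
                count += bool(masks[chroms[ci]][pos])
            null_counts[t] = count
    else:
        chrom_draws = rng.choice(len(chroms), size=(n, m), p=lengths / lengths.sum())
        uniforms = rng.random((n, m))
        for t in range(n):
            count = 0
            for ci, u in zip(chrom_draws[t], uniforms[t]):
                pos = int(u * genome[chroms[ci]])
                count += bool(masks[chroms[ci]][pos])
            null_counts[t] = count
    pvalue = (1 + int((null_counts >= observed).sum())) / (n + 1)
    return OverlapTest(observed=observed, null_counts=null_counts, pvalue=pvalue,
                       n_trials=n, seed=seed)


def presence_metaplot(
    anchor_groups: dict[str, list[tuple[str, int]]],
    startseq: CoverageTrack,
    flank: int = 2000,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Median-normalized binary Start-seq presence profiles around anchors.

    Per anchor, each base in [anchor - flank, anchor + flank) is converted
    to a presence indicator (any signal > 0, strands combined); the mean
    presence probability is computed per ``bin_size`` bin across anchors,
    then divided by the median bin value of the group (a pseudocount of
    1 / (n_anchors * bin_size) is used when the median is zero). Empty
    groups are omitted. Returns a bins x groups table.
    """
    n_bins = 2 * flank // bin_size
    out = {}
    for group, anchors in anchor_groups.items():
        if not anchors:
            continue
        acc = np.zeros(2 * flank)
        count = 0
        for chrom, pos in anchors:
            n = startseq.genome[chrom]
            lo, hi = pos - flank, pos + flank
            window = np.zeros(2 * flank)
            s, e = max(lo, 0), min(hi, n)
            window[s - lo : s - lo + (e - s)] = startseq.combined(chrom)[s:e]
            acc += (window > 0).astype(float)
            count += 1
        prob = acc / count
        binned = prob[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        median = float(np.median(binned))
        if median == 0:
            median = 1.0 / (count * bin_size)
        out[group] = binned / median
    centers = np.arange(n_bins) * bin_size - flank + bin_size // 2
    return pd.DataFrame(out, index=pd.Index(centers, name="offset"))
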