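"""Annotation of TSS clusters and per-TSS shape/pausing statistics.

A cluster overlapping a same-strand annotated first exon is an observed
promoter TSS (obsTSS) of that gene; anything else is a novel unannotated
TSS (nuTSS). Each record carries:

* Shape Index  SI = 2 + sum_i p_i log2(p_i), with p_i the fraction of
  cluster signal at member nucleotide i. SI = 2 means perfectly focused
  initiation (one nucleotide); a uniform N-nucleotide cluster scores
  2 - log2(N).
* Pausing Index  PI = normalized cluster 5'-end signal / gene-body RNA-seq
  RPKM; high PI indicates promoter-proximal Pol II pausing. Undefined
  (None) when RPKM is zero.
* Shape class — single (width 1); peaked (width < 12 nt); broad (width
  >= 12 nt with > 50% of signal in the highest nucleotide); weak
  (width >= 12 nt otherwise). The published class fractions are quoted
  among TSSs broader than 1 nt, so width-1 clusters are kept separate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, GenomicInterval, intersect
from .startseq_core import TSSCluster

PEAK_WIDTH_BOUNDARY = 12  # nt; width >= 12 goes to the broad/weak side
BROAD_TOP_FRACTION = 0.5

SHAPE_CLASSES = ("single", "peaked", "broad", "weak")


@dataclass
class TSSRecord:
    cluster: TSSCluster
    category: str  # obsTSS | nuTSS
    gene_id: str | None = None
    si: float | None = None
    pi: float | None = None
    pi_defined: bool = True
    shape_class: str | None = None
    signals: dict = field(default_factory=dict)

    @property
    def summit(self) -> int:
        return self.cluster.summit

    @property
    def strand(self) -> str:
        return self.cluster.strand

    @property
    def chrom(self) -> str:
        return self.cluster.chrom


@dataclass
class GeneExpression:
    gene_id: str
    rpkm: float
    reads: float
    length_bp: int


def shape_index(cluster: TSSCluster) -> float:
    """SI = 2 + sum p_i log2 p_i over member nucleotides with signal."""
    total = cluster.total_signal
    if total <= 0:
        raise ValueError("shape index undefined for zero-signal cluster")
    p = cluster.signal[cluster.signal > 0] / total
    return float(2.0 + np.sum(p * np.log2(p)))


def pause_index(cluster_signal: float, rpkm: float) -> tuple[float | None, bool]:
    """PI = cluster signal / RPKM; returns (value, defined). Undefined when RPKM = 0."""
    if rpkm < 0:
        raise ValueError("RPKM must be nonnegative")
    if cluster_signal < 0:
        raise ValueError("cluster signal must be nonnegative")
    if rpkm == 0:
        return None, False
    return float(cluster_signal / rpkm), True


def classify_shape(cluster: TSSCluster) -> str:
    if cluster.width == 1:
        return "single"
    if cluster.width < PEAK_WIDTH_BOUNDARY:
        return "peaked"
    return "broad" if cluster.top_fraction > BROAD_TOP_FRACTION else "weak"


def assign_clusters(
    clusters: list[TSSCluster], first_exons: list[GenomicInterval]
) -> list[TSSRecord]:
    """Partition clusters into obsTSS (same-strand first-exon overlap) and nuTSS.

    A cluster overlapping first exons of multiple genes links to the gene
    whose exon start (5' end by strand) is nearest the cluster summit.
    """
    cluster_ivs = [
        GenomicInterval(c.chrom, c.start, c.end, c.strand if c.strand in "+-" else ".")
        for c in clusters
    ]
    hits: dict[int, list[GenomicInterval]] = {}
    for i, j in intersect(cluster_ivs, first_exons, stranded=True):
        hits.setdefault(i, []).append(first_exons[j])
    records = []
    for i, cluster in enumerate(clusters):
        exons = hits.get(i)
        if not exons:
            records.append(TSSRecord(cluster, "nuTSS"))
            continue
        def tss_of(exon: GenomicInterval) -> int:
            return exon.start if exon.strand != "-" else exon.end - 1
        best = min(exons, key=lambda e: (abs(tss_of(e) - cluster.summit), e.name))
        records.append(TSSRecord(cluster, "obsTSS", gene_id=best.name))
    return records


def select_dominant_tss(records: list[TSSRecord]) -> TSSRecord:
    """The gene's most frequently used start site: the record whose summit
    nucleotide carries the most normalized signal; 5'-most on ties."""
    obs = [r for r in records if r.category == "obsTSS"]
    if not obs:
        raise ValueError("no obsTSS records for this gene")

    def key(r: TSSRecord):
        pos = r.summit if r.strand != "-" else -r.summit
        return (-r.cluster.summit_signal, pos)

    return min(obs, key=key)


def rpkm(gene: GeneModel, rna: CoverageTrack, total_mapped: float) -> GeneExpression:
    """Reads per kilobase per million mapped, over the gene span on its strand."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    span = gene.span
    if span.length <= 0:
        raise ValueError(f"gene {gene.gene_id} has zero length")
    strand = gene.strand if rna.stranded else None
    reads = float(rna.array(span.chrom, strand)[span.start : span.end].sum())
    value = reads / ((span.length / 1e3) * (total_mapped / 1e6))
    return GeneExpression(gene.gene_id, value, reads, span.length)


def window_signal(
    track: CoverageTrack,
    chrom: str,
    position: int,
    strand: str,
    upstream: int,
    downstream: int,
    track_strand: str | None = None,
) -> float:
    """Sum of signal over the strand-oriented window around ``position``.

    On the + strand the window is [position - upstream, position + downstream);
    on the - strand upstream extends toward larger coordinates. Windows
    running off the chromosome are truncated with a warning.
    """
    if strand != "-":
        lo, hi = position - upstream, position + downstream
    else:
        lo, hi = position - downstream + 1, position + upstream + 1
    n = track.genome[chrom]
    if lo < 0 or hi > n:
        warnings.warn(f"window {chrom}:{lo}-{hi} truncated to chromosome bounds")
        lo, hi = max(lo, 0), min(hi, n)
    if track.stranded and track_strand is None:
        arr = track.combined(chrom)
    else:
        arr = track.array(chrom, track_strand if track.stranded else None)
    return float(arr[lo:hi].sum())


def quantile_partition(values, k: int) -> np.ndarray:
    """Rank-based bins of near-equal size; bin 1 is lowest, ties by input order."""
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(values) < k:
        raise ValueError(f"need at least {k} values for {k} bins")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(len(values))
    return (ranks * k // len(values)) + 1


def build_catalog(
    records: list[TSSRecord],
    rna: CoverageTrack | None = None,
    atac: CoverageTrack | None = None,
    startseq_summed: CoverageTrack | None = None,
    genes: dict[str, GeneModel] | None = None,
    total_mapped: float | None = None,
    atac_window: int = 200,
    start_window: int = 100,
) -> list[TSSRecord]:
    """Fill SI, shape class, PI and windowed signals for every record in place."""
    expr: dict[str, GeneExpression] = {}
    if rna is not None and genes and total_mapped:
        for gid, gene in genes.items():
            try:
                expr[gid] = rpkm(gene, rna, total_mapped)
            except ValueError:
                continue
    for r in records:
        r.si = shape_index(r.cluster)
        r.shape_class = classify_shape(r.cluster)
        if r.category == "obsTSS" and r.gene_id in expr:
            r.pi, r.pi_defined = pause_index(r.cluster.total_signal, expr[r.gene_id].rpkm)
            r.signals["rpkm"] = expr[r.gene_id].rpkm
        if atac is not None:
            r.signals["atac"] = window_signal(
                atac, r.chrom, r.summit, r.strand, atac_window, atac_window
            )
        if startseq_summed is not None:
            r.signals["start"] = window_signal(
                startseq_summed, r.chrom, r.summit, r.strand, start_window, start_window,
                track_strand=r.strand if startseq_summed.stranded else None,
            )
    return records


def catalog_to_frame(records: list[TSSRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                chrom=r.chrom, start=r.cluster.start, end=r.cluster.end,
                strand=r.strand, summit=r.summit, category=r.category,
                gene_id=r.gene_id or ".", width=r.cluster.width,
                total_signal=r.cluster.total_signal,
                summit_prop=r.cluster.summit_prop, si=r.si,
                pi=r.pi if r.pi_defined else np.nan,
                pi_defined=r.pi_defined, shape_class=r.shape_class,
                **{f"signal_{k}": v for k, v in r.signals.items()},
            )
        )
    return pd.DataFrame(rows)
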