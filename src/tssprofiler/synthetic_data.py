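"""Synthetic multi-assay dataset generator with known ground truth.

Emulates the statistical structure of a larval fly TSS-profiling study:
per-nucleotide stranded capped-5'-end counts per replicate with planted TSS
clusters of controllable shape, spike-in transcript counts under known
per-replicate scale factors, stranded nuclear RNA-seq downstream of
elongating starts, ATAC coverage with nucleosome-depleted regions, four
histone-mark ChIP tracks with class-specific enrichment at novel TSSs, and
enhancer intervals with planted eRNA initiation.

Shape archetypes (fractions of cluster signal per nucleotide):

* peaked — 5 nt, >= 80% of signal within ±2 nt of the summit;
* broad  — 15 nt with > 50% of signal in the top nucleotide;
* weak   — 15 nt with <= 50% in the top nucleotide.

Counts are drawn negative-binomially around the archetype-profile
expectation (variance mu + dispersion * mu^2); with dispersion 0 the
emitted counts equal the analytic expectation exactly. At most 10% of
TSS-proximal 5' signal is placed antisense, so planted sense fractions are
>= 0.9 by construction. The genome is gap-free with >= 2 chromosomes so
shuffle-based tests exercise cross-chromosome placement. All outputs are
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Transcript,
    extract_first_exons,
    write_chrom_sizes,
    write_coverage,
    write_intervals,
)
from .startseq_core import SpikeInCounts

ARCHETYPES = ("peaked", "broad", "weak")
NUTSS_CLASSES = ("TSS-like", "Coding", "Enhancer-like", "Featureless")
MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3")

# signal fraction per member nucleotide, summit-centred
_PROFILES = {
    "peaked": np.array([0.04, 0.08, 0.76, 0.08, 0.04]),
    "broad": np.array([0.45 / 14] * 7 + [0.55] + [0.45 / 14] * 7),
    "weak": np.array([0.8 / 14] * 7 + [0.2] + [0.8 / 14] * 7),
}


@dataclass
class SimulationConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 400_000, "chrS2": 300_000}
    )
    n_genes: int = 120
    n_spikeins: int = 50
    n_replicates: int = 2
    gene_reads: float = 2000.0  # expected 5'-end reads per gene per replicate
    nutss_reads: float = 800.0
    shape_mixture: tuple[float, float, float] = (0.8, 0.1, 0.1)
    paused_fraction: float = 0.25
    n_divergent_pairs: int = 15
    n_convergent_pairs: int = 8
    bidirectional_fraction: float = 0.5  # of divergent pairs that are gene/gene
    divergent_spacing: tuple[int, int] = (60, 180)
    convergent_spacing: tuple[int, int] = (100, 200)
    nutss_per_class: dict = field(
        default_factory=lambda: {"TSS-like": 20, "Coding": 20, "Featureless": 20}
    )
    n_enhancers: int = 30
    erna_fraction: float = 0.5  # planted Enhancer-like nuTSS inside this many enhancers
    elongating_nutss_fraction: float = 0.1
    antisense_fraction: float = 0.05
    dispersion: float = 0.05  # NB dispersion; 0 = exact expectation
    spikein_noise: float = 0.1  # lognormal sd on spike-in counts
    true_factors: tuple[float, ...] | None = None  # default: lognormal, geomean 1
    slot_spacing: int = 2500
    gene_length: int = 800
    enhancer_length: int = 600
    include_sequence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_sizes) < 2:
            raise ValueError("need at least 2 chromosomes")
        mix = np.asarray(self.shape_mixture, dtype=float)
        if (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError("shape_mixture must be nonnegative and sum to 1")
        for name in ("n_genes", "n_spikeins", "n_replicates", "n_divergent_pairs",
                     "n_convergent_pairs", "n_enhancers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class TruthManifest:
    """Ground truth for every planted feature, one table per feature kind."""

    genes: pd.DataFrame
    pairs: pd.DataFrame
    nutss: pd.DataFrame
    enhancers: pd.DataFrame
    replicates: pd.DataFrame


@dataclass
class SyntheticDataset:
    genome: dict[str, int]
    startseq: dict[str, CoverageTrack]  # replicate -> stranded raw counts
    spikeins: SpikeInCounts
    rna: CoverageTrack
    atac: CoverageTrack
    chip: dict[str, CoverageTrack]
    chip_input: CoverageTrack
    genes: list[GeneModel]
    enhancers: list[GenomicInterval]
    truth: TruthManifest
    sequence: dict[str, str] | None = None

    @property
    def first_exons(self) -> list[GenomicInterval]:
        return extract_first_exons(self.genes)


def generate_spikein_counts(
    true_factors, n_transcripts: int, noise: float, seed: int
) -> SpikeInCounts:
    """R_ti = base_t * factor_i * lognormal noise; exact ratios at noise 0."""
    factors = np.asarray(true_factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("scale factors must be positive")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(500), sigma=1.0, size=n_transcripts)
    R = np.outer(base, factors)
    if noise > 0:
        R = R * rng.lognormal(0.0, noise, size=R.shape)
    reps = [f"rep{i + 1}" for i in range(len(factors))]
    txs = [f"spike_{t + 1}" for t in range(n_transcripts)]
    return SpikeInCounts(pd.DataFrame(R, index=txs, columns=reps))


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + dispersion mu^2); dispersion 0 returns mu exactly."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return mu.copy()
    r = 1.0 / dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = r / (r + mu)
    out = np.zeros_like(mu)
    positive = mu > 0
    out[positive] = rng.negative_binomial(r, p[positive])
    return out


class _Layout:
    """Round-robin slot allocator: one anchor per element, fixed spacing."""

    def __init__(self, genome: dict[str, int], spacing: int, margin: int = 3000):
        self.genome = genome
        self.spacing = spacing
        self.margin = margin
        self.cursors = {c: margin for c in genome}
        self.order = list(genome)
        self.turn = 0

    def next_anchor(self) -> tuple[str, int]:
        for _ in range(len(self.order)):
            chrom = self.order[self.turn % len(self.order)]
            self.turn += 1
            pos = self.cursors[chrom]
            if pos + self.spacing + self.margin <= self.genome[chrom]:
                self.cursors[chrom] = pos + self.spacing
                return chrom, pos
        raise ValueError("infeasible config: genome too small for the requested features")


def _place_profile(arr: np.ndarray, summit: int, total: float, profile: np.ndarray) -> np.ndarray:
    """Expected counts for one cluster, summit-centred; returns member positions."""
    offset = summit - int(np.argmax(profile))
    positions = np.arange(offset, offset + len(profile))
    arr[positions] += total * profile
    return positions


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Build every input track plus the ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    genome = dict(config.chrom_sizes)
    layout = _Layout(genome, config.slot_spacing)

    if config.true_factors is not None:
        factors = np.asarray(config.true_factors, dtype=float)
        if len(factors) != config.n_replicates:
            raise ValueError("true_factors length must equal n_replicates")
    else:
        factors = rng.lognormal(0.0, 0.2, size=config.n_replicates)
        factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    reps = [f"rep{i + 1}" for i in range(config.n_replicates)]

    # expected (pre-noise, factor-free) per-base 5' signal per strand
    expect = {c: {"+": np.zeros(n), "-": np.zeros(n)} for c, n in genome.items()}
    rna_expect = {c: {"+": np.zeros(n), "-": np.zeros(n)} for c, n in genome.items()}
    atac = CoverageTrack(genome)
    chip = {m: CoverageTrack(genome) for m in MARKS}
    chip_input = CoverageTrack(genome)
    for c, n in genome.items():
        atac.array(c)[:] = 1.0  # accessible-chromatin floor
        chip_input.array(c)[:] = 2.0
        for m in MARKS:
            chip[m].array(c)[:] = 2.0

    genes: list[GeneModel] = []
    gene_rows = []
    pair_rows = []
    nutss_rows = []
    enhancer_rows = []
    enhancers: list[GenomicInterval] = []

    def plant_ndr(chrom: str, lo: int, hi: int, height: float = 20.0) -> None:
        atac.array(chrom)[max(lo, 0) : hi] += height

    def add_gene(chrom: str, tss: int, strand: str, archetype: str, paused: bool,
                 expression: float, pair_id: str | None = None) -> str:
        gid = f"gene_{len(genes) + 1}"
        initiation = (3.0 if paused else 1.0) * expression
        total = config.gene_reads * initiation
        if total > 0:
            positions = _place_profile(expect[chrom][strand], tss, total, _PROFILES[archetype])
            # antisense leak upstream on the other strand, spread thinly over
            # 400 nt so no single nucleotide approaches the calling threshold
            anti = "-" if strand == "+" else "+"
            leak = total * config.antisense_fraction / (1 - config.antisense_fraction)
            lo = tss - 440 if strand == "+" else tss + 40
            expect[chrom][anti][lo : lo + 400] += leak / 400
        if strand == "+":
            body = (tss - 2, min(tss + config.gene_length, genome[chrom]))
            exon1 = (tss - 2, tss + 198)
            exon2 = (tss + 300, body[1])
        else:
            body = (max(tss - config.gene_length, 0), tss + 3)
            exon1 = (tss - 197, tss + 3)
            exon2 = (body[0], tss - 300)
        elongation = 0.15 if paused else 1.0
        rna_expect[chrom][strand][body[0] : body[1]] += 5.0 * expression * elongation
        exons = sorted(
            [GenomicInterval(chrom, *exon1, strand, gid),
             GenomicInterval(chrom, *exon2, strand, gid)],
            key=lambda e: e.start,
        )
        genes.append(GeneModel(gid, strand, [Transcript(f"{gid}.t1", strand, exons)]))
        plant_ndr(chrom, tss - 150, tss + 150)
        chip["H3K4me3"].array(chrom)[max(tss - 200, 0) : tss + 200] += 8.0
        chip["H3K36me3"].array(chrom)[body[0] : body[1]] += 6.0 * elongation
        gene_rows.append(dict(gene_id=gid, chrom=chrom, tss=tss, strand=strand,
                              archetype=archetype, paused=paused, expression=expression,
                              pair_id=pair_id or "."))
        return gid

    def add_nutss(chrom: str, pos: int, strand: str, klass: str, elongating: bool,
                  in_enhancer: str = ".", pair_id: str | None = None) -> None:
        nid = f"nutss_{len(nutss_rows) + 1}"
        total = config.nutss_reads
        if total > 0:
            _place_profile(expect[chrom][strand], pos, total, _PROFILES["peaked"])
        plant_ndr(chrom, pos - 150, pos + 150, height=12.0)
        win = slice(max(pos - 200, 0), pos + 200)
        if klass == "TSS-like":
            chip["H3K4me3"].array(chrom)[win] += 8.0
        elif klass == "Coding":
            chip["H3K36me3"].array(chrom)[win] += 8.0
        elif klass == "Enhancer-like":
            chip["H3K4me1"].array(chrom)[win] += 8.0
            chip["H3K27ac"].array(chrom)[win] += 8.0
        if elongating:
            if strand == "+":
                rna_expect[chrom][strand][pos + 1 : pos + 401] += 4.0
            else:
                rna_expect[chrom][strand][max(pos - 400, 0) : pos] += 4.0
        nutss_rows.append(dict(nutss_id=nid, chrom=chrom, pos=pos, strand=strand,
                               planted_class=klass, elongating=elongating,
                               enhancer_id=in_enhancer, pair_id=pair_id or "."))

    archetype_draw = rng.choice(len(ARCHETYPES), size=config.n_genes, p=config.shape_mixture)
    paused_draw = rng.random(config.n_genes) < config.paused_fraction
    expression = np.clip(rng.lognormal(0.0, 0.4, size=config.n_genes), 0.4, None)
    gene_cursor = 0

    def next_gene_params():
        nonlocal gene_cursor
        if gene_cursor >= config.n_genes:
            raise ValueError("infeasible config: more planted pairs than genes")
        i = gene_cursor
        gene_cursor += 1
        return ARCHETYPES[archetype_draw[i]], bool(paused_draw[i]), float(expression[i])

    # divergent / convergent pairs first (each consumes gene slots)
    n_bidir = int(round(config.bidirectional_fraction * config.n_divergent_pairs))
    for p in range(config.n_divergent_pairs):
        chrom, anchor = layout.next_anchor()
        d = int(rng.integers(*config.divergent_spacing, endpoint=True))
        plus_tss, minus_tss = anchor + d, anchor
        pid = f"div_{p + 1}"
        arch, paused, expr = next_gene_params()
        add_gene(chrom, plus_tss, "+", arch, paused, expr, pair_id=pid)
        if p < n_bidir:
            arch2, paused2, expr2 = next_gene_params()
            add_gene(chrom, minus_tss, "-", arch2, paused2, expr2, pair_id=pid)
            kind = "bidirectional_promoter"
        else:
            add_nutss(chrom, minus_tss, "-", "TSS-like", False, pair_id=pid)
            kind = "divergent"
        plant_ndr(chrom, minus_tss - 100, plus_tss + 100)
        pair_rows.append(dict(pair_id=pid, chrom=chrom, plus_summit=plus_tss,
                              minus_summit=minus_tss, spacing=d, geometry="divergent",
                              pair_class=kind))
    for p in range(config.n_convergent_pairs):
        chrom, anchor = layout.next_anchor()
        d = int(rng.integers(*config.convergent_spacing, endpoint=True))
        plus_tss, minus_tss = anchor, anchor + d
        pid = f"conv_{p + 1}"
        arch, paused, expr = next_gene_params()
        add_gene(chrom, plus_tss, "+", arch, paused, expr, pair_id=pid)
        add_nutss(chrom, minus_tss, "-", "TSS-like", False, pair_id=pid)
        plant_ndr(chrom, plus_tss - 100, minus_tss + 100)
        pair_rows.append(dict(pair_id=pid, chrom=chrom, plus_summit=plus_tss,
                              minus_summit=minus_tss, spacing=d, geometry="convergent",
                              pair_class="convergent"))

    # remaining singleton genes
    while gene_cursor < config.n_genes:
        chrom, anchor = layout.next_anchor()
        strand = "+" if rng.random() < 0.5 else "-"
        arch, paused, expr = next_gene_params()
        add_gene(chrom, anchor, strand, arch, paused, expr)

    # standalone novel TSSs by class
    elong_pool = []
    for klass, count in config.nutss_per_class.items():
        if klass not in NUTSS_CLASSES:
            raise ValueError(f"unknown nuTSS class {klass!r}")
        for _ in range(count):
            chrom, anchor = layout.next_anchor()
            strand = "+" if rng.random() < 0.5 else "-"
            elong_pool.append((chrom, anchor, strand, klass))
    elongating = rng.random(len(elong_pool)) < config.elongating_nutss_fraction
    for (chrom, anchor, strand, klass), e in zip(elong_pool, elongating):
        add_nutss(chrom, anchor, strand, klass, bool(e))

    # enhancers; a planted fraction carries an Enhancer-like eRNA start
    n_erna = int(round(config.erna_fraction * config.n_enhancers))
    for e in range(config.n_enhancers):
        chrom, anchor = layout.next_anchor()
        iv = GenomicInterval(chrom, anchor, anchor + config.enhancer_length, ".",
                             f"enh_{e + 1}", float(e % 2))
        enhancers.append(iv)
        centre = anchor + config.enhancer_length // 2
        plant_ndr(chrom, iv.start, iv.end, height=10.0)
        chip["H3K4me1"].array(chrom)[iv.start : iv.end] += 6.0
        chip["H3K27ac"].array(chrom)[iv.start : iv.end] += 6.0
        has_erna = e < n_erna
        if has_erna:
            strand = "+" if rng.random() < 0.5 else "-"
            add_nutss(chrom, centre, strand, "Enhancer-like", False, in_enhancer=iv.name)
        enhancer_rows.append(dict(enhancer_id=iv.name, chrom=chrom, start=iv.start,
                                  end=iv.end, tissue="CNS" if e % 2 else "disc",
                                  erna_planted=has_erna))

    # replicate 5'-end counts: expectation x factor, NB noise
    startseq = {}
    for i, rep in enumerate(reps):
        track = CoverageTrack(genome, stranded=True)
        for chrom in genome:
            for strand in ("+", "-"):
                mu = expect[chrom][strand] * factors[i]
                track.array(chrom, strand)[:] = _draw_counts(rng, mu, config.dispersion)
        startseq[rep] = track

    rna = CoverageTrack(genome, stranded=True)
    for chrom in genome:
        for strand in ("+", "-"):
            rna.array(chrom, strand)[:] = _draw_counts(
                rng, rna_expect[chrom][strand], config.dispersion
            )

    spikeins = generate_spikein_counts(
        factors, config.n_spikeins, config.spikein_noise,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    sequence = None
    if config.include_sequence:
        bases = np.frombuffer(b"ACGT", dtype="S1")
        sequence = {
            c: rng.choice(bases, size=n).tobytes().decode()
            for c, n in genome.items()
        }

    truth = TruthManifest(
        genes=pd.DataFrame(gene_rows),
        pairs=pd.DataFrame(pair_rows),
        nutss=pd.DataFrame(nutss_rows),
        enhancers=pd.DataFrame(enhancer_rows),
        replicates=pd.DataFrame({"replicate": reps, "true_factor": factors}),
    )
    return SyntheticDataset(
        genome=genome, startseq=startseq, spikeins=spikeins, rna=rna, atac=atac,
        chip=chip, chip_input=chip_input, genes=genes, enhancers=enhancers,
        truth=truth, sequence=sequence,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every track/table in the plain-text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_chrom_sizes(ds.genome, _p("genome.chrom.sizes"))
    for rep, track in ds.startseq.items():
        write_coverage(track, _p(f"startseq_{rep}_plus.bedgraph"), "+")
        write_coverage(track, _p(f"startseq_{rep}_minus.bedgraph"), "-")
    ds.spikeins.counts.to_csv(_p("spikeins.tsv"), sep="\t")
    write_coverage(ds.rna, _p("rna_plus.bedgraph"), "+")
    write_coverage(ds.rna, _p("rna_minus.bedgraph"), "-")
    write_coverage(ds.atac, _p("atac.bedgraph"))
    for mark, track in ds.chip.items():
        write_coverage(track, _p(f"chip_{mark}.bedgraph"))
    write_coverage(ds.chip_input, _p("chip_input.bedgraph"))
    with open(_p("genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in ds.genes:
            span = gene.span
            fh.write(f"{span.chrom}\tsynthetic\tgene\t{span.start + 1}\t{span.end}\t.\t"
                     f"{gene.strand}\t.\tID={gene.gene_id}\n")
            for tx in gene.transcripts:
                lo = min(e.start for e in tx.exons) + 1
                hi = max(e.end for e in tx.exons)
                fh.write(f"{span.chrom}\tsynthetic\tmRNA\t{lo}\t{hi}\t.\t{gene.strand}\t.\t"
                         f"ID={tx.transcript_id};Parent={gene.gene_id}\n")
                for e in tx.exons:
                    fh.write(f"{e.chrom}\tsynthetic\texon\t{e.start + 1}\t{e.end}\t.\t"
                             f"{tx.strand}\t.\tParent={tx.transcript_id}\n")
    write_intervals(ds.enhancers, _p("enhancers.bed"))
    if ds.sequence is not None:
        with open(_p("genome.fa"), "w") as fh:
            for chrom, seq in ds.sequence.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    for name in ("genes", "pairs", "nutss", "enhancers", "replicates"):
        getattr(ds.truth, name).to_csv(_p(f"truth_{name}.tsv"), sep="\t", index=False)
    return paths
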