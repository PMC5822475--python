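"""End-to-end orchestration: normalize -> threshold -> cluster -> catalog ->
motifs -> pairs -> chromatin -> enhancers, from one flat configuration.

Every numeric operating point appears exactly once, as a PipelineConfig
default. Each stage writes a TSV and a log line with input/output counts;
the run manifest records the seed, parameter values and per-stage output
checksums, so a repeated run with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import chromatin_class, directionality, genomic_io, motif_analysis
from . import startseq_core, tss_catalog

log = logging.getLogger("tssprofiler")

STAGES = ("normalize", "callpeaks", "catalog", "motifs", "pairs", "chromatin", "enhancers")


@dataclass
class PipelineConfig:
    # inputs
    chrom_sizes: str = ""
    startseq: dict = field(default_factory=dict)  # replicate -> {plus, minus} bedGraphs
    spikeins: str = ""
    rna_plus: str = ""
    rna_minus: str = ""
    atac: str = ""
    chip: dict = field(default_factory=dict)  # mark -> bedGraph
    chip_input: str = ""
    annotation: str = ""  # GFF3 gene models
    enhancers: str = ""
    genome_fasta: str = ""
    motif_file: str = ""  # empty -> packaged defaults
    # operating points
    threshold_override: float = 9.0  # normalized reads/nt per replicate
    target_fdr: float = 0.05
    chain_dist: int = 5
    pair_max_dist: int = 200
    sense_window: int = 200
    ptm_window: int = 200
    atac_window: int = 400
    metaplot_flank: int = 2000
    metaplot_bin: int = 10
    permutations: int = 5000
    k_min: int = 2
    k_max: int = 15
    motif_max_mismatch: int = 4
    motif_cluster_k: int = 3
    motif_min_summit_signal: float = 100.0
    seed: int = 0
    outdir: str = "tssprofiler_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key = value file; startseq/chip entries use dotted keys
        (startseq.rep1.plus = ..., chip.H3K4me3 = ...)."""
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("startseq."):
                _, rep, side = key.split(".")
                cfg.startseq.setdefault(rep, {})[side] = value
            elif key.startswith("chip."):
                cfg.chip[key.split(".", 1)[1]] = value
            elif hasattr(cfg, key):
                current = getattr(cfg, key)
                if isinstance(current, bool):
                    value = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    value = int(value)
                elif isinstance(current, float):
                    value = float(value)
                setattr(cfg, key, value)
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def run_pipeline(config: PipelineConfig, dataset=None) -> dict:
    """Execute every stage in order; returns the run manifest.

    ``dataset`` may be a SyntheticDataset already in memory (demo mode);
    otherwise all inputs are read from the configured paths. Stages whose
    inputs are absent (ChIP tracks, genome FASTA, enhancers) are skipped
    with a warning; any stage error aborts with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": {
        k: v for k, v in asdict(config).items() if not isinstance(v, dict)
    }, "stages": {}}

    def save(stage: str, name: str, frame: pd.DataFrame, n_in: int, n_out: int) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        log.info("stage %s: %d in -> %d out (%s)", stage, n_in, n_out, name)
        manifest["stages"][stage] = dict(
            inputs=n_in, outputs=n_out, file=name, checksum=_checksum(path)
        )

    try:
        stage = "normalize"
        if dataset is not None:
            genome = dataset.genome
            raw = dataset.startseq
            spikeins = dataset.spikeins
        else:
            genome = genomic_io.read_chrom_sizes(config.chrom_sizes)
            raw = {
                rep: genomic_io.read_stranded_coverage(p["plus"], p["minus"], genome)
                for rep, p in config.startseq.items()
            }
            spikeins = startseq_core.SpikeInCounts(
                pd.read_csv(config.spikeins, sep="\t", index_col=0)
            )
        factors = startseq_core.compute_spikein_factors(spikeins)
        normalized = startseq_core.normalize_counts(raw, factors)
        save(stage, "norm_factors.tsv",
             factors.S.rename("S").rename_axis("replicate").reset_index(),
             len(spikeins.counts), len(factors.S))

        stage = "callpeaks"
        threshold = startseq_core.derive_fdr_threshold(
            normalized, target_fdr=config.target_fdr, override=config.threshold_override
        )
        clusters = startseq_core.call_clusters(normalized, threshold, config.chain_dist)
        save(stage, "clusters.bed6plus.tsv", startseq_core.clusters_to_bed(clusters),
             len(normalized), len(clusters))

        stage = "catalog"
        if dataset is not None:
            gene_models = dataset.genes
            first_exons = dataset.first_exons
            rna = dataset.rna
            atac = dataset.atac
        else:
            gene_models = genomic_io.read_gene_models(config.annotation) if config.annotation else []
            first_exons = genomic_io.extract_first_exons(gene_models)
            rna = (genomic_io.read_stranded_coverage(config.rna_plus, config.rna_minus, genome)
                   if config.rna_plus else None)
            atac = genomic_io.read_coverage(config.atac, genome) if config.atac else None
        records = tss_catalog.assign_clusters(clusters, first_exons)
        summed = startseq_core.sum_tracks(list(normalized.values()))
        tss_catalog.build_catalog(
            records, rna=rna, atac=atac, startseq_summed=summed,
            genes={g.gene_id: g for g in gene_models},
            total_mapped=rna.total() if rna is not None else None,
            atac_window=config.atac_window // 2,
        )
        save(stage, "tss_catalog.tsv", tss_catalog.catalog_to_frame(records),
             len(clusters), len(records))

        stage = "motifs"
        sequence = None
        if dataset is not None and dataset.sequence:
            sequence = dataset.sequence
        elif config.genome_fasta:
            sequence = _read_fasta(config.genome_fasta)
        if sequence is None:
            log.warning("stage motifs skipped: no genome sequence configured")
        else:
            motifs = motif_analysis.load_motifs(config.motif_file or None)
            strong = [
                r for r in records
                if r.category == "obsTSS"
                and r.cluster.summit_signal > config.motif_min_summit_signal
            ]
            if len(strong) > config.motif_cluster_k:
                matrix = motif_analysis.build_score_matrix(
                    strong, sequence, motifs, config.motif_max_mismatch
                )
                labels = motif_analysis.cluster_tss_by_motifs(
                    matrix.Z, config.motif_cluster_k
                )
                zs = matrix.Z.copy()
                zs.insert(0, "motif_cluster", labels)
                save(stage, "motif_zscores.tsv", zs, len(strong), len(zs))
            else:
                log.warning("stage motifs skipped: too few strong obsTSSs (%d)", len(strong))

        stage = "pairs"
        if atac is None:
            log.warning("stage pairs skipped: no ATAC track")
            pairs = []
        else:
            pairs = directionality.find_pairs(records, atac, max_dist=config.pair_max_dist)
            paired_ids = {id(p.tss_a) for p in pairs} | {id(p.tss_b) for p in pairs}
            singles = [r for r in records if id(r) not in paired_ids]
            save(stage, "tss_pairs.tsv", directionality.pairs_to_frame(pairs),
                 len(records), len(pairs))
            enrich = directionality.pair_atac_enrichment(
                pairs, singles, atac, window=config.atac_window
            )
            enrich.to_csv(outdir / "pair_atac_enrichment.tsv", sep="\t", index=False)

        stage = "chromatin"
        nutss = [r for r in records if r.category == "nuTSS"]
        if dataset is not None:
            chip, chip_input = dataset.chip, dataset.chip_input
        elif config.chip and config.chip_input:
            chip = {m: genomic_io.read_coverage(p, genome) for m, p in config.chip.items()}
            chip_input = genomic_io.read_coverage(config.chip_input, genome)
        else:
            chip = chip_input = None
        if chip is None or len(nutss) <= config.k_max:
            log.warning("stage chromatin skipped: missing ChIP tracks or too few nuTSSs")
            solution = None
        else:
            profiles = chromatin_class.ptm_enrichment(
                nutss, chip, chip_input, window=config.ptm_window
            )
            solution = chromatin_class.cluster_nutss(
                profiles, range(config.k_min, config.k_max + 1)
            )
            semantic = chromatin_class.label_clusters(solution)
            table = profiles.copy()
            table.insert(0, "cluster", solution.labels)
            table.insert(1, "class", [semantic[c] for c in solution.labels])
            save(stage, "nutss_chromatin.tsv", table, len(nutss), len(table))
            if rna is not None:
                elong = chromatin_class.elongation_test(nutss, rna, window=config.ptm_window)
                elong.to_csv(outdir / "nutss_elongation.tsv", sep="\t", index=False)

        stage = "enhancers"
        if dataset is not None:
            enhancers = dataset.enhancers
        elif config.enhancers:
            enhancers = genomic_io.read_intervals(config.enhancers, "BED", genome)
        else:
            enhancers = []
        if not enhancers or not nutss:
            log.warning("stage enhancers skipped: no enhancer intervals or no nuTSSs")
        else:
            test = chromatin_class.permutation_overlap_test(
                nutss, enhancers, genome, n=config.permutations, seed=config.seed
            )
            summary = pd.DataFrame([dict(
                observed=test.observed, trials=test.n_trials, pvalue=test.pvalue,
                null_mean=float(test.null_counts.mean()),
                null_max=int(test.null_counts.max()), seed=test.seed,
            )])
            save(stage, "enhancer_overlap.tsv", summary, len(nutss), 1)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
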