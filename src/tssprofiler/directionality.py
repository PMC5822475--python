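"""Sense/antisense initiation quantification and divergent-pair detection.

A TSS whose nearest neighbouring TSS (by summit distance) sits on the
opposite strand forms a candidate pair. Geometry: the pair is *divergent*
when the minus-strand member lies upstream (leftward) of the plus-strand
member so the two transcription units point away from each other, and
*convergent* when they point toward each other. A pair is retained when the
summits are within ``max_dist`` (default 200 nt) and every base between
them carries ATAC signal at or above ``ndr_floor`` — the operational
definition of one continuous shared nucleosome-depleted region. A divergent
pair of obsTSSs from two distinct genes is a bidirectional promoter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import CoverageTrack
from .tss_catalog import TSSRecord, window_signal

DEFAULT_PAIR_MAX_DIST = 200
DEFAULT_SENSE_WINDOW = 200
DEFAULT_ATAC_WINDOW = 400


@dataclass
class TSSPair:
    tss_a: TSSRecord  # plus-strand member
    tss_b: TSSRecord  # minus-strand member
    distance: int  # minus-strand summit minus plus-strand summit (signed)
    geometry: str | None = None  # divergent | convergent
    pair_class: str | None = None  # bidirectional_promoter | divergent | convergent
    shared_ndr: bool = False


def sense_fraction(
    tss: TSSRecord, startseq: CoverageTrack, window: int = DEFAULT_SENSE_WINDOW
) -> float | None:
    """Sense reads / total reads in [summit - window, summit + window).

    None (undefined) when no reads fall in the window at all.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not startseq.stranded:
        raise ValueError("sense_fraction requires a stranded track")
    n = startseq.genome[tss.chrom]
    lo, hi = max(tss.summit - window, 0), min(tss.summit + window, n)
    sense = float(startseq.array(tss.chrom, tss.strand)[lo:hi].sum())
    anti_strand = "-" if tss.strand == "+" else "+"
    anti = float(startseq.array(tss.chrom, anti_strand)[lo:hi].sum())
    if sense + anti == 0:
        return None
    return sense / (sense + anti)


def pair_nearest_opposite(records: list[TSSRecord]) -> list[TSSPair]:
    """Candidate pairs: TSSs whose nearest neighbour is on the opposite strand.

    For every TSS the nearest neighbouring TSS on the same chromosome is
    found by summit distance (ties resolved toward the smaller coordinate).
    When the strands differ the pair becomes a candidate; candidates are
    then ordered by distance and accepted greedily so each TSS joins at
    most one pair. The greedy order makes the result independent of input
    ordering and symmetric under genome mirroring.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_chrom.setdefault(r.chrom, []).append(i)
    candidates: list[tuple[int, str, int, int, int]] = []
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda i: records[i].summit)
        if len(idx) < 2:
            continue
        for pos, i in enumerate(idx):
            flanking = []
            if pos > 0:
                flanking.append(idx[pos - 1])
            if pos < len(idx) - 1:
                flanking.append(idx[pos + 1])
            j = min(
                flanking,
                key=lambda c: (abs(records[c].summit - records[i].summit),
                               records[c].summit),
            )
            if records[j].strand == records[i].strand:
                continue
            dist = abs(records[j].summit - records[i].summit)
            lo = min(records[i].summit, records[j].summit)
            candidates.append((dist, chrom, lo, min(i, j), max(i, j)))
    used: set[int] = set()
    pairs: list[TSSPair] = []
    for dist, chrom, lo, i, j in sorted(set(candidates)):
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = (records[i], records[j]) if records[i].strand == "+" else (records[j], records[i])
        pairs.append(TSSPair(a, b, distance=b.summit - a.summit))
    return pairs


def classify_pair(
    pair: TSSPair,
    atac: CoverageTrack,
    max_dist: int = DEFAULT_PAIR_MAX_DIST,
    ndr_floor: float | None = None,
) -> TSSPair | None:
    """Assign geometry and retain only close pairs sharing one continuous NDR.

    ``ndr_floor`` defaults to the genome-wide median of nonzero ATAC signal.
    Returns None when the pair fails the distance or shared-NDR filter.
    """
    if pair.tss_a.strand == pair.tss_b.strand:
        raise ValueError("pair members must be on opposite strands")
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if ndr_floor is None:
        ndr_floor = default_ndr_floor(atac)
    # minus member upstream (left) of plus member -> transcription proceeds outward
    pair.geometry = "divergent" if pair.distance <= 0 else "convergent"
    if abs(pair.distance) > max_dist:
        return None
    lo = min(pair.tss_a.summit, pair.tss_b.summit)
    hi = max(pair.tss_a.summit, pair.tss_b.summit)
    between = atac.combined(pair.tss_a.chrom)[lo : hi + 1]
    pair.shared_ndr = bool(np.all(between >= ndr_floor))
    if not pair.shared_ndr:
        return None
    both_obs = (
        pair.tss_a.category == "obsTSS"
        and pair.tss_b.category == "obsTSS"
        and pair.tss_a.gene_id != pair.tss_b.gene_id
    )
    if pair.geometry == "divergent" and both_obs:
        pair.pair_class = "bidirectional_promoter"
    else:
        pair.pair_class = pair.geometry
    return pair


def default_ndr_floor(atac: CoverageTrack) -> float:
    values = np.concatenate([atac.combined(c) for c in atac.genome])
    nonzero = values[values > 0]
    return float(np.median(nonzero)) if nonzero.size else 0.0


def find_pairs(
    records: list[TSSRecord],
    atac: CoverageTrack,
    max_dist: int = DEFAULT_PAIR_MAX_DIST,
    ndr_floor: float | None = None,
) -> list[TSSPair]:
    """Nearest-opposite pairing followed by distance/NDR classification."""
    if ndr_floor is None:
        ndr_floor = default_ndr_floor(atac)
    out = []
    for pair in pair_nearest_opposite(records):
        kept = classify_pair(pair, atac, max_dist=max_dist, ndr_floor=ndr_floor)
        if kept is not None:
            out.append(kept)
    return out


def pair_atac_enrichment(
    pairs: list[TSSPair],
    singles: list[TSSRecord],
    atac: CoverageTrack,
    window: int = DEFAULT_ATAC_WINDOW,
) -> pd.DataFrame:
    """Per-class ATAC signal in a ±window/2 window plus rank-sum contrasts.

    Classes: bidirectional (both members of a bidirectional promoter),
    divergent (members of other divergent pairs), non_divergent (unpaired
    TSSs). Pairwise Wilcoxon rank-sum p-values are BH-adjusted.
    """
    half = window // 2
    groups: dict[str, list[float]] = {"bidirectional": [], "divergent": [], "non_divergent": []}
    for p in pairs:
        key = "bidirectional" if p.pair_class == "bidirectional_promoter" else (
            "divergent" if p.geometry == "divergent" else None
        )
        if key is None:
            continue
        for r in (p.tss_a, p.tss_b):
            groups[key].append(window_signal(atac, r.chrom, r.summit, r.strand, half, half))
    for r in singles:
        groups["non_divergent"].append(
            window_signal(atac, r.chrom, r.summit, r.strand, half, half)
        )
    groups = {k: v for k, v in groups.items() if v}
    rows = []
    names = sorted(groups)
    raw_p = []
    contrasts = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            stat = stats.ranksums(groups[names[i]], groups[names[j]])
            contrasts.append((names[i], names[j], stat.statistic))
            raw_p.append(stat.pvalue)
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    for (g1, g2, statistic), p, q in zip(contrasts, raw_p, adj):
        rows.append(
            dict(group_a=g1, group_b=g2,
                 median_a=float(np.median(groups[g1])), median_b=float(np.median(groups[g2])),
                 n_a=len(groups[g1]), n_b=len(groups[g2]),
                 statistic=statistic, pvalue=p, adj_pvalue=q)
        )
    return pd.DataFrame(rows)


def pairs_to_frame(pairs: list[TSSPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            dict(
                chrom=p.tss_a.chrom, plus_summit=p.tss_a.summit, minus_summit=p.tss_b.summit,
                distance=p.distance, geometry=p.geometry, pair_class=p.pair_class,
                shared_ndr=p.shared_ndr,
                plus_category=p.tss_a.category, minus_category=p.tss_b.category,
                plus_gene=p.tss_a.gene_id or ".", minus_gene=p.tss_b.gene_id or ".",
            )
        )
    return pd.DataFrame(rows)
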