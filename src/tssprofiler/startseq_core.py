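"""Spike-in normalization, FDR thresholding and TSS-cluster calling.

The normalization follows the double geometric-mean scheme: each spike-in
transcript's raw count R_ti is divided by the geometric mean of its counts
across replicates, giving N_ti; the per-replicate score S_i is the geometric
mean of N_ti over transcripts. By construction the row-wise geometric mean
of N is 1 and the product of the S_i is 1.

Cluster calling operates on normalized per-nucleotide 5'-end counts: a
nucleotide qualifies when it meets the threshold in EVERY replicate, and
qualifying nucleotides within the chaining distance (default 5 nt) of each
other are connected into one cluster. The summit is the member with the
most summed normalized signal (leftmost on ties); summit_prop is the
fraction of cluster signal within 2 nt on either side of the summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CoverageTrack

DEFAULT_CHAIN_DIST = 5
DEFAULT_THRESHOLD = 9.0  # normalized reads per nucleotide per replicate


@dataclass
class SpikeInCounts:
    """Raw spike-in read counts: transcripts are rows, replicates columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spike-in counts must be nonnegative")


@dataclass
class NormFactors:
    """Normalized spike-in matrix N and per-replicate scores S."""

    N: pd.DataFrame
    S: pd.Series


def compute_spikein_factors(spikeins: SpikeInCounts) -> NormFactors:
    """Geometric-mean spike-in normalization.

    Rows containing any zero are excluded from both N and S: a zero would
    make the row geometric mean degenerate.
    """
    R = spikeins.counts
    if R.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    positive = (R > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no usable spike-ins: every transcript has a zero count")
    Rp = R.loc[positive].astype(float)
    row_geomean = np.exp(np.log(Rp).mean(axis=1))
    N = Rp.div(row_geomean, axis=0)
    S = np.exp(np.log(N).mean(axis=0))
    return NormFactors(N=N, S=pd.Series(S, index=R.columns))


def normalize_counts(
    tracks: dict[str, CoverageTrack], factors: NormFactors
) -> dict[str, CoverageTrack]:
    """Divide each replicate's per-nucleotide counts by its score S_i."""
    out = {}
    for rep, track in tracks.items():
        if rep not in factors.S.index:
            raise KeyError(f"no normalization factor for replicate {rep!r}")
        out[rep] = track.scale(1.0 / float(factors.S[rep]))
    return out


def sum_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    tracks = list(tracks)
    out = tracks[0].copy()
    for t in tracks[1:]:
        out += t
    return out


def derive_fdr_threshold(
    tracks: dict[str, CoverageTrack],
    target_fdr: float = 0.05,
    override: float | None = DEFAULT_THRESHOLD,
    effective_genome_size: int | None = None,
) -> float:
    """Per-replicate nucleotide threshold for bona-fide initiation signal.

    With ``override`` set (the default operating point, 9 normalized reads
    per nucleotide per replicate) that value is returned directly. Otherwise
    a genome-wide Poisson background is fitted per replicate — rate = total
    normalized signal / effective genome size (non-zero positions unless
    given) — and the smallest integer c is returned for which the expected
    number of false-positive nucleotides at >= c, divided by the observed
    number at >= c, is <= target_fdr. The maximum over replicates is used so
    the every-replicate rule is conservative.
    """
    if override is not None:
        return float(override)
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    if not tracks:
        raise ValueError("no tracks supplied")
    thresholds = []
    for rep, track in tracks.items():
        values = []
        for chrom in track.genome:
            if track.stranded:
                values.append(track.array(chrom, "+"))
                values.append(track.array(chrom, "-"))
            else:
                values.append(track.array(chrom))
        values = np.concatenate(values)
        total = values.sum()
        if total == 0:
            raise ValueError(f"replicate {rep!r} has no signal")
        size = effective_genome_size if effective_genome_size else int((values > 0).sum())
        lam = total / size
        for c in range(1, 10_000):
            expected_fp = size * stats.poisson.sf(c - 1, lam)
            observed = max(1, int((values >= c).sum()))
            if expected_fp / observed <= target_fdr:
                thresholds.append(c)
                break
        else:  # pragma: no cover - pathological rate
            raise RuntimeError("no threshold below 10000 reached the target FDR")
    return float(max(thresholds))


@dataclass
class TSSCluster:
    """A chained run of above-threshold nucleotides on one strand."""

    chrom: str
    strand: str
    positions: np.ndarray  # sorted member positions
    signal: np.ndarray  # summed normalized signal per member
    summit: int = field(init=False)
    secondary: int | None = field(init=False)
    tertiary: int | None = field(init=False)
    width: int = field(init=False)
    total_signal: float = field(init=False)
    summit_prop: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.positions, kind="stable")
        self.positions = np.asarray(self.positions)[order]
        self.signal = np.asarray(self.signal, dtype=float)[order]
        self.width = int(self.positions[-1] - self.positions[0] + 1)
        self.total_signal = float(self.signal.sum())
        # ranked peaks by descending signal, leftmost wins ties
        rank = np.lexsort((self.positions, -self.signal))
        self.summit = int(self.positions[rank[0]])
        self.secondary = int(self.positions[rank[1]]) if len(rank) > 1 else None
        self.tertiary = int(self.positions[rank[2]]) if len(rank) > 2 else None
        near = np.abs(self.positions - self.summit) <= 2
        self.summit_prop = float(self.signal[near].sum() / self.total_signal) if self.total_signal else 0.0

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1]) + 1

    @property
    def summit_signal(self) -> float:
        return float(self.signal[np.searchsorted(self.positions, self.summit)])

    @property
    def top_fraction(self) -> float:
        """Fraction of cluster signal in the single highest nucleotide."""
        return float(self.signal.max() / self.total_signal) if self.total_signal else 0.0


def cluster_positions(positions: np.ndarray, chain_dist: int) -> list[np.ndarray]:
    """Partition sorted positions into runs with consecutive gaps <= chain_dist."""
    if chain_dist < 1:
        raise ValueError("chain_dist must be >= 1")
    positions = np.sort(np.asarray(positions))
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > chain_dist) + 1
    return np.split(positions, breaks)


def call_clusters(
    rep_tracks: Sequence[CoverageTrack] | dict[str, CoverageTrack],
    threshold: float = DEFAULT_THRESHOLD,
    chain_dist: int = DEFAULT_CHAIN_DIST,
) -> list[TSSCluster]:
    """Call TSS clusters from normalized stranded per-replicate count tracks.

    A nucleotide qualifies only if its normalized count meets ``threshold``
    in every replicate; cluster signal is the replicate-summed count at the
    qualifying member nucleotides. Strands are processed independently.
    """
    if isinstance(rep_tracks, dict):
        rep_tracks = list(rep_tracks.values())
    if not rep_tracks:
        return []
    summed = sum_tracks(rep_tracks)
    clusters: list[TSSCluster] = []
    for chrom in summed.genome:
        strands = ("+", "-") if summed.stranded else (".",)
        for strand in strands:
            s = None if strand == "." else strand
            qualify = np.ones(summed.genome[chrom], dtype=bool)
            for track in rep_tracks:
                qualify &= track.array(chrom, s) >= threshold
            positions = np.flatnonzero(qualify)
            total = summed.array(chrom, s)
            for members in cluster_positions(positions, chain_dist):
                clusters.append(TSSCluster(chrom, strand, members, total[members]))
    return clusters


def subsample_counts(track: CoverageTrack, n_reads: int, seed: int) -> CoverageTrack:
    """Draw ``n_reads`` without replacement across nucleotides.

    A multivariate hypergeometric draw over the per-base integer counts;
    deterministic for a given seed. The track must hold integer counts.
    """
    keys = []
    counts = []
    for chrom in track.genome:
        strands = ("+", "-") if track.stranded else (None,)
        for s in strands:
            arr = track.array(chrom, s)
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("subsampling requires integer raw counts")
            keys.append((chrom, s))
            counts.append(np.round(arr).astype(np.int64))
    flat = np.concatenate(counts)
    total = int(flat.sum())
    if n_reads > total:
        raise ValueError(f"cannot draw {n_reads} reads from {total}")
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(flat, n_reads, method="marginals")
    out = CoverageTrack(track.genome, track.stranded)
    offset = 0
    for (chrom, s), arr in zip(keys, counts):
        out.array(chrom, s)[:] = drawn[offset : offset + arr.size]
        offset += arr.size
    return out


def clusters_to_bed(clusters: Sequence[TSSCluster]) -> pd.DataFrame:
    """BED6+ table: extra columns width, total_signal, summit, summit_prop, secondary, tertiary."""
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            dict(
                chrom=c.chrom, start=c.start, end=c.end, name=f"cluster_{i}",
                score=round(c.total_signal, 4), strand=c.strand, width=c.width,
                total_signal=c.total_signal, summit=c.summit,
                summit_prop=round(c.summit_prop, 6),
                secondary=-1 if c.secondary is None else c.secondary,
                tertiary=-1 if c.tertiary is None else c.tertiary,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "width",
                 "total_signal", "summit", "summit_prop", "secondary", "tertiary"],
    )
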