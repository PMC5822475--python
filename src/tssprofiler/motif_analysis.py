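"""Position-restricted promoter-motif scanning and motif-profile clustering.

Each motif carries an IUPAC consensus and an expected window relative to the
TSS (strand-oriented). Scanning slides the consensus over the window
sequence, keeps offsets with at most ``max_mismatch`` mismatches (IUPAC-
aware), scores each as a log-odds sum against background using a PWM derived
from the consensus (0.97 probability shared by the consensus bases at each
position), and reports the maximum. TSSs in which a motif is never detected
are floor-imputed with the minimum detected score for that motif before
z-scoring: Z = (X - mu) / sd per motif column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
BASES = "ACGT"
DEFAULT_MAX_MISMATCH = 4
CONSENSUS_PROB = 0.97


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named IUPAC consensus with its expected TSS-relative window."""

    name: str
    consensus: str
    offset_start: int  # strand-oriented, relative to the TSS (negative = upstream)
    offset_end: int
    background: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in BASES}
    )
    consensus_prob: float = CONSENSUS_PROB

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if any(c not in IUPAC for c in self.consensus):
            raise ValueError(f"non-IUPAC character in consensus {self.consensus!r}")
        if self.offset_end - self.offset_start < len(self.consensus):
            raise ValueError(f"window of {self.name} shorter than its consensus")

    def pwm(self) -> np.ndarray:
        """Columns sum to 1; consensus bases share ``consensus_prob``."""
        W = np.empty((len(self.consensus), 4))
        for i, code in enumerate(self.consensus):
            allowed = IUPAC[code]
            if len(allowed) == 4:  # fully degenerate column carries no information
                W[i, :] = 0.25
                continue
            for j, b in enumerate(BASES):
                if b in allowed:
                    W[i, j] = self.consensus_prob / len(allowed)
                else:
                    W[i, j] = (1 - self.consensus_prob) / (4 - len(allowed))
        return W

    def reverse_complemented(self) -> "MotifModel":
        return MotifModel(
            self.name, reverse_complement(self.consensus),
            self.offset_start, self.offset_end, dict(self.background),
            self.consensus_prob,
        )


def scan_motif(
    sequence: str, motif: MotifModel, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> float | None:
    """Best log-odds score of the motif in the (strand-oriented) sequence.

    Offsets with more than ``max_mismatch`` IUPAC-aware mismatches are not
    scored; returns None when no offset qualifies (including sequences
    shorter than the motif and all-N stretches).
    """
    sequence = sequence.upper()
    m = len(motif.consensus)
    if len(sequence) < m:
        return None
    W = motif.pwm()
    logodds = np.full((m, 4), -np.inf)
    for j, b in enumerate(BASES):
        bg = motif.background[b]
        logodds[:, j] = np.log2(W[:, j] / bg)
    allowed = [IUPAC[c] for c in motif.consensus]
    best: float | None = None
    for off in range(len(sequence) - m + 1):
        window = sequence[off : off + m]
        if "N" in window:
            continue
        mismatches = sum(1 for s, a in zip(window, allowed) if s not in a)
        if mismatches > max_mismatch:
            continue
        score = float(sum(logodds[i, BASES.index(b)] for i, b in enumerate(window)))
        if best is None or score > best:
            best = score
    return best


def load_motifs(path: str | Path | None = None) -> list[MotifModel]:
    """Packaged motif table (name, consensus, window) unless a path is given."""
    if path is None:
        text = resources.files("tssprofiler.data").joinpath("motifs.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, consensus, start, end = line.split("\t")[:4]
        motifs.append(MotifModel(name, consensus, int(start), int(end)))
    return motifs


def tss_window_sequence(
    genome_seq: dict[str, str], chrom: str, tss: int, strand: str,
    offset_start: int, offset_end: int,
) -> str:
    """Strand-oriented sequence of [tss+offset_start, tss+offset_end) bp.

    Offsets are in transcript orientation: negative offsets are upstream of
    the TSS on its own strand. Minus-strand windows are reverse-complemented.
    """
    seq = genome_seq[chrom]
    if strand != "-":
        lo, hi = tss + offset_start, tss + offset_end
        sub = seq[max(lo, 0) : max(hi, 0)]
        return sub
    lo, hi = tss - offset_end + 1, tss - offset_start + 1
    sub = seq[max(lo, 0) : max(hi, 0)]
    return reverse_complement(sub)


@dataclass
class MotifScoreMatrix:
    X: pd.DataFrame  # TSS x motif raw max log-odds (floor-imputed)
    Z: pd.DataFrame  # z-scored per motif column
    mu: pd.Series
    sd: pd.Series
    imputed: pd.DataFrame  # boolean mask of floor-imputed entries


def zscore_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = sd.replace(0, np.nan)
    Z = (X - mu) / sd_safe
    return Z.fillna(0.0), mu, sd


def build_score_matrix(
    tss_records,
    genome_seq: dict[str, str],
    motifs: list[MotifModel],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> MotifScoreMatrix:
    """Scan each motif in its own window around every TSS and z-score.

    Missing detections are imputed with the motif's column minimum over
    detected scores; motifs never detected anywhere are dropped with a
    warning.
    """
    names = [m.name for m in motifs]
    raw = pd.DataFrame(np.nan, index=range(len(tss_records)), columns=names)
    for t, rec in enumerate(tss_records):
        for m in motifs:
            seq = tss_window_sequence(
                genome_seq, rec.chrom, rec.summit, rec.strand, m.offset_start, m.offset_end
            )
            raw.iloc[t, raw.columns.get_loc(m.name)] = np.nan
            score = scan_motif(seq, m, max_mismatch)
            if score is not None:
                raw.iloc[t, raw.columns.get_loc(m.name)] = score
    dropped = [c for c in raw.columns if raw[c].isna().all()]
    if dropped:
        warnings.warn(f"motifs never detected, dropped: {', '.join(dropped)}")
        raw = raw.drop(columns=dropped)
    imputed = raw.isna()
    X = raw.fillna(raw.min(axis=0))
    Z, mu, sd = zscore_columns(X)
    return MotifScoreMatrix(X=X, Z=Z, mu=mu, sd=sd, imputed=imputed)


def cluster_tss_by_motifs(Z: pd.DataFrame, k: int = 3) -> np.ndarray:
    """Agglomerative (Euclidean, complete linkage) clustering cut at k groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(Z):
        raise ValueError(f"k={k} exceeds the number of TSSs ({len(Z)})")
    L = linkage(Z.to_numpy(), method="complete", metric="euclidean")
    return fcluster(L, t=k, criterion="maxclust")


def motif_correlations(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between motif score columns; zero-variance -> NaN."""
    if len(X) < 3:
        raise ValueError("need at least 3 TSSs for correlations")
    return X.corr(method="pearson")


def information_content(sequences: list[str]) -> np.ndarray:
    """Per-position IC = 2 + sum_b f_b log2 f_b (bits); Ns excluded per column."""
    if not sequences:
        raise ValueError("no sequences supplied")
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(sequences[0])
    if any(len(s) != n for s in sequences):
        raise ValueError("sequences must be equal length")
    ic = np.zeros(n)
    for i in range(n):
        column = [s[i].upper() for s in sequences if s[i].upper() in BASES]
        if not column:
            ic[i] = 0.0
            continue
        freqs = np.array([column.count(b) for b in BASES], dtype=float)
        f = freqs[freqs > 0] / freqs.sum()
        ic[i] = 2.0 + float(np.sum(f * np.log2(f)))
    return ic
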