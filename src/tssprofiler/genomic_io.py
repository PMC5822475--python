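"""Interval and coverage I/O with fixed coordinate conventions.

All coordinates inside the package are 0-based half-open ``[start, end)``.
BED is read natively; GFF3 is converted from 1-based closed at the parsing
boundary. A single-nucleotide position ``p`` is represented as the interval
``[p, p + 1)``.

Coverage (bedGraph) is expanded to dense per-base arrays, one array per
chromosome (and per strand for stranded tracks). Overlapping bedGraph
records are summed, which is how replicate tracks are merged by addition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised for malformed interval/coverage records; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[GenomicInterval]

    def first_exon(self) -> GenomicInterval:
        """5'-most exon by strand; minus-strand transcripts start at the rightmost exon."""
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        key = (lambda e: e.start) if self.strand != "-" else (lambda e: -e.end)
        return min(self.exons, key=key)


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        exons = [e for t in self.transcripts for e in t.exons]
        if not exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return GenomicInterval(
            exons[0].chrom,
            min(e.start for e in exons),
            max(e.end for e in exons),
            self.strand,
            self.gene_id,
        )


class CoverageTrack:
    """Dense per-base signal over a genome, optionally stranded.

    Unstranded tracks hold one float array per chromosome; stranded tracks
    hold a (+, -) pair. All values are nonnegative; positions run over
    ``[0, genome[chrom])``.
    """

    def __init__(self, genome: dict[str, int], stranded: bool = False):
        if not genome:
            raise ValueError("genome must map at least one chromosome to its length")
        self.genome = dict(genome)
        self.stranded = stranded
        if stranded:
            self._data: dict = {
                c: {"+": np.zeros(n), "-": np.zeros(n)} for c, n in genome.items()
            }
        else:
            self._data = {c: np.zeros(n) for c, n in genome.items()}

    def array(self, chrom: str, strand: str | None = None) -> np.ndarray:
        if chrom not in self._data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if self.stranded:
            if strand not in ("+", "-"):
                raise ValueError("stranded track requires strand '+' or '-'")
            return self._data[chrom][strand]
        return self._data[chrom]

    def add(self, chrom: str, start: int, end: int, value: float, strand: str | None = None) -> None:
        if value < 0:
            raise ValueError(f"negative coverage value {value}")
        if end > self.genome[chrom] or start < 0:
            raise ValueError(
                f"record {chrom}:{start}-{end} outside chromosome of length {self.genome[chrom]}"
            )
        self.array(chrom, strand)[start:end] += value

    def combined(self, chrom: str) -> np.ndarray:
        """Strand-summed signal (identity for unstranded tracks)."""
        if self.stranded:
            return self._data[chrom]["+"] + self._data[chrom]["-"]
        return self._data[chrom]

    def total(self) -> float:
        if self.stranded:
            return float(sum(a.sum() for d in self._data.values() for a in d.values()))
        return float(sum(a.sum() for a in self._data.values()))

    def copy(self) -> "CoverageTrack":
        out = CoverageTrack(self.genome, self.stranded)
        for c in self._data:
            if self.stranded:
                for s in ("+", "-"):
                    out._data[c][s] = self._data[c][s].copy()
            else:
                out._data[c] = self._data[c].copy()
        return out

    def scale(self, factor: float) -> "CoverageTrack":
        out = self.copy()
        for c in out._data:
            if self.stranded:
                for s in ("+", "-"):
                    out._data[c][s] *= factor
            else:
                out._data[c] *= factor
        return out

    def __iadd__(self, other: "CoverageTrack") -> "CoverageTrack":
        if self.stranded != other.stranded or self.genome != other.genome:
            raise ValueError("tracks are not compatible")
        for c in self._data:
            if self.stranded:
                for s in ("+", "-"):
                    self._data[c][s] += other._data[c][s]
            else:
                self._data[c] += other._data[c]
        return self


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file."""
    genome: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        genome[parts[0]] = int(parts[1])
    return genome


def write_chrom_sizes(genome: dict[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in genome.items()))


def _parse_bed_line(parts: list[str], lineno: int, path) -> GenomicInterval:
    if len(parts) < 3:
        raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    name = parts[3] if len(parts) > 3 else "."
    score: float | None = None
    if len(parts) > 4 and parts[4] not in (".", ""):
        score = float(parts[4])
    strand = parts[5] if len(parts) > 5 else "."
    try:
        return GenomicInterval(parts[0], start, end, strand, name, score)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def _parse_gff_line(parts: list[str], lineno: int, path) -> GenomicInterval:
    if len(parts) < 8:
        raise FormatError(f"{path}:{lineno}: GFF needs >=8 columns")
    try:
        # GFF is 1-based closed; convert to 0-based half-open.
        start, end = int(parts[3]) - 1, int(parts[4])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    score = None if parts[5] in (".", "") else float(parts[5])
    strand = parts[6] if parts[6] in STRANDS else "."
    name = parts[8] if len(parts) > 8 else parts[2]
    try:
        return GenomicInterval(parts[0], start, end, strand, name, score)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_intervals(
    path: str | Path, format: str = "BED", genome: dict[str, int] | None = None
) -> list[GenomicInterval]:
    """Read BED (0-based half-open) or GFF (1-based closed, converted) intervals.

    Unknown chromosomes are flagged only when ``genome`` is supplied.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF"):
        raise ValueError(f"unknown format {format!r}")
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        iv = _parse_bed_line(parts, lineno, path) if fmt == "BED" else _parse_gff_line(parts, lineno, path)
        if genome is not None and iv.chrom not in genome:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {iv.chrom!r}")
        out.append(iv)
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (score '.' when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_coverage(
    path: str | Path, genome: dict[str, int], strand: str | None = None,
    track: CoverageTrack | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a dense track; overlapping records are summed.

    Pass an existing ``track`` (with ``strand``) to accumulate a stranded
    pair from two files.
    """
    if track is None:
        track = CoverageTrack(genome, stranded=strand is not None)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative value {value}")
        if chrom not in genome:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > genome[chrom]:
            raise FormatError(f"{path}:{lineno}: record extends beyond chromosome end")
        track.add(chrom, start, end, value, strand)
    return track


def read_stranded_coverage(
    plus_path: str | Path, minus_path: str | Path, genome: dict[str, int]
) -> CoverageTrack:
    track = CoverageTrack(genome, stranded=True)
    read_coverage(plus_path, genome, "+", track)
    read_coverage(minus_path, genome, "-", track)
    return track


def write_coverage(track: CoverageTrack, path: str | Path, strand: str | None = None) -> None:
    """Write one strand (or the unstranded signal) as a run-length bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.genome:
            arr = track.array(chrom, strand)
            if not arr.any():
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.12g}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Minimal GFF3 gene/mRNA/exon parser keyed on ID/Parent attributes."""
    genes: dict[str, GeneModel] = {}
    tx_to_gene: dict[str, str] = {}
    transcripts: dict[str, Transcript] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9:
            raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
        ftype, strand, attrs = parts[2], parts[6], parts[8]
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = GeneModel(gid, strand)
        elif ftype in ("mRNA", "transcript"):
            tid, gid = attr["ID"], attr["Parent"]
            tx_to_gene[tid] = gid
            transcripts[tid] = Transcript(tid, strand, [])
        elif ftype == "exon":
            tid = attr["Parent"]
            iv = _parse_gff_line(parts, lineno, path)
            transcripts.setdefault(tid, Transcript(tid, strand, [])).exons.append(iv)
    for tid, tx in transcripts.items():
        gid = tx_to_gene.get(tid, tid)
        if gid not in genes:
            genes[gid] = GeneModel(gid, tx.strand)
        tx.exons.sort(key=lambda e: e.start)
        genes[gid].transcripts.append(tx)
    return [g for g in genes.values() if g.transcripts]


def extract_first_exons(genes: Sequence[GeneModel]) -> list[GenomicInterval]:
    """One interval per transcript: the 5'-most exon by strand, named by gene id.

    Duplicates (transcripts sharing a first exon) are retained.
    """
    out = []
    for gene in genes:
        for tx in gene.transcripts:
            fe = tx.first_exon()
            out.append(GenomicInterval(fe.chrom, fe.start, fe.end, tx.strand, gene.gene_id))
    return out


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval], stranded: bool = False
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]`` (half-open).

    Sorted sweep per chromosome; adjacency (end == start) is not overlap.
    """
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[1].start)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        candidates = by_chrom.get(iv.chrom, ())
        starts = [t[1].start for t in candidates]
        # all b intervals with start < iv.end might overlap
        import bisect

        hi = bisect.bisect_left(starts, iv.end)
        for j, other in candidates[:hi]:
            if other.end > iv.start and (not stranded or other.strand == iv.strand):
                pairs.append((i, j))
    pairs.sort()
    return pairs
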