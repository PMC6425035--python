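"""Genomic coordinate primitives, binning, tag counting and format I/O.

All coordinates are 0-based half-open (BED convention). Reads are represented
as single-coordinate *tags* (the 5' mapping position); a tag is assigned to an
interval iff its coordinate lies in ``[start, end)``, which makes counting over
any disjoint tiling conserve the total read count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeDescription",
    "GenomePartition",
    "TagCollection",
    "TranscriptModel",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_transcript_table",
    "write_transcript_table",
    "make_bins",
    "count_tags_in_intervals",
    "make_promoters",
    "make_genic_regions",
    "merge_intervals",
    "filter_blacklist",
    "interval_union_length",
]


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GenomeDescription:
    """Ordered chromosome names and lengths."""

    chroms: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "GenomeDescription":
        return cls(tuple(d.items()))

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(self.chroms)

    @property
    def names(self) -> List[str]:
        return [c for c, _ in self.chroms]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


class GenomePartition:
    """Fixed-width tiling of a genome into ordered, non-overlapping bins.

    Every chromosome is tiled left to right with ``width``-bp bins; the final
    bin of a chromosome may be shorter. Bins are addressable both as
    :class:`GenomicInterval` objects and by a flat integer index, which is the
    layout used by :class:`~epispread.normalize.BinTrack` values.
    """

    def __init__(self, genome: GenomeDescription, width: int):
        if width <= 0:
            raise ValueError(f"bin width must be positive, got {width}")
        self.genome = genome
        self.width = int(width)
        self._n_per_chrom: Dict[str, int] = {}
        self._offsets: Dict[str, int] = {}
        off = 0
        for chrom, length in genome.chroms:
            n = -(-length // self.width)  # ceil division
            self._n_per_chrom[chrom] = n
            self._offsets[chrom] = off
            off += n
        self.n_bins = off

    def __len__(self) -> int:
        return self.n_bins

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomePartition)
            and other.genome == self.genome
            and other.width == self.width
        )

    def n_bins_for(self, chrom: str) -> int:
        return self._n_per_chrom[chrom]

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Flat index of the bin containing ``pos`` on ``chrom``."""
        length = self.genome.lengths[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom}:[0,{length})")
        return self._offsets[chrom] + pos // self.width

    def bin_interval(self, index: int) -> GenomicInterval:
        for chrom, length in self.genome.chroms:
            n = self._n_per_chrom[chrom]
            off = self._offsets[chrom]
            if off <= index < off + n:
                local = index - off
                start = local * self.width
                return GenomicInterval(chrom, start, min(start + self.width, length))
        raise IndexError(index)

    @property
    def bins(self) -> List[GenomicInterval]:
        return [self.bin_interval(i) for i in range(self.n_bins)]

    def bin_widths(self) -> np.ndarray:
        """True width of every bin (the trailing bin may be short)."""
        widths = np.full(self.n_bins, self.width, dtype=float)
        for chrom, length in self.genome.chroms:
            rem = length % self.width
            if rem:
                widths[self._offsets[chrom] + self._n_per_chrom[chrom] - 1] = rem
        return widths


def make_bins(genome: GenomeDescription, width: int) -> GenomePartition:
    """Tile ``genome`` into fixed-width bins (1 kb / 10 kb / 100 kb in practice)."""
    return GenomePartition(genome, width)


class TagCollection:
    """Per-chromosome sorted read tags plus target/spike-in read totals.

    ``n_spike`` counts exogenous (spike-in genome) reads; those are tallied but
    never placed on the target genome, since spike-in normalization uses only
    mapped-read fractions.
    """

    def __init__(
        self,
        tags: Mapping[str, Sequence[int]],
        n_spike: int = 0,
        genome: Optional[GenomeDescription] = None,
    ):
        self.tags: Dict[str, np.ndarray] = {}
        for chrom, positions in tags.items():
            arr = np.asarray(positions, dtype=np.int64)
            arr = np.sort(arr)
            if arr.size and arr[0] < 0:
                raise ValueError(f"negative tag coordinate on {chrom}")
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                if arr.size and arr[-1] >= genome.lengths[chrom]:
                    raise ValueError(
                        f"tag at {chrom}:{arr[-1]} outside chromosome bounds"
                    )
            self.tags[chrom] = arr
        self.n_spike = int(n_spike)
        self.n_target = int(sum(a.size for a in self.tags.values()))

    @property
    def spike_fraction(self) -> float:
        total = self.n_target + self.n_spike
        if total == 0:
            raise ValueError("empty tag collection")
        return self.n_spike / total


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with strand-aware TSS/TES coordinates (bp).

    ``tss`` is the transcription start: for a minus-strand transcript it is
    the larger genomic coordinate.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError("zero-length transcript")

    @property
    def span(self) -> int:
        return abs(self.tes - self.tss)


# ---------------------------------------------------------------------------
# I/O


def read_bed(path) -> List[GenomicInterval]:
    """Read a BED3/BED6 file into sorted :class:`GenomicInterval` objects."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name=name, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=GenomicInterval.sort_key)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED3 (or BED6 when any interval carries name/strand)."""
    intervals = list(intervals)
    six = any(iv.name is not None or iv.strand is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> GenomeDescription:
    chroms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split("\t")[:2]
            chroms.append((name, int(length)))
    return GenomeDescription(tuple(chroms))


def write_chrom_sizes(genome: GenomeDescription, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


def read_transcript_table(path, one_based: bool = False) -> List[TranscriptModel]:
    """Read a refGene-style TSV: gene, transcript, chrom, strand, txStart, txEnd.

    UCSC table dumps are 0-based half-open; pass ``one_based=True`` for
    browser-style 1-based inclusive exports (start is shifted down by one).
    The strand decides which end is the TSS.
    """
    out: List[TranscriptModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, transcript, chrom, strand, tx_start, tx_end = line.split("\t")[:6]
            s, e = int(tx_start), int(tx_end)
            if one_based:
                s -= 1
            tss, tes = (s, e) if strand == "+" else (e, s)
            out.append(TranscriptModel(gene, transcript, chrom, strand, tss, tes))
    return out


def write_transcript_table(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\ttranscript\tchrom\tstrand\ttxStart\ttxEnd\n")
        for t in transcripts:
            s, e = (t.tss, t.tes) if t.strand == "+" else (t.tes, t.tss)
            fh.write(f"{t.gene}\t{t.transcript}\t{t.chrom}\t{t.strand}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Interval operations


def count_tags_in_intervals(
    tags: TagCollection, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Count tags whose coordinate lies in each interval.

    A tag may be counted by several overlapping intervals; over a disjoint
    partition of the genome the counts sum to ``tags.n_target``.
    """
    counts = np.zeros(len(intervals), dtype=np.int64)
    empty = np.empty(0, dtype=np.int64)
    for i, iv in enumerate(intervals):
        arr = tags.tags.get(iv.chrom, empty)
        counts[i] = np.searchsorted(arr, iv.end, side="left") - np.searchsorted(
            arr, iv.start, side="left"
        )
    return counts


def make_promoters(
    transcripts: Sequence[TranscriptModel],
    flank: int = 2500,
    genome: Optional[GenomeDescription] = None,
) -> List[GenomicInterval]:
    """Promoters as ``2*flank``-bp regions centered on each unique TSS.

    The default flank of 2500 bp yields the conventional 5 kb promoter.
    Centering ignores strand (the TSS coordinate itself is strand-aware);
    identical TSSs from multiple transcripts are deduplicated. Intervals are
    clipped at position 0 and, when a genome is supplied, at chromosome ends.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    seen = set()
    out: List[GenomicInterval] = []
    for t in transcripts:
        key = (t.chrom, t.tss)
        if key in seen:
            continue
        seen.add(key)
        start = max(0, t.tss - flank)
        end = t.tss + flank
        if genome is not None:
            end = min(end, genome.lengths[t.chrom])
        out.append(GenomicInterval(t.chrom, start, end, name=t.gene))
    out.sort(key=GenomicInterval.sort_key)
    return out


def make_genic_regions(
    transcripts: Sequence[TranscriptModel],
) -> List[GenomicInterval]:
    """One interval per gene: the transcript span maximizing ``|TES - TSS|``.

    Ties between equally long transcripts resolve to the lowest start
    coordinate (stable under input order).
    """
    best: Dict[str, Tuple[int, int, str]] = {}
    for t in transcripts:
        start, end = min(t.tss, t.tes), max(t.tss, t.tes)
        cur = best.get(t.gene)
        if cur is None or (end - start, -start) > (cur[1] - cur[0], -cur[0]):
            best[t.gene] = (start, end, t.chrom)
    out = [
        GenomicInterval(chrom, start, end, name=gene)
        for gene, (start, end, chrom) in best.items()
    ]
    out.sort(key=GenomicInterval.sort_key)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: overlapping (>=1 bp) regions are merged per chromosome.

    Book-ended intervals (sharing only a boundary coordinate) are merged too,
    since their union is a single contiguous region.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=GenomicInterval.sort_key)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def interval_union_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals)) if intervals else 0


def filter_blacklist(
    intervals: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval],
) -> List[GenomicInterval]:
    """Drop every interval overlapping a blacklist region by >=1 bp."""
    if not blacklist:
        return list(intervals)
    merged = merge_intervals(blacklist)
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    for chrom in {iv.chrom for iv in merged}:
        chrom_ivs = [iv for iv in merged if iv.chrom == chrom]
        starts[chrom] = np.array([iv.start for iv in chrom_ivs])
        ends[chrom] = np.array([iv.end for iv in chrom_ivs])
    kept = []
    for iv in intervals:
        if iv.chrom not in starts:
            kept.append(iv)
            continue
        # merged blocks are disjoint+sorted: the only candidate overlapping
        # block is the last one starting before iv.end
        idx = int(np.searchsorted(starts[iv.chrom], iv.end, side="left"))
        if idx == 0 or ends[iv.chrom][idx - 1] <= iv.start:
            kept.append(iv)
    return kept
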