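"""Spike-in (ChIP-Rx) quantification and track normalization.

ChIP-seq enrichment is a relative measure: each library sees only its own
immunoprecipitated fraction, so a genome-wide loss of a histone mark is
invisible after ordinary depth normalization. Spiking a fixed proportion of
exogenous (e.g. Drosophila) chromatin into every ChIP provides an internal
scale. For a ChIP sample with target-genome read fraction ``s`` and spike-in
fraction ``s_spike``, and its input with fractions ``i``/``i_spike``, the Rx
ratio is::

    Rx = (s / s_spike) / (i / i_spike)

Tracks scaled by Rx are comparable in absolute mark abundance across samples.
This module also implements depth/input normalization of binned count tracks:

* ``rx_scale_track``:   v_i = count_i / total * Rx * norm_factor
* ``input_normalize``:  v_i = log2( ((S_i + c)/TS) / ((N_i + c)/TN) )
* ``input_normalize_with_rx`` additionally multiplies the ChIP term by Rx,
  which is exactly ``input_normalize + log2(Rx)``.
* ``rpkm``:             v_i = count_i / (width_kb * total/1e6)

The pseudocount ``c`` (default 1 raw read) is added to raw counts before any
scaling, keeping logarithms finite in empty bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .genome import GenomePartition, TagCollection, count_tags_in_intervals

__all__ = [
    "SpikeInStats",
    "RxPair",
    "BinTrack",
    "NormalizationConfig",
    "rx_ratio",
    "rx_scale_track",
    "input_normalize",
    "input_normalize_with_rx",
    "rpkm",
    "track_from_tags",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass(frozen=True)
class SpikeInStats:
    """Mapped-read fractions of one library: target genome vs spike-in genome."""

    s: float
    s_spike: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("target-genome read fraction must be positive")
        if self.s_spike <= 0:
            raise ValueError(
                "spike-in read fraction must be positive (unusable spike-in)"
            )
        if self.s + self.s_spike > 1 + 1e-9:
            raise ValueError("fractions sum to more than 1")

    @classmethod
    def from_counts(cls, n_target: int, n_spike: int) -> "SpikeInStats":
        total = n_target + n_spike
        if total == 0:
            raise ValueError("no mapped reads")
        return cls(n_target / total, n_spike / total)

    @classmethod
    def from_tags(cls, tags: TagCollection) -> "SpikeInStats":
        return cls.from_counts(tags.n_target, tags.n_spike)


def rx_ratio(chip: SpikeInStats, input: SpikeInStats) -> float:
    """ChIP-Rx ratio: (chip.s/chip.s_spike) / (input.s/input.s_spike)."""
    return (chip.s / chip.s_spike) / (input.s / input.s_spike)


@dataclass(frozen=True)
class RxPair:
    """A ChIP sample paired with its input, plus the derived Rx ratio."""

    chip: SpikeInStats
    input: SpikeInStats

    @property
    def rx(self) -> float:
        return rx_ratio(self.chip, self.input)


@dataclass(frozen=True)
class NormalizationConfig:
    """Constants of the normalization formulas.

    pseudocount: raw reads added per compartment before scaling (c = 1).
    norm_factor: common multiplier avoiding very small values (1e10).
    """

    pseudocount: float = 1.0
    norm_factor: float = 1e10
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0 or self.norm_factor <= 0:
            raise ValueError("pseudocount and norm_factor must be positive")


class BinTrack:
    """Per-bin values over a :class:`GenomePartition` plus the library total.

    ``values`` holds raw counts for count tracks (then ``sum(values) <=
    total_reads``) or normalized reals after a normalization step.
    """

    def __init__(
        self,
        partition: GenomePartition,
        values: Sequence[float],
        total_reads: Optional[int] = None,
        is_counts: bool = True,
    ):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(partition),):
            raise ValueError(
                f"expected {len(partition)} values, got {arr.shape}"
            )
        if is_counts:
            if np.any(arr < 0):
                raise ValueError("counts must be non-negative")
            if total_reads is not None and arr.sum() > total_reads + 1e-6:
                raise ValueError("bin counts exceed the library total")
        self.partition = partition
        self.values = arr
        self.total_reads = total_reads
        self.is_counts = is_counts

    def _require_same_partition(self, other: "BinTrack") -> None:
        if self.partition != other.partition:
            raise ValueError("tracks are binned on different partitions")


def track_from_tags(tags: TagCollection, partition: GenomePartition) -> BinTrack:
    """Bin a tag collection into per-bin counts; total_reads = n_target."""
    counts = count_tags_in_intervals(tags, partition.bins)
    return BinTrack(partition, counts, total_reads=tags.n_target, is_counts=True)


def rx_scale_track(
    track: BinTrack, rx: float, cfg: NormalizationConfig = NormalizationConfig()
) -> BinTrack:
    """Depth-normalize counts, scale by the sample's Rx and by norm_factor."""
    if not track.total_reads:
        raise ValueError("track has no library total")
    vals = track.values / track.total_reads * rx * cfg.norm_factor
    return BinTrack(track.partition, vals, total_reads=track.total_reads,
                    is_counts=False)


def _log_ratio(num: np.ndarray, den: np.ndarray, base: float) -> np.ndarray:
    if base == 2.0:
        return np.log2(num / den)
    return np.log(num / den) / np.log(base)


def input_normalize(
    chip: BinTrack, input: BinTrack, cfg: NormalizationConfig = NormalizationConfig()
) -> BinTrack:
    """log2 of depth-normalized, pseudocounted ChIP over input per bin."""
    chip._require_same_partition(input)
    if not chip.total_reads or not input.total_reads:
        raise ValueError("both tracks need library totals")
    c = cfg.pseudocount
    num = (chip.values + c) / chip.total_reads
    den = (input.values + c) / input.total_reads
    return BinTrack(chip.partition, _log_ratio(num, den, cfg.log_base),
                    total_reads=chip.total_reads, is_counts=False)


def input_normalize_with_rx(
    chip: BinTrack,
    input: BinTrack,
    rx: float,
    cfg: NormalizationConfig = NormalizationConfig(),
) -> BinTrack:
    """Input normalization with the ChIP term scaled by Rx.

    Algebraically identical to ``input_normalize(chip, input) + log2(rx)``;
    only the ChIP sample is Rx-scaled, never the input.
    """
    chip._require_same_partition(input)
    if not chip.total_reads or not input.total_reads:
        raise ValueError("both tracks need library totals")
    if rx <= 0:
        raise ValueError("rx must be positive")
    c = cfg.pseudocount
    num = rx * (chip.values + c) / chip.total_reads
    den = (input.values + c) / input.total_reads
    return BinTrack(chip.partition, _log_ratio(num, den, cfg.log_base),
                    total_reads=chip.total_reads, is_counts=False)


def rpkm(track: BinTrack) -> BinTrack:
    """Reads per kilobase per million mapped reads, using true bin widths."""
    if not track.total_reads:
        raise ValueError("track has no library total")
    width_kb = track.partition.bin_widths() / 1000.0
    vals = track.values / (width_kb * track.total_reads / 1e6)
    return BinTrack(track.partition, vals, total_reads=track.total_reads,
                    is_counts=False)


# ---------------------------------------------------------------------------
# bedGraph I/O


def write_bedgraph(track: BinTrack, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(track.partition)):
            iv = track.partition.bin_interval(i)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.values[i]:.6g}\n")


def read_bedgraph(path, partition: GenomePartition,
                  total_reads: Optional[int] = None) -> BinTrack:
    """Read a bedGraph written on ``partition`` back into a BinTrack."""
    vals = np.zeros(len(partition))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, value = line.split("\t")[:4]
            vals[partition.bin_index(chrom, int(start))] = float(value)
    return BinTrack(partition, vals, total_reads=total_reads, is_counts=False)
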