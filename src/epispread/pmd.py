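"""Partially methylated domain (PMD) calling from per-CpG WGBS calls.

PMDs are megabase-scale regions whose mean CpG methylation sits well below
the ~85% genome-wide background of somatic methylomes. The caller works on a
table of per-CpG records (chrom, pos, coverage, methylated fraction):

1. filter CpGs: coverage >= ``min_coverage`` (default 5), not at a known SNP,
   outside blacklist regions;
2. tile each chromosome with ``window``-bp windows stepped by ``increment``
   (both default 10 kb); a window whose mean methylation is below
   ``threshold`` (default 0.70) seeds a candidate;
3. extend the candidate rightward in ``increment`` steps; with the default
   ``extension="window_mean"`` rule the candidate grows while each added
   window is itself sub-threshold (CpG-free windows are neutral and are
   bridged), so domain boundaries land within one window of the true edge.
   The alternative ``extension="region_mean"`` rule grows the candidate while
   the running mean of the whole region stays sub-threshold, excluding the
   terminating increment; its right boundary then depends on how fast flanking
   high-methylation CpGs dilute the running mean, and can overshoot the
   domain edge by many windows;
4. overlapping candidates are merged and regions longer than ``min_length``
   (default 1 Mb, strict) are reported as PMDs.

Mean methylation is the unweighted mean of per-CpG methylated fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import GenomicInterval, merge_intervals

__all__ = [
    "CpGRecord",
    "PMDCallerConfig",
    "filter_cpgs",
    "seed_windows",
    "call_pmds",
    "read_cpg_table",
    "write_cpg_table",
]

CPG_COLUMNS = ["chrom", "pos", "coverage", "meth_fraction"]


@dataclass(frozen=True)
class CpGRecord:
    """One CpG methylation call."""

    chrom: str
    pos: int
    coverage: int
    meth_fraction: float

    def __post_init__(self) -> None:
        if self.pos < 0 or self.coverage < 0:
            raise ValueError("negative position or coverage")
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise ValueError("meth_fraction outside [0, 1]")


@dataclass(frozen=True)
class PMDCallerConfig:
    window: int = 10_000
    increment: int = 10_000
    threshold: float = 0.70
    min_length: int = 1_000_000
    min_coverage: int = 5
    extension: str = "window_mean"  # or "region_mean"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.increment <= 0 or self.min_length <= 0:
            raise ValueError("window, increment and min_length must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.extension not in ("window_mean", "region_mean"):
            raise ValueError(f"unknown extension rule {self.extension!r}")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, CPG_COLUMNS].reset_index(drop=True)
    else:
        df = pd.DataFrame(
            [(r.chrom, r.pos, r.coverage, r.meth_fraction) for r in records],
            columns=CPG_COLUMNS,
        )
    return df


def _check_sorted(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) >= 0):
            raise ValueError(f"CpG records not sorted by position on {chrom}")


def filter_cpgs(
    records,
    cfg: PMDCallerConfig = PMDCallerConfig(),
    blacklist: Sequence[GenomicInterval] = (),
    snp_positions: Iterable[Tuple[str, int]] = (),
) -> pd.DataFrame:
    """Coverage / SNP / blacklist filter preceding PMD calling.

    Retains CpGs with coverage >= ``cfg.min_coverage`` whose position is not a
    known SNP and lies outside every blacklist interval.
    """
    df = _as_frame(records)
    keep = df["coverage"].to_numpy() >= cfg.min_coverage
    snps: Set[Tuple[str, int]] = set(snp_positions)
    if snps:
        keep &= ~np.array(
            [(c, p) in snps for c, p in zip(df["chrom"], df["pos"])], dtype=bool
        )
    if blacklist:
        merged = merge_intervals(list(blacklist))
        starts: Dict[str, np.ndarray] = {}
        ends: Dict[str, np.ndarray] = {}
        for chrom in {iv.chrom for iv in merged}:
            ivs = [iv for iv in merged if iv.chrom == chrom]
            starts[chrom] = np.array([iv.start for iv in ivs])
            ends[chrom] = np.array([iv.end for iv in ivs])
        in_black = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in starts:
                continue
            pos = sub["pos"].to_numpy()
            idx = np.searchsorted(starts[chrom], pos, side="right")
            hit = (idx > 0) & (pos < ends[chrom][np.maximum(idx - 1, 0)])
            in_black[sub.index] = hit
        keep &= ~in_black
    return df.loc[keep].reset_index(drop=True)


def _window_stats(
    pos: np.ndarray, meth: np.ndarray, start: int, end: int
) -> Tuple[int, float]:
    """(CpG count, methylation sum) over [start, end)."""
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    return hi - lo, float(meth[lo:hi].sum())


def seed_windows(records, cfg: PMDCallerConfig = PMDCallerConfig()) -> List[
    Tuple[str, int]
]:
    """(chrom, window start) of every window seeding a PMD candidate.

    A window seeds iff it contains at least one CpG and its mean methylated
    fraction is strictly below ``cfg.threshold``; a window at exactly the
    threshold does not seed.
    """
    df = _as_frame(records)
    _check_sorted(df)
    seeds: List[Tuple[str, int]] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = sub["meth_fraction"].to_numpy()
        if pos.size == 0:
            continue
        last = int(pos[-1])
        for start in range(0, last + 1, cfg.increment):
            n, total = _window_stats(pos, meth, start, start + cfg.window)
            if n > 0 and total / n < cfg.threshold:
                seeds.append((chrom, start))
    return seeds


def _extend_window_mean(
    pos: np.ndarray, meth: np.ndarray, start: int, cfg: PMDCallerConfig, limit: int
) -> int:
    """Right edge of the candidate: last sub-threshold window of the run.

    CpG-free windows neither stop nor extend the run; the candidate end is
    the end of the last CpG-containing sub-threshold window reached.
    """
    end = start + cfg.window
    probe = end
    while probe < limit:
        n, total = _window_stats(pos, meth, probe, probe + cfg.increment)
        if n > 0:
            if total / n >= cfg.threshold:
                break
            end = probe + cfg.increment
        probe += cfg.increment
    return end


def _extend_region_mean(
    pos: np.ndarray, meth: np.ndarray, start: int, cfg: PMDCallerConfig, limit: int
) -> int:
    """Right edge under the literal running-region-mean rule.

    The region grows by one increment at a time while its overall mean stays
    sub-threshold; the increment that pushes the mean to or above the
    threshold is excluded. Empty increments leave the mean unchanged and the
    region keeps growing through them until the chromosome's last CpG window.
    """
    end = start + cfg.window
    n, total = _window_stats(pos, meth, start, end)
    while end < limit:
        n_add, t_add = _window_stats(pos, meth, end, end + cfg.increment)
        if n_add > 0 and (total + t_add) / (n + n_add) >= cfg.threshold:
            break
        n, total = n + n_add, total + t_add
        end += cfg.increment
    return end


def call_pmds(records, cfg: PMDCallerConfig = PMDCallerConfig()) -> List[
    GenomicInterval
]:
    """Seed-and-extend PMD calling on (already filtered) CpG records.

    Returns sorted, pairwise-disjoint intervals of length strictly greater
    than ``cfg.min_length`` whose mean methylation is below ``cfg.threshold``.
    """
    df = _as_frame(records)
    _check_sorted(df)
    extend = (
        _extend_window_mean if cfg.extension == "window_mean" else _extend_region_mean
    )
    candidates: List[GenomicInterval] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = sub["meth_fraction"].to_numpy()
        if pos.size == 0:
            continue
        last = int(pos[-1])
        # limit: end of the last window that can contain a CpG
        limit = (last // cfg.increment) * cfg.increment + cfg.window
        called_until = -1
        for start in range(0, last + 1, cfg.increment):
            if start < called_until:
                continue  # seed inside an already-called candidate
            n, total = _window_stats(pos, meth, start, start + cfg.window)
            if n == 0 or total / n >= cfg.threshold:
                continue
            end = extend(pos, meth, start, cfg, limit)
            candidates.append(GenomicInterval(chrom, start, end))
            called_until = end
    merged = merge_intervals(candidates) if candidates else []
    return [iv for iv in merged if iv.length > cfg.min_length]


# ---------------------------------------------------------------------------
# I/O: bedGraph-like TSV (chrom, pos, coverage, meth_fraction)


def read_cpg_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=CPG_COLUMNS,
        dtype={"chrom": str, "pos": int, "coverage": int, "meth_fraction": float},
    )
    return df


def write_cpg_table(records, path) -> None:
    df = _as_frame(records)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CPG_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
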