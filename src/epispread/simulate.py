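"""Synthetic datasets emulating the K27M vs wild-type chromatin regimes.

The generator produces, with known ground truth and full determinism,
everything the downstream statistics consume:

* **annotations** — non-overlapping CpG islands, of which the widest fraction
  are unmethylated PRC2 *nucleation* sites (DNA methylation ~0.05 vs ~0.65
  elsewhere); SUZ12 peaks coincide with nucleation CGIs; promoters/transcripts
  with the first genes anchored at CGIs; a random blacklist.
* **ChIP samples** — tag collections drawn per condition and mark from a
  piecewise-constant rate map: in the wild-type (WT) regime H3K27me3 forms
  broad domains (nucleation CGIs +/- ``spread_length``, plus PMDs) and
  H3K27me2 blankets the complement; in the K27M regime H3K27me3 collapses to
  focal peaks (nucleation CGIs +/- ``peak_width``) while H3K27me2 moves into
  the WT H3K27me3 footprint. Inputs are uniform. Spike-in reads are tallied
  (never placed); target rates are scaled by a per-mark abundance ratio at a
  fixed spike-in rate, which is how a global mark loss manifests in ChIP-Rx.
* **methylome** — CpGs every ~100 bp, coverage ~Poisson(30) with a configured
  fraction of low-coverage sites, methylated fraction ~0.85 outside planted
  PMDs and at each PMD's configured mean inside.
* **expression** — a DE-statistics table with planted up/downregulated genes,
  upregulation skewed toward low parental-expression deciles.

Counts are Poisson per 100-bp generation bin with tags placed uniformly
within the bin; overdispersion is deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genome import (
    GenomeDescription,
    GenomicInterval,
    TagCollection,
    TranscriptModel,
    merge_intervals,
    write_bed,
    write_chrom_sizes,
    write_transcript_table,
)
from .pmd import write_cpg_table

__all__ = [
    "SimulationConfig",
    "Annotations",
    "SimulatedDataset",
    "simulate_annotations",
    "simulate_chip_sample",
    "simulate_methylome",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]

CONDITIONS = ("WT", "K27M")
MARKS = ("me3", "me2", "input", "suz12")

# stable per-sample RNG stream ids (seed sequence spawn keys)
_SAMPLE_STREAM = {
    (cond, mark): 10 * ci + mi
    for ci, cond in enumerate(CONDITIONS)
    for mi, mark in enumerate(MARKS)
}
_ANNOT_STREAM = 1000
_METH_STREAM = 1001
_EXPR_STREAM = 1002


def _default_genome() -> GenomeDescription:
    return GenomeDescription((("chr1", 5_000_000), ("chr2", 5_000_000)))


def _default_pmd_spec() -> List[Tuple[str, int, int, float]]:
    return [
        ("chr1", 3_000_000, 4_500_000, 0.50),
        ("chr2", 500_000, 1_700_000, 0.55),
    ]


def _default_abundance() -> Dict[str, float]:
    # K27M / WT genome-wide abundance per mark: H3K27me3 is strongly depleted
    # in K27M cells, H3K27me2 mildly; inputs and SUZ12 are unchanged.
    return {"me3": 0.2, "me2": 0.7, "suz12": 1.0, "input": 1.0}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; a pure function of this fixes the data."""

    seed: int = 0
    genome: GenomeDescription = field(default_factory=_default_genome)
    n_cgi: int = 200
    nucleation_fraction: float = 0.2
    peak_width: int = 4_000
    spread_length: int = 100_000
    pmd_spec: List[Tuple[str, int, int, float]] = field(
        default_factory=_default_pmd_spec
    )
    depth: int = 200_000
    spike_fraction: float = 0.05
    spike_fractions: Dict[Tuple[str, str], float] = field(default_factory=dict)
    abundance_ratio: Dict[str, float] = field(default_factory=_default_abundance)
    background_rate: float = 1.0
    enrichment_rate: float = 30.0
    suz12_flank_wt: int = 1_000
    suz12_flank_k27m: int = 5_000
    n_blacklist: int = 8
    blacklist_width: int = 20_000
    cgi_log_width_mean: float = 7.1  # exp(7.1) ~ 1200 bp
    cgi_log_width_sd: float = 0.45
    meth_background: float = 0.85
    meth_concentration: float = 60.0
    cpg_spacing: float = 100.0
    coverage_mean: float = 30.0
    low_coverage_fraction: float = 0.05
    low_coverage_mean: float = 2.0
    n_genes: int = 2_000
    n_up: int = 102
    n_down: int = 12
    gen_resolution: int = 100

    def __post_init__(self) -> None:
        for name, frac in (
            ("nucleation_fraction", self.nucleation_fraction),
            ("spike_fraction", self.spike_fraction),
        ):
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.background_rate < 0 or self.enrichment_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("more DE genes than genes")

    def sample_spike_fraction(self, condition: str, mark: str) -> float:
        """Configured spike fraction of one sample at reference abundance."""
        return self.spike_fractions.get((condition, mark), self.spike_fraction)

    def expected_spike_fraction(self, condition: str, mark: str) -> float:
        """Expected realized spike fraction after abundance scaling.

        The spike-in rate is fixed while target rates scale with the mark's
        abundance ratio, so a globally depleted mark shows an elevated
        spike fraction — the signal ChIP-Rx quantification reads out.
        """
        base = self.sample_spike_fraction(condition, mark)
        scale = self.abundance_scale(condition, mark)
        s_exp = self.depth * base / (1.0 - base)
        return s_exp / (s_exp + scale * self.depth)

    def abundance_scale(self, condition: str, mark: str) -> float:
        if condition == "WT":
            return 1.0
        return float(self.abundance_ratio.get(mark, 1.0))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class Annotations:
    """Ground-truth annotation set shared by every simulated sample."""

    cgis: List[GenomicInterval]
    nucleation: np.ndarray  # bool per CGI
    cgi_methylation: np.ndarray  # fraction per CGI
    suz12_peaks: List[GenomicInterval]
    transcripts: List[TranscriptModel]
    promoters: List[GenomicInterval]
    blacklist: List[GenomicInterval]

    @property
    def nucleation_cgis(self) -> List[GenomicInterval]:
        return [iv for iv, n in zip(self.cgis, self.nucleation) if n]


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: GenomeDescription,
    widths: np.ndarray,
) -> List[GenomicInterval]:
    """Place intervals of given widths uniformly without overlap.

    Widths are distributed over chromosomes proportionally to length, then
    positioned by drawing the inter-interval gaps uniformly from the simplex
    (stick breaking), which is the uniform law on non-overlapping placements.
    """
    order = rng.permutation(len(widths))
    n_chroms = len(genome.chroms)
    lengths = np.array([l for _, l in genome.chroms], dtype=float)
    assign = rng.choice(n_chroms, size=len(widths), p=lengths / lengths.sum())
    out: List[GenomicInterval] = []
    for ci, (chrom, length) in enumerate(genome.chroms):
        w = widths[order][assign == ci]
        if w.size == 0:
            continue
        slack = length - w.sum()
        if slack < 0:
            raise ValueError(f"genome too small to place intervals on {chrom}")
        gaps = np.sort(rng.uniform(0, slack, size=w.size))
        starts = (gaps + np.concatenate([[0], np.cumsum(w[:-1])])).astype(int)
        for s, width in zip(starts, w):
            out.append(GenomicInterval(chrom, int(s), int(s + width)))
    out.sort(key=GenomicInterval.sort_key)
    return out


def simulate_annotations(config: SimulationConfig) -> Annotations:
    """CGIs, SUZ12 peaks, transcripts/promoters and a blacklist with truth flags.

    The widest ``n_cgi * nucleation_fraction`` CGIs are flagged as nucleation
    sites: large unmethylated CGIs are the high-affinity PRC2 recruitment
    sites, so width and hypomethylation co-occur by construction.
    """
    rng = config._rng(_ANNOT_STREAM)
    widths = np.exp(
        rng.normal(config.cgi_log_width_mean, config.cgi_log_width_sd, config.n_cgi)
    ).astype(int)
    widths = np.maximum(widths, 200)
    cgis = _place_nonoverlapping(rng, config.genome, widths)
    cgis = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"cgi_{i:04d}")
        for i, iv in enumerate(cgis)
    ]
    n_nuc = int(round(config.n_cgi * config.nucleation_fraction))
    cgi_widths = np.array([iv.length for iv in cgis])
    nucleation = np.zeros(len(cgis), dtype=bool)
    if n_nuc > 0:
        nucleation[np.argsort(-cgi_widths, kind="stable")[:n_nuc]] = True
    meth = np.where(
        nucleation,
        rng.normal(0.05, 0.02, len(cgis)),
        rng.normal(0.65, 0.08, len(cgis)),
    ).clip(0.0, 1.0)
    suz12 = [iv for iv, n in zip(cgis, nucleation) if n]

    # genes: one per CGI anchored at its midpoint, remainder at random TSSs
    transcripts: List[TranscriptModel] = []
    lengths = config.genome.lengths
    for i, iv in enumerate(cgis):
        tss = iv.midpoint
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(5_000, 50_000))
        tes = tss + span if strand == "+" else max(0, tss - span)
        if tes == tss:
            tes = tss + span
        transcripts.append(
            TranscriptModel(f"gene_{i:04d}", f"tx_{i:04d}", iv.chrom, strand, tss, tes)
        )
    chrom_names = config.genome.names
    for i in range(len(cgis), config.n_genes):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        tss = int(rng.integers(60_000, lengths[chrom] - 60_000))
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(5_000, 50_000))
        tes = tss + span if strand == "+" else tss - span
        transcripts.append(
            TranscriptModel(f"gene_{i:04d}", f"tx_{i:04d}", chrom, strand, tss, tes)
        )
    from .genome import make_promoters

    promoters = make_promoters(transcripts, genome=config.genome)

    bl_widths = np.full(config.n_blacklist, config.blacklist_width)
    blacklist = (
        _place_nonoverlapping(rng, config.genome, bl_widths)
        if config.n_blacklist
        else []
    )
    return Annotations(
        cgis=cgis,
        nucleation=nucleation,
        cgi_methylation=meth,
        suz12_peaks=suz12,
        transcripts=transcripts,
        promoters=promoters,
        blacklist=blacklist,
    )


def _flanked(ivs: Sequence[GenomicInterval], flank: int,
             genome: GenomeDescription) -> List[GenomicInterval]:
    out = []
    for iv in ivs:
        out.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - flank),
                min(genome.lengths[iv.chrom], iv.end + flank),
            )
        )
    return merge_intervals(out)


def _complement(ivs: Sequence[GenomicInterval],
                genome: GenomeDescription) -> List[GenomicInterval]:
    merged = merge_intervals(ivs) if ivs else []
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom, length in genome.chroms:
        cursor = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return out


def wt_me3_footprint(config: SimulationConfig,
                     annotations: Annotations) -> List[GenomicInterval]:
    """The broad WT H3K27me3 domains: nucleation CGIs +/- spread_length, plus PMDs."""
    domains = _flanked(annotations.nucleation_cgis, config.spread_length, config.genome)
    pmds = [GenomicInterval(c, s, e) for c, s, e, _m in config.pmd_spec]
    return merge_intervals(domains + pmds)


def enriched_regions(
    config: SimulationConfig, annotations: Annotations, condition: str, mark: str
) -> List[GenomicInterval]:
    """Rate-map support of one sample: where the mark sits above background."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    if mark == "input":
        return []
    wt_me3 = wt_me3_footprint(config, annotations)
    if mark == "me3":
        if condition == "WT":
            return wt_me3
        return _flanked(annotations.nucleation_cgis, config.peak_width, config.genome)
    if mark == "me2":
        # K27M H3K27me2 occupies exactly the WT H3K27me3 footprint; WT
        # H3K27me2 blankets its complement.
        return wt_me3 if condition == "K27M" else _complement(wt_me3, config.genome)
    flank = config.suz12_flank_k27m if condition == "K27M" else config.suz12_flank_wt
    return _flanked(annotations.nucleation_cgis, flank, config.genome)


def _rate_weights(
    config: SimulationConfig,
    regions: Sequence[GenomicInterval],
) -> Tuple[Dict[str, np.ndarray], float]:
    """Per generation-bin sampling weights (expected tags up to normalization)."""
    res = config.gen_resolution
    weights: Dict[str, np.ndarray] = {}
    for chrom, length in config.genome.chroms:
        n = -(-length // res)
        edges = np.minimum(np.arange(n + 1) * res, length).astype(float)
        w = config.background_rate * np.diff(edges)
        weights[chrom] = w
    extra = config.enrichment_rate - config.background_rate
    for iv in regions:
        w = weights[iv.chrom]
        first, last = iv.start // res, (iv.end - 1) // res
        for b in range(first, last + 1):
            lo = max(iv.start, b * res)
            hi = min(iv.end, (b + 1) * res)
            w[b] += extra * (hi - lo)
    total = float(sum(w.sum() for w in weights.values()))
    return weights, total


def expected_tag_fraction(
    config: SimulationConfig,
    annotations: Annotations,
    condition: str,
    mark: str,
    features: Sequence[GenomicInterval],
) -> float:
    """Expected fraction of a sample's tags inside the union of ``features``.

    Computed from the configured rate map before any sampling; used to verify
    structural claims about the regimes independently of the draws.
    """
    regions = enriched_regions(config, annotations, condition, mark)
    merged = merge_intervals(list(features)) if features else []
    res = config.gen_resolution
    weights, total = _rate_weights(config, regions)
    inside = 0.0
    for iv in merged:
        w = weights[iv.chrom]
        first, last = iv.start // res, (iv.end - 1) // res
        for b in range(first, last + 1):
            lo = max(iv.start, b * res)
            hi = min(iv.end, (b + 1) * res)
            bin_lo = b * res
            bin_hi = min((b + 1) * res, config.genome.lengths[iv.chrom])
            inside += w[b] * (hi - lo) / (bin_hi - bin_lo)
    return inside / total


def simulate_chip_sample(
    config: SimulationConfig,
    condition: str,
    mark: str,
    annotations: Optional[Annotations] = None,
) -> TagCollection:
    """Draw one ChIP (or input) sample as a TagCollection with spike-in tally.

    Per 100-bp generation bin the tag count is Poisson with mean proportional
    to the condition/mark rate map, normalized so the expected target total is
    ``depth * abundance_scale``; tags are placed uniformly within their bin.
    The spike-in count is Poisson with a mean independent of abundance scale.
    """
    if annotations is None:
        annotations = simulate_annotations(config)
    regions = enriched_regions(config, annotations, condition, mark)
    rng = config._rng(_SAMPLE_STREAM[(condition, mark)])
    scale = config.abundance_scale(condition, mark)
    weights, total_weight = _rate_weights(config, regions)
    expected_total = config.depth * scale
    res = config.gen_resolution
    tags: Dict[str, np.ndarray] = {}
    for chrom, length in config.genome.chroms:
        lam = weights[chrom] / total_weight * expected_total
        counts = rng.poisson(lam)
        n_bins = lam.size
        starts = np.repeat(np.arange(n_bins) * res, counts)
        bin_len = np.minimum((np.arange(n_bins) + 1) * res, length) - np.arange(
            n_bins
        ) * res
        span = np.repeat(bin_len, counts)
        pos = starts + np.floor(rng.random(starts.size) * span).astype(np.int64)
        tags[chrom] = np.sort(pos)
    base = config.sample_spike_fraction(condition, mark)
    spike_mean = config.depth * base / (1.0 - base)
    n_spike = int(rng.poisson(spike_mean))
    return TagCollection(tags, n_spike=n_spike, genome=config.genome)


def simulate_methylome(config: SimulationConfig) -> pd.DataFrame:
    """Per-CpG calls with planted PMDs (chrom, pos, coverage, meth_fraction)."""
    spec = sorted(config.pmd_spec)
    for (c1, s1, e1, _), (c2, s2, e2, _) in zip(spec, spec[1:]):
        if c1 == c2 and e1 > s2:
            raise ValueError("overlapping pmd_spec regions")
    for chrom, start, end, mean in config.pmd_spec:
        if chrom not in config.genome or end > config.genome.lengths[chrom]:
            raise ValueError(f"pmd_spec region outside genome: {chrom}:{start}-{end}")
        if not 0.0 < mean < 1.0:
            raise ValueError("pmd mean methylation must lie in (0, 1)")
    rng = config._rng(_METH_STREAM)
    rows = []
    kappa = config.meth_concentration
    for chrom, length in config.genome.chroms:
        gaps = rng.exponential(config.cpg_spacing, int(2.2 * length / config.cpg_spacing))
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        pos = pos[pos < length]
        mean = np.full(pos.size, config.meth_background)
        for c, s, e, m in config.pmd_spec:
            if c == chrom:
                mean[(pos >= s) & (pos < e)] = m
        meth = rng.beta(mean * kappa, (1.0 - mean) * kappa)
        coverage = rng.poisson(config.coverage_mean, pos.size)
        low = rng.random(pos.size) < config.low_coverage_fraction
        coverage[low] = rng.poisson(config.low_coverage_mean, int(low.sum()))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "coverage": coverage,
                    "meth_fraction": meth,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_expression(config: SimulationConfig) -> pd.DataFrame:
    """DE-statistics table with planted truth labels.

    Columns: gene, log2fc, padj, parental_expression, true_label. Upregulated
    genes are drawn preferentially from low-expression genes, emulating the
    excess of lowly-expressed upregulated genes in the K27M regime; effects
    are well separated from the classification thresholds (|lfc| > 1.5,
    padj < 1e-3 for DE; |lfc| < 0.9, padj >= 0.1 otherwise).
    """
    rng = config._rng(_EXPR_STREAM)
    n = config.n_genes
    genes = [f"gene_{i:04d}" for i in range(n)]
    parental = np.exp(rng.normal(2.0, 1.2, n))
    order = np.argsort(np.argsort(parental, kind="stable"), kind="stable")
    # sampling weight decays with expression rank: low deciles favoured ~e^3-fold
    up_weight = np.exp(-3.0 * order / n)
    up_idx = rng.choice(n, size=config.n_up, replace=False,
                        p=up_weight / up_weight.sum())
    remaining = np.setdiff1d(np.arange(n), up_idx)
    down_idx = rng.choice(remaining, size=config.n_down, replace=False)
    label = np.array(["NS"] * n, dtype=object)
    label[up_idx] = "Up"
    label[down_idx] = "Down"
    log2fc = rng.normal(0.0, 0.3, n).clip(-0.9, 0.9)
    log2fc[up_idx] = 1.5 + rng.exponential(1.0, config.n_up)
    log2fc[down_idx] = -(1.5 + rng.exponential(1.0, config.n_down))
    padj = rng.uniform(0.1, 1.0, n)
    de = label != "NS"
    padj[de] = 10 ** rng.uniform(-8, -3, int(de.sum()))
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "padj": padj,
            "parental_expression": parental,
            "true_label": label,
        }
    )


@dataclass
class SimulatedDataset:
    """A full synthetic study: annotations, samples, methylome, expression."""

    config: SimulationConfig
    annotations: Annotations
    samples: Dict[Tuple[str, str], TagCollection]
    methylome: pd.DataFrame
    expression: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate every component; bit-identical under a repeated seed."""
    annotations = simulate_annotations(config)
    samples = {
        (cond, mark): simulate_chip_sample(config, cond, mark, annotations)
        for cond in CONDITIONS
        for mark in MARKS
    }
    return SimulatedDataset(
        config=config,
        annotations=annotations,
        samples=samples,
        methylome=simulate_methylome(config),
        expression=simulate_expression(config),
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Emit the dataset in the same formats the pipeline readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ann = dataset.annotations
    write_chrom_sizes(dataset.config.genome, out / "genome.chrom.sizes")
    write_bed(ann.cgis, out / "cgis.bed")
    write_bed(ann.suz12_peaks, out / "suz12_peaks.bed")
    write_bed(ann.promoters, out / "promoters.bed")
    if ann.blacklist:
        write_bed(ann.blacklist, out / "blacklist.bed")
    write_transcript_table(ann.transcripts, out / "transcripts.tsv")
    pd.DataFrame(
        {
            "cgi": [iv.name for iv in ann.cgis],
            "nucleation": ann.nucleation.astype(int),
            "dna_methylation": ann.cgi_methylation,
        }
    ).to_csv(out / "cgi_annotations.tsv", sep="\t", index=False)

    spike_rows = []
    for (cond, mark), tags in dataset.samples.items():
        name = f"{cond}_{mark}"
        with open(out / f"{name}.tags.tsv", "w") as fh:
            for chrom in dataset.config.genome.names:
                for pos in tags.tags.get(chrom, ()):
                    fh.write(f"{chrom}\t{pos}\n")
        spike_rows.append((name, tags.n_target, tags.n_spike))
    pd.DataFrame(
        spike_rows, columns=["sample", "target_reads", "spike_reads"]
    ).to_csv(out / "spike_counts.tsv", sep="\t", index=False)

    write_cpg_table(dataset.methylome, out / "methylome.tsv")
    dataset.expression.to_csv(out / "expression.tsv", sep="\t", index=False)

    manifest = {
        "seed": dataset.config.seed,
        "genome": {c: l for c, l in dataset.config.genome.chroms},
        "n_cgi": dataset.config.n_cgi,
        "nucleation_fraction": dataset.config.nucleation_fraction,
        "peak_width": dataset.config.peak_width,
        "spread_length": dataset.config.spread_length,
        "pmd_spec": [list(p) for p in dataset.config.pmd_spec],
        "depth": dataset.config.depth,
        "spike_fraction": dataset.config.spike_fraction,
        "abundance_ratio": dict(dataset.config.abundance_ratio),
        "background_rate": dataset.config.background_rate,
        "enrichment_rate": dataset.config.enrichment_rate,
        "n_genes": dataset.config.n_genes,
        "n_up": dataset.config.n_up,
        "n_down": dataset.config.n_down,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
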