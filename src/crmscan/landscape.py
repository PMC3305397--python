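"""Genome-wide non-coding landscape statistics and percentile ranking.

The question answered here: how does a query region (e.g. the intergenic
neighbourhood of a gene of interest) compare with *all* non-coding regions
of a genome in (a) average conservation and (b) density of conserved
transcription-factor binding motifs per 1000 bp?  The answer is an
empirical percentile: the percentage of non-coding regions whose metric is
strictly less than the query's.

Non-coding regions are, by default, the complement of annotated exons
(introns + intergenic); the complement of whole gene spans (intergenic
only) is available as an option.  Regions shorter than a minimum length are
dropped because per-kb densities on very short regions are numerically
unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationConfig, conserved_hits, mean_conservation
from .genome_io import AnnotationSet, GenomeSequence
from .intervals import GenomicInterval
from .motifs import MotifHit, PWM, ScanConfig, scan_sequence
from .tracks import ConservationTrack

__all__ = [
    "RegionStats",
    "LandscapeDistribution",
    "LandscapeConfig",
    "extract_noncoding",
    "region_stats",
    "landscape_percentile",
    "run_landscape",
    "LandscapeReport",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Operational definition of the non-coding comparison universe."""

    noncoding_definition: str = "exon_complement"
    min_region_length: int = 100
    density_unit: int = 1000

    def __post_init__(self):
        if self.noncoding_definition not in ("exon_complement", "gene_complement"):
            raise ValueError(
                f"unknown noncoding_definition {self.noncoding_definition!r}"
            )
        if self.min_region_length < 1:
            raise ValueError("min_region_length must be >= 1")


@dataclass(frozen=True)
class RegionStats:
    """Per-region record: mean conservation and conserved-motif density."""

    interval: GenomicInterval
    mean_conservation: float
    n_conserved_motifs: int

    @property
    def motif_density(self) -> float:
        """Conserved motifs per 1000 bp."""
        return self.n_conserved_motifs / self.interval.length() * 1000.0

    @property
    def name(self) -> str:
        return str(self.interval)

    def bed_score(self) -> int:
        return int(round(self.mean_conservation * 1000))

    def metric(self, name: str) -> float:
        if name == "mean_conservation":
            return self.mean_conservation
        if name == "motif_density":
            return self.motif_density
        raise ValueError(f"unknown metric {name!r}")


@dataclass
class LandscapeDistribution:
    """Genome-wide collection of RegionStats for percentile queries."""

    regions: list[RegionStats]

    def __len__(self) -> int:
        return len(self.regions)

    def metrics(self, name: str) -> np.ndarray:
        return np.array([r.metric(name) for r in self.regions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in self.regions],
                "start": [r.interval.start for r in self.regions],
                "end": [r.interval.end for r in self.regions],
                "length": [r.interval.length() for r in self.regions],
                "mean_conservation": [r.mean_conservation for r in self.regions],
                "n_conserved_motifs": [r.n_conserved_motifs for r in self.regions],
                "motif_density_per_kb": [r.motif_density for r in self.regions],
            }
        )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def extract_noncoding(
    annotation: AnnotationSet,
    chrom_lengths: Mapping[str, int],
    config: LandscapeConfig | None = None,
) -> list[GenomicInterval]:
    """Complement of the masking features on every chromosome.

    Masking features are exons (``exon_complement``) or whole gene spans
    (``gene_complement``).  Regions shorter than ``min_region_length`` are
    dropped; the output is disjoint and sorted by (chrom, start).
    """
    if config is None:
        config = LandscapeConfig()
    mask_type = "exon" if config.noncoding_definition == "exon_complement" else "gene"
    masking = annotation.of_type(mask_type)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for f in masking:
        iv = f.interval
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"annotation feature on unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_lengths[iv.chrom]:
            raise ValueError(
                f"feature {iv} exceeds chromosome length {chrom_lengths[iv.chrom]}"
            )
        by_chrom[iv.chrom].append((iv.start, iv.end))
    regions: list[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pos = 0
        for s, e in _merge_intervals(by_chrom.get(chrom, [])):
            if s > pos:
                regions.append(GenomicInterval(chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            regions.append(GenomicInterval(chrom, pos, length))
    return [r for r in regions if r.length() >= config.min_region_length]


def region_stats(
    region: GenomicInterval,
    track: ConservationTrack,
    hits: Sequence[MotifHit],
    conservation_config: ConservationConfig | None = None,
    hits_are_conserved: bool = False,
) -> RegionStats:
    """Mean conservation plus conserved-motif count/density for one region.

    ``hits`` should already be restricted to the motif set of interest; a
    hit is assigned to the region containing its *start* coordinate.  Pass
    ``hits_are_conserved=True`` when the conservation filter has already
    been applied (avoids refiltering in genome-wide loops).
    """
    if conservation_config is None:
        conservation_config = ConservationConfig()
    mean = mean_conservation(track, region, conservation_config.missing_policy)
    pool = list(hits) if hits_are_conserved else conserved_hits(hits, track, conservation_config)
    n = sum(
        1
        for h in pool
        if h.interval.chrom == region.chrom and region.contains(h.interval.start)
    )
    return RegionStats(region, mean, n)


def landscape_percentile(
    dist: LandscapeDistribution,
    query: RegionStats,
    metric: str,
) -> float:
    """Percentage of regions with metric strictly less than the query's.

    If the query interval is itself a member of the distribution it is
    excluded from the denominator.
    """
    if len(dist) == 0:
        raise ValueError("empty landscape distribution")
    qv = query.metric(metric)
    others = [r for r in dist.regions if r.interval != query.interval]
    if not others:
        raise ValueError("distribution holds only the query region")
    below = sum(1 for r in others if r.metric(metric) < qv)
    return 100.0 * below / len(others)


@dataclass
class LandscapeReport:
    """Full output of the genome-wide landscape analysis for one query."""

    distribution: LandscapeDistribution
    query_stats: RegionStats
    conservation_percentile: float
    density_percentile: float
    thresholds: dict

    def summary(self) -> dict:
        return {
            "n_noncoding_regions": len(self.distribution),
            "query": str(self.query_stats.interval),
            "query_mean_conservation": self.query_stats.mean_conservation,
            "query_motif_density_per_kb": self.query_stats.motif_density,
            "query_n_conserved_motifs": self.query_stats.n_conserved_motifs,
            "conservation_percentile": self.conservation_percentile,
            "density_percentile": self.density_percentile,
            "thresholds": dict(self.thresholds),
        }


def run_landscape(
    genome: GenomeSequence,
    annotation: AnnotationSet,
    track: ConservationTrack,
    pwms: Sequence[PWM] | PWM,
    query_interval: GenomicInterval,
    scan_config: ScanConfig | None = None,
    conservation_config: ConservationConfig | None = None,
    landscape_config: LandscapeConfig | None = None,
) -> LandscapeReport:
    """Extract non-coding regions, scan them, conservation-filter the hits,
    build the genome-wide distribution and percentile-rank the query.

    Every threshold actually applied is recorded in the report.
    """
    from .motifs import PWM as _PWM

    scan_config = scan_config or ScanConfig()
    conservation_config = conservation_config or ConservationConfig()
    landscape_config = landscape_config or LandscapeConfig()
    if isinstance(pwms, _PWM):
        pwms = [pwms]

    if query_interval.chrom not in genome.lengths:
        raise ValueError(f"query chromosome {query_interval.chrom!r} not in genome")
    regions = extract_noncoding(annotation, genome.lengths, landscape_config)

    def stats_for(iv: GenomicInterval) -> RegionStats:
        seq = genome.fetch(GenomicInterval(iv.chrom, iv.start, iv.end))
        hits: list[MotifHit] = []
        for pwm in pwms:
            hits.extend(scan_sequence(seq, pwm, scan_config, chrom=iv.chrom, offset=iv.start))
        kept = conserved_hits(hits, track, conservation_config)
        return region_stats(iv, track, kept, conservation_config, hits_are_conserved=True)

    dist = LandscapeDistribution([stats_for(iv) for iv in regions])
    query_stats = stats_for(query_interval)
    cons_pct = landscape_percentile(dist, query_stats, "mean_conservation")
    dens_pct = landscape_percentile(dist, query_stats, "motif_density")
    thresholds = {
        "relative_threshold": scan_config.relative_threshold,
        "both_strands": scan_config.both_strands,
        "pseudocount": scan_config.pseudocount,
        "background": list(scan_config.background),
        "site_conserved_threshold": conservation_config.site_conserved_threshold,
        "region_conserved_threshold": conservation_config.region_conserved_threshold,
        "missing_policy": conservation_config.missing_policy,
        "noncoding_definition": landscape_config.noncoding_definition,
        "min_region_length": landscape_config.min_region_length,
    }
    return LandscapeReport(dist, query_stats, cons_pct, dens_pct, thresholds)


def plot_landscape(report: LandscapeReport, path: str, bins: int = 40) -> None:
    """Histogram the two metrics with the query highlighted (analogue of a
    genome-browser style distribution figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, metric, label in zip(
        axes,
        ("mean_conservation", "motif_density"),
        ("mean conservation", "conserved motifs / kb"),
    ):
        vals = report.distribution.metrics(metric)
        ax.hist(vals, bins=bins, color="0.7")
        ax.axvline(report.query_stats.metric(metric), color="red", lw=2)
        ax.set_xlabel(label)
        ax.set_ylabel("non-coding regions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
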