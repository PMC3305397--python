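"""Binding-site cluster calling with the k-sites-in-w-bp window rule.

A cluster of transcription-factor binding sites is the classic signature of
a cis-regulatory module.  The rule implemented here: a motif hit is
*cluster-eligible* if some half-open window ``[x, x + w)`` contains the
start positions of at least ``k`` hits including it (defaults k=3, w=400,
with windows slid at single-base resolution).  Runs of eligible hits whose
consecutive starts are at most ``w`` apart are merged into one maximal,
disjoint cluster call.

Counting uses hit *start* positions, so the rule is insensitive to motif
length; plus- and minus-strand hits are pooled by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import GenomicInterval
from .motifs import MotifHit

__all__ = ["ClusterConfig", "SiteCluster", "call_clusters", "cluster_density"]


@dataclass(frozen=True)
class ClusterConfig:
    """k-in-w window rule parameters.

    min_sites : int
        Minimum number of hit starts a window must hold (k, default 3).
    window_bp : int
        Window width in bp (w, default 400).
    count_strands_jointly : bool
        Pool both strands before counting (default); if False the rule is
        applied per strand and the per-strand clusters are combined.
    min_sites_per_factor : mapping, optional
        For pooled multi-factor hit lists: minimum member count per motif id;
        clusters failing any per-factor minimum are dropped.
    """

    min_sites: int = 3
    window_bp: int = 400
    count_strands_jointly: bool = True
    min_sites_per_factor: Mapping[str, int] | None = None

    def __post_init__(self):
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")


@dataclass
class SiteCluster:
    """A maximal group of hits satisfying the window rule."""

    interval: GenomicInterval
    member_hits: list[MotifHit]

    @property
    def n_sites(self) -> int:
        return len(self.member_hits)

    @property
    def name(self) -> str:
        ids = sorted({h.motif_id for h in self.member_hits})
        return "+".join(ids) + f"_x{self.n_sites}"

    def bed_score(self) -> int:
        return self.n_sites

    def density_per_kb(self) -> float:
        return self.n_sites / self.interval.length() * 1000.0


def _eligible_indices(starts: Sequence[int], k: int, w: int) -> set[int]:
    """Indices (into the start-sorted list) that lie in some qualifying window.

    ``k`` sorted starts fit in a half-open width-``w`` window iff the span of
    any ``k`` consecutive starts is < ``w``; every start inside such a run is
    eligible.
    """
    n = len(starts)
    eligible: set[int] = set()
    for i in range(n - k + 1):
        if starts[i + k - 1] - starts[i] < w:
            eligible.update(range(i, i + k))
    return eligible


def _call_one_strata(hits: list[MotifHit], config: ClusterConfig) -> list[SiteCluster]:
    hits = sorted(hits, key=lambda h: (h.interval.start, h.interval.strand))
    starts = [h.interval.start for h in hits]
    eligible = sorted(_eligible_indices(starts, config.min_sites, config.window_bp))
    clusters: list[SiteCluster] = []
    group: list[MotifHit] = []
    prev_start: int | None = None
    for idx in eligible:
        h = hits[idx]
        if prev_start is not None and h.interval.start - prev_start > config.window_bp:
            clusters.append(_make_cluster(group))
            group = []
        group.append(h)
        prev_start = h.interval.start
    if group:
        clusters.append(_make_cluster(group))
    return clusters


def _make_cluster(members: list[MotifHit]) -> SiteCluster:
    chrom = members[0].interval.chrom
    start = min(h.interval.start for h in members)
    end = max(h.interval.end for h in members)
    return SiteCluster(GenomicInterval(chrom, start, end), members)


def call_clusters(hits: Sequence[MotifHit], config: ClusterConfig | None = None) -> list[SiteCluster]:
    """Detect maximal binding-site clusters on one chromosome.

    All hits must share a chromosome (iterate chromosomes in the caller).
    Clusters are disjoint, sorted by start, and each member hit's start lies
    in some width-``w`` window holding at least ``k`` member starts.
    """
    if config is None:
        config = ClusterConfig()
    hits = list(hits)
    if not hits:
        return []
    chroms = {h.interval.chrom for h in hits}
    if len(chroms) > 1:
        raise ValueError(f"hits span multiple chromosomes: {sorted(chroms)}")
    if config.count_strands_jointly:
        clusters = _call_one_strata(hits, config)
    else:
        clusters = []
        for strand in ("+", "-", "."):
            subset = [h for h in hits if h.interval.strand == strand]
            if subset:
                clusters.extend(_call_one_strata(subset, config))
        clusters.sort(key=lambda c: (c.interval.start, c.interval.end))
    if config.min_sites_per_factor:
        kept = []
        for c in clusters:
            counts: dict[str, int] = {}
            for h in c.member_hits:
                counts[h.motif_id] = counts.get(h.motif_id, 0) + 1
            if all(counts.get(f, 0) >= m for f, m in config.min_sites_per_factor.items()):
                kept.append(c)
        clusters = kept
    return clusters


def call_clusters_genome(hits: Sequence[MotifHit], config: ClusterConfig | None = None) -> list[SiteCluster]:
    """Cluster-call hits chromosome by chromosome."""
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    clusters: list[SiteCluster] = []
    for chrom in sorted(by_chrom):
        clusters.extend(call_clusters(by_chrom[chrom], config))
    return clusters


def cluster_density(cluster: SiteCluster) -> float:
    """Member sites per kb of cluster span."""
    return cluster.density_per_kb()
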