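"""Conservation summaries and conservation filtering of regions and hits.

Conservation enters the pipeline as a PhastCons-style per-base track.  Two
questions are asked of it: is a candidate *region* conserved (mean score
over all its bases at or above a cut-off), and is an individual *motif hit*
conserved (mean score over its footprint at or above a cut-off)?  Neither
cut-off has a canonical published value; 0.5 — the midpoint of the
PhastCons probability scale — is the default and both are explicit
parameters that every report records.

Missing track data (bases the track never covers, typically unalignable
sequence) defaults to a score of 0 (``as_zero``), since unalignable bases
are non-conserved for this purpose; ``exclude`` instead averages covered
bases only and treats a fully uncovered interval as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval
from .motifs import MotifHit
from .tracks import ConservationTrack

__all__ = [
    "ConservationConfig",
    "mean_conservation",
    "conserved_regions",
    "conserved_hits",
    "MissingDataError",
]


class MissingDataError(ValueError):
    """Interval has no covered bases under the ``exclude`` missing policy."""


@dataclass(frozen=True)
class ConservationConfig:
    region_conserved_threshold: float = 0.5
    site_conserved_threshold: float = 0.5
    missing_policy: str = "as_zero"

    def __post_init__(self):
        for name in ("region_conserved_threshold", "site_conserved_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.missing_policy not in ("as_zero", "exclude"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def mean_conservation(
    track: ConservationTrack,
    interval: GenomicInterval,
    missing_policy: str = "as_zero",
) -> float:
    """Arithmetic mean of per-base scores over the interval.

    ``as_zero`` counts uncovered bases as 0; ``exclude`` averages covered
    bases only and raises :class:`MissingDataError` if none are covered.
    """
    vals, cov = track.values_over(interval)
    if missing_policy == "as_zero":
        return float((vals * cov).sum() / interval.length())
    if missing_policy == "exclude":
        if not cov.any():
            raise MissingDataError(
                f"interval {interval} has no covered bases; mean undefined under 'exclude'"
            )
        return float(vals[cov].mean())
    raise ValueError(f"unknown missing_policy {missing_policy!r}")


def conserved_regions(
    track: ConservationTrack,
    candidate_intervals: Sequence[GenomicInterval],
    config: ConservationConfig | None = None,
) -> list[tuple[GenomicInterval, float]]:
    """Candidates whose mean conservation reaches the region threshold.

    Returns ``(interval, mean)`` pairs in input order.
    """
    if config is None:
        config = ConservationConfig()
    out = []
    for iv in candidate_intervals:
        mean = mean_conservation(track, iv, config.missing_policy)
        if mean >= config.region_conserved_threshold:
            out.append((iv, mean))
    return out


def conserved_hits(
    hits: Sequence[MotifHit],
    track: ConservationTrack,
    config: ConservationConfig | None = None,
) -> list[MotifHit]:
    """Hits whose footprint mean conservation reaches the site threshold.

    Each retained hit is returned annotated with its footprint mean in the
    ``conservation`` field; the result is a subset of the input and the
    operation is idempotent.
    """
    if config is None:
        config = ConservationConfig()
    out = []
    for hit in hits:
        footprint = replace_strand(hit.interval)
        mean = mean_conservation(track, footprint, config.missing_policy)
        if mean >= config.site_conserved_threshold:
            annotated = MotifHit(
                interval=hit.interval,
                raw_score=hit.raw_score,
                relative_score=hit.relative_score,
                matched_sequence=hit.matched_sequence,
                motif_id=hit.motif_id,
                conservation=mean,
            )
            out.append(annotated)
    return out


def replace_strand(interval: GenomicInterval) -> GenomicInterval:
    """Footprint of a hit on the forward axis (strand irrelevant for track lookup)."""
    if interval.strand == ".":
        return interval
    return GenomicInterval(interval.chrom, interval.start, interval.end, ".")
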