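"""Genomic interval model and coordinate-string parsing.

Internal coordinates are 0-based half-open throughout the package (BED
convention).  User-facing reports use the 1-based fully-closed display form
common in genome browsers and publications, e.g. ``3L:18384438..18385008``.
Both directions round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["GenomicInterval", "parse_onebased_interval", "format_onebased_interval"]

VALID_STRANDS = ("+", "-", ".")

# "<chrom>:<start>..<end>", 1-based inclusive; whitespace tolerated anywhere,
# including inside the chromosome token ("3 L" is a typographic artefact of
# print legends and normalises to "3L").
_COORD_RE = re.compile(
    r"^\s*(?P<chrom>[^:]+?)\s*:\s*(?P<start>\d+)\s*\.\.\s*(?P<end>\d+)\s*$"
)


class IntervalError(ValueError):
    """Raised for malformed or inconsistent genomic coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (exact string identity after whitespace stripping).
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must satisfy ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"negative start {self.start} in {self.chrom}")
        if self.end <= self.start:
            raise IntervalError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - delegation
        return self.length()

    def contains(self, pos: int) -> bool:
        """True if the 0-based position lies within the interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_onebased(self) -> str:
        """Display form, 1-based inclusive: ``chrom:start..end``."""
        return f"{self.chrom}:{self.start + 1}..{self.end}"

    def __str__(self) -> str:
        return self.to_onebased()


def parse_onebased_interval(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive coordinate string into a GenomicInterval.

    ``"3L:18384438..18385008"`` yields the half-open interval
    ``[18384437, 18385008)`` of length 571 bp.  Internal whitespace in the
    chromosome token is removed.

    Raises
    ------
    IntervalError
        If the text does not match ``chrom:start..end`` or start > end.
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise IntervalError(f"malformed coordinate string: {text!r}")
    chrom = re.sub(r"\s+", "", m.group("chrom"))
    start1, end1 = int(m.group("start")), int(m.group("end"))
    if start1 < 1:
        raise IntervalError(f"1-based start must be >= 1, got {start1} in {text!r}")
    if start1 > end1:
        raise IntervalError(f"start {start1} > end {end1} in {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_onebased_interval(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_onebased_interval` (strand not rendered)."""
    return interval.to_onebased()
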