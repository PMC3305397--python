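"""Per-base conservation tracks with explicit missing-data semantics.

Tracks hold PhastCons-style per-base scores (probability of conservation,
in [0, 1]) plus a coverage mask: positions never covered by the input file
are *missing*, and how missing bases enter region means is a policy decision
made downstream (see :mod:`crmscan.conservation`).

Two text encodings are supported: wiggle ``fixedStep`` (1-based starts) and
``bedGraph`` (0-based half-open).  Equivalent encodings of the same data
produce identical tracks.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping

import numpy as np

from .genome_io import FormatError
from .intervals import GenomicInterval

__all__ = ["ConservationTrack", "read_conservation_track", "write_bedgraph"]

logger = logging.getLogger(__name__)


class ConservationTrack:
    """Per-chromosome score arrays with a boolean coverage mask."""

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        covered: Mapping[str, np.ndarray],
        validate_range: bool = True,
    ):
        self._values: dict[str, np.ndarray] = {}
        self._covered: dict[str, np.ndarray] = {}
        for chrom in values:
            v = np.asarray(values[chrom], dtype=float)
            c = np.asarray(covered[chrom], dtype=bool)
            if v.shape != c.shape:
                raise ValueError(f"value/mask length mismatch on {chrom}")
            if validate_range and c.any():
                vc = v[c]
                if vc.min() < 0.0 or vc.max() > 1.0:
                    raise FormatError(
                        f"conservation values outside [0,1] on {chrom}"
                    )
            self._values[chrom] = v
            self._covered[chrom] = c

    @property
    def chromosomes(self) -> list[str]:
        return list(self._values)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._values

    def chrom_length(self, chrom: str) -> int:
        return len(self._values[chrom])

    def n_covered(self, chrom: str | None = None) -> int:
        """Total number of covered bases (optionally on one chromosome)."""
        if chrom is not None:
            return int(self._covered[chrom].sum())
        return sum(int(c.sum()) for c in self._covered.values())

    def values_over(self, interval: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """(scores, covered-mask) over an interval; positions beyond the
        stored array are treated as uncovered."""
        n = interval.length()
        vals = np.zeros(n)
        cov = np.zeros(n, dtype=bool)
        if interval.chrom in self._values:
            arr = self._values[interval.chrom]
            msk = self._covered[interval.chrom]
            hi = min(interval.end, len(arr))
            if hi > interval.start:
                span = hi - interval.start
                vals[:span] = arr[interval.start : hi]
                cov[:span] = msk[interval.start : hi]
        return vals, cov

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConservationTrack):
            return NotImplemented
        if set(self._values) != set(other._values):
            return False
        for chrom in self._values:
            a, b = self._values[chrom], other._values[chrom]
            ca, cb = self._covered[chrom], other._covered[chrom]
            n = max(len(a), len(b))

            def pad(x, fill=0.0):
                return np.pad(x, (0, n - len(x)), constant_values=fill)

            if not np.array_equal(pad(ca), pad(cb)):
                return False
            if not np.allclose(pad(a) * pad(ca), pad(b) * pad(cb)):
                return False
        return True

    @classmethod
    def constant(
        cls, chrom_lengths: Mapping[str, int], value: float
    ) -> "ConservationTrack":
        """Uniform track covering every base (useful for tests)."""
        values = {c: np.full(n, value) for c, n in chrom_lengths.items()}
        covered = {c: np.ones(n, dtype=bool) for c, n in chrom_lengths.items()}
        return cls(values, covered)


def _accumulate(
    chunks: Iterable[tuple[str, int, int, float]],
    on_out_of_range: str,
) -> ConservationTrack:
    """Build a track from (chrom, start, end, value) chunks, rejecting overlap."""
    values: dict[str, np.ndarray] = {}
    covered: dict[str, np.ndarray] = {}
    clamped = False
    for chrom, start, end, value in chunks:
        if not 0.0 <= value <= 1.0:
            if on_out_of_range == "error":
                raise FormatError(
                    f"value {value} outside [0,1] at {chrom}:{start}-{end}; "
                    "pass on_out_of_range='clamp' or 'allow' for non-PhastCons tracks"
                )
            if on_out_of_range == "clamp":
                value = min(1.0, max(0.0, value))
                clamped = True
        if chrom not in values:
            values[chrom] = np.zeros(end)
            covered[chrom] = np.zeros(end, dtype=bool)
        if end > len(values[chrom]):
            grow = end - len(values[chrom])
            values[chrom] = np.pad(values[chrom], (0, grow))
            covered[chrom] = np.pad(covered[chrom], (0, grow))
        if covered[chrom][start:end].any():
            raise FormatError(
                f"overlapping coverage at {chrom}:{start}-{end}"
            )
        values[chrom][start:end] = value
        covered[chrom][start:end] = True
    if clamped:
        logger.warning("out-of-range conservation values were clamped to [0,1]")
    return ConservationTrack(values, covered, validate_range=on_out_of_range != "allow")


def _iter_fixedstep(lines: Iterable[str]):
    chrom, pos, step, span = None, 0, 1, 1
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in line.split()[1:])
            try:
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle starts are 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"bad fixedStep declaration (line {lineno}): {line!r}") from exc
            if pos < 0 or step < 1 or span < 1:
                raise FormatError(f"bad fixedStep declaration (line {lineno}): {line!r}")
            continue
        if line.startswith("variableStep"):
            raise FormatError("variableStep wiggle is not supported; use bedGraph")
        if chrom is None:
            raise FormatError(f"data before fixedStep declaration (line {lineno})")
        try:
            value = float(line)
        except ValueError as exc:
            raise FormatError(f"bad wiggle value (line {lineno}): {line!r}") from exc
        yield chrom, pos, pos + span, value
        pos += step


def _iter_bedgraph(lines: Iterable[str]):
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"bedGraph line {lineno} has {len(parts)} fields")
        chrom, start, end, value = parts
        try:
            s, e, v = int(start), int(end), float(value)
        except ValueError as exc:
            raise FormatError(f"bad bedGraph line {lineno}: {line!r}") from exc
        if s < 0 or e <= s:
            raise FormatError(f"bad bedGraph interval on line {lineno}: {line!r}")
        yield chrom, s, e, v


def read_conservation_track(
    path: str | os.PathLike,
    format: str = "bedGraph",
    on_out_of_range: str = "error",
) -> ConservationTrack:
    """Read a per-base conservation track.

    Parameters
    ----------
    path : str
        Input file.
    format : {"bedGraph", "wiggle-fixedStep"}
        Text encoding of the track.
    on_out_of_range : {"error", "clamp", "allow"}
        Policy for values outside the PhastCons range [0, 1]: reject (default),
        clamp with a logged warning, or accept verbatim.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if format in ("bedGraph", "bedgraph"):
        chunks = _iter_bedgraph(lines)
    elif format in ("wiggle-fixedStep", "wiggle", "fixedStep", "wig"):
        chunks = _iter_fixedstep(lines)
    else:
        raise ValueError(f"unknown track format {format!r}")
    return _accumulate(chunks, on_out_of_range)


def write_bedgraph(track: ConservationTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph, merging runs of identical values."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            n = track.chrom_length(chrom)
            vals, cov = track.values_over(GenomicInterval(chrom, 0, n))
            i = 0
            while i < n:
                if not cov[i]:
                    i += 1
                    continue
                j = i + 1
                while j < n and cov[j] and vals[j] == vals[i]:
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{vals[i]:.6g}\n")
                i = j
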