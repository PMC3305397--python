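"""Readers and writers for FASTA genomes, GFF3 annotation and BED6 records.

FASTA parsing goes through Bio.SeqIO and GFF3 through gffutils; this module
adds the alphabet/consistency validation the pipeline relies on and maps
everything onto the shared :class:`~crmscan.intervals.GenomicInterval`
coordinate model (0-based half-open internally).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from .intervals import GenomicInterval

__all__ = [
    "GenomeSequence",
    "Feature",
    "AnnotationSet",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "read_bed",
    "FormatError",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Genome as a mapping of chromosome name to an A/C/G/T/N string."""

    def __init__(self, sequences: Mapping[str, str]):
        for name, seq in sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )
        self._seqs = dict(sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; minus-strand intervals are reverse-complemented."""
        if interval.chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} exceeds chromosome length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Records are keyed by the first whitespace-delimited header token;
    lowercase bases are upcased; characters outside A/C/G/T/N and duplicate
    record names are rejected, as is an empty file.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Feature:
    """One annotation feature (gene, mRNA, exon, ...)."""

    interval: GenomicInterval
    feature_type: str
    feature_id: str
    gene_id: str


class AnnotationSet:
    """Flat collection of annotation features with type-based access."""

    def __init__(self, features: Iterable[Feature]):
        self.features = sorted(
            features, key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end)
        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_type(self, feature_type: str) -> list[Feature]:
        ft = feature_type.lower()
        return [f for f in self.features if f.feature_type.lower() == ft]

    @property
    def chromosomes(self) -> set[str]:
        return {f.interval.chrom for f in self.features}


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Read GFF3 annotation into an :class:`AnnotationSet` (via gffutils)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features = []
    for f in db.all_features():
        gene_id = f.attributes.get("gene_id", f.attributes.get("Parent", [f.id]))[0]
        strand = f.strand if f.strand in ("+", "-") else "."
        features.append(
            Feature(
                interval=GenomicInterval(f.seqid, f.start - 1, f.end, strand),
                feature_type=f.featuretype,
                feature_id=f.id,
                gene_id=gene_id,
            )
        )
    return AnnotationSet(features)


def write_gff3(annotation: AnnotationSet, path: str | os.PathLike, source: str = "crmscan") -> None:
    """Write features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation:
            iv = f.interval
            attrs = f"ID={f.feature_id};gene_id={f.gene_id}"
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        source,
                        f.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _bed_fields(record) -> tuple[GenomicInterval, str, float]:
    """Extract (interval, name, score scaled to [0,1] or raw int) from a record.

    Accepts anything exposing ``interval``/``name``/``bed_score`` attributes or
    a plain ``(interval, name, score)`` tuple; scores are expected already on
    the 0-1000 integer BED scale via ``bed_score``.
    """
    if hasattr(record, "interval") and hasattr(record, "bed_score"):
        return record.interval, getattr(record, "name", "."), record.bed_score()
    interval, name, score = record
    return interval, name, score


def write_bed(records: Sequence, path: str | os.PathLike) -> None:
    """Write records as sorted BED6.

    Each record is ``(GenomicInterval, name, score)`` with score already on
    the integer 0-1000 scale, or an object with ``interval``, ``name`` and a
    ``bed_score()`` method.  Output is sorted by (chrom, start); an empty
    record list yields a file holding only the header comment.
    """
    rows = []
    for rec in records:
        iv, name, score = _bed_fields(rec)
        score_int = int(round(score))
        score_int = max(0, min(1000, score_int))
        rows.append((iv.chrom, iv.start, iv.end, name, score_int, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str, int]]:
    """Read BED6 back into ``(interval, name, score)`` tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"BED6 line with {len(parts)} fields: {line!r}")
            chrom, start, end, name, score, strand = parts[:6]
            out.append(
                (GenomicInterval(chrom, int(start), int(end), strand), name, int(score))
            )
    return out
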