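"""Position-frequency-matrix models and relative-score sequence scanning.

Scoring follows the standard log-odds scheme for transcription-factor
binding sites: a count matrix (PFM) is converted to a position weight matrix
(PWM) of log2 odds against a background base composition, and each
length-``L`` window ``w`` of sequence receives

    raw(w)      = sum_j W[j, w_j]                       (bits)
    relative(w) = (raw(w) - min) / (max - min)          (dimensionless, [0, 1])

where min/max are the matrix's best and worst attainable raw scores.  The
relative score makes cut-offs comparable across matrices; the conventional
threshold for calling a binding site is a relative score >= 0.90.

The PFM/PWM containers here are deliberately thin numpy wrappers; parsing of
JASPAR-format records is delegated to Bio.motifs with validation added.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .genome_io import FormatError, reverse_complement
from .intervals import GenomicInterval

__all__ = [
    "PFM",
    "PWM",
    "MotifHit",
    "ScanConfig",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "pfm_to_pwm",
    "relative_score",
    "scan_sequence",
    "diff_blocks",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: per-position nucleotide counts.

    ``counts`` has shape (L, 4) with columns ordered A, C, G, T.
    """

    counts: np.ndarray
    matrix_id: str = "motif"
    name: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise FormatError(
                f"PFM {self.matrix_id}: counts must be L x 4 with L >= 1, got {counts.shape}"
            )
        if (counts < 0).any():
            raise FormatError(f"PFM {self.matrix_id}: negative counts")
        if (counts.sum(axis=1) <= 0).any():
            raise FormatError(f"PFM {self.matrix_id}: all-zero column")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def consensus(self) -> str:
        """Per-column most frequent base (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def probabilities(self, pseudocount: float = 0.0,
                      background: Sequence[float] = UNIFORM_BACKGROUND) -> np.ndarray:
        bg = np.asarray(background, dtype=float)
        num = self.counts + pseudocount * bg
        return num / num.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PWM:
    """Log-odds scoring matrix (bits) derived from a PFM.

    Carries per-position extreme weights and the overall score bounds used
    for the relative-score normalisation.
    """

    weights: np.ndarray
    background: tuple[float, ...]
    pseudocount: float
    matrix_id: str = "motif"
    name: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)

    def _score_range(self) -> float:
        span = self.max_score - self.min_score
        if span <= 0:
            raise ValueError(
                f"PWM {self.matrix_id}: degenerate matrix (max == min score); "
                "relative scoring is undefined"
            )
        return span

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def column_min(self) -> np.ndarray:
        return self.weights.min(axis=1)

    @property
    def column_max(self) -> np.ndarray:
        return self.weights.max(axis=1)

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmin(axis=1))

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse complement: W'[j, b] = W[L-1-j, comp(b)]."""
        return replace(self, weights=self.weights[::-1, ::-1].copy())


@dataclass
class MotifHit:
    """A scored motif occurrence on one strand of a chromosome.

    ``interval`` is always on the forward axis; ``matched_sequence`` is the
    motif-oriented word (reverse-complemented for minus-strand hits).
    ``conservation`` is filled in by the conservation filter.
    """

    interval: GenomicInterval
    raw_score: float
    relative_score: float
    matched_sequence: str
    motif_id: str = "motif"
    conservation: float | None = None

    def __post_init__(self):
        if not -1e-9 <= self.relative_score <= 1 + 1e-9:
            raise ValueError(f"relative score {self.relative_score} outside [0,1]")
        self.relative_score = float(min(1.0, max(0.0, self.relative_score)))

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def name(self) -> str:
        return self.motif_id

    def bed_score(self) -> int:
        return int(round(self.relative_score * 1000))


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a scan: threshold, strands, background and pseudocount.

    ``relative_threshold`` is inclusive (a window scoring exactly the
    threshold is reported).  ``pseudocount`` is the total pseudo-observation
    mass per column, distributed across bases by the background frequencies.
    """

    relative_threshold: float = 0.90
    both_strands: bool = True
    pseudocount: float = 1.0
    background: tuple[float, ...] = UNIFORM_BACKGROUND

    def __post_init__(self):
        if not 0.0 < self.relative_threshold <= 1.0:
            raise ValueError("relative_threshold must be in (0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive frequencies summing to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


# ---------------------------------------------------------------------------
# JASPAR I/O

def read_jaspar_pfm(path_or_handle) -> list[PFM]:
    """Read JASPAR-format PFM records (``>ID name`` header, then four rows
    ``A [ n n ... ]`` etc.) into a list of :class:`PFM` in file order.

    Ragged rows, negative counts and missing base rows are rejected with an
    error naming the record.
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
        source = "<handle>"
    else:
        source = str(path_or_handle)
        with open(source) as fh:
            text = fh.read()
    _validate_jaspar_text(text, source)
    records = bio_motifs.parse(io.StringIO(text), "jaspar")
    pfms = []
    for rec in records:
        counts = np.column_stack([np.asarray(rec.counts[b], dtype=float) for b in BASES])
        pfms.append(PFM(counts, matrix_id=rec.matrix_id or rec.name or "motif",
                        name=rec.name or ""))
    if not pfms:
        raise FormatError(f"no JASPAR records found in {source}")
    return pfms


def _validate_jaspar_text(text: str, source: str) -> None:
    """Structural checks Bio.motifs is lenient about: ragged rows, negative
    counts, missing base rows."""
    current: str | None = None
    rows: dict[str, int] = {}

    def flush():
        if current is None:
            return
        if set(rows) != set(BASES):
            missing = sorted(set(BASES) - set(rows))
            raise FormatError(f"record {current!r} in {source}: missing rows {missing}")
        if len(set(rows.values())) != 1:
            raise FormatError(f"record {current!r} in {source}: ragged row lengths {rows}")

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            current = line[1:].split()[0] if line[1:].split() else "<unnamed>"
            rows = {}
            continue
        base = line[0].upper()
        if base in _BASE_INDEX and current is not None:
            body = line[1:].strip().strip("[]").replace("[", " ").replace("]", " ")
            try:
                vals = [float(tok) for tok in body.split()]
            except ValueError as exc:
                raise FormatError(f"record {current!r} in {source}: bad counts row {line!r}") from exc
            if any(v < 0 for v in vals):
                raise FormatError(f"record {current!r} in {source}: negative count")
            rows[base] = len(vals)
    flush()


def write_jaspar_pfm(pfms: Sequence[PFM], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.matrix_id} {pfm.name}".rstrip() + "\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in pfm.counts[:, i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Scoring

def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> PWM:
    """Convert counts to a log2-odds weight matrix.

    ``W[j, b] = log2( (n[j, b] + p * q_b) / (N_j + p) / q_b )`` where ``N_j``
    is the column total, ``q`` the background and ``p`` the total pseudocount
    per column (distributed by background).
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    totals = pfm.column_totals[:, None]
    if pseudocount == 0 and (pfm.counts == 0).any():
        raise ValueError(
            f"PFM {pfm.matrix_id} has zero counts; a positive pseudocount is required"
        )
    probs = (pfm.counts + pseudocount * bg) / (totals + pseudocount)
    weights = np.log2(probs / bg)
    return PWM(weights, tuple(bg), pseudocount, matrix_id=pfm.matrix_id, name=pfm.name)


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; N and anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def raw_score(pwm: PWM, word: str) -> float:
    codes = _encode(word)
    if len(codes) != len(pwm):
        raise ValueError(f"word length {len(codes)} != motif length {len(pwm)}")
    if (codes < 0).any():
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    return float(pwm.weights[np.arange(len(pwm)), codes].sum())


def relative_score(pwm: PWM, word: str) -> float:
    """Normalised match quality of ``word`` in [0, 1].

    1.0 is the consensus (best attainable) word, 0.0 the anti-consensus.
    Words containing N are rejected; scanning skips such windows instead.
    """
    raw = raw_score(pwm, word)
    rel = (raw - pwm.min_score) / pwm._score_range()
    return float(min(1.0, max(0.0, rel)))


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw scores for all length-L windows plus a validity mask (no N)."""
    L = weights.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for j in range(L):
        col = safe[j : j + n_win]
        scores += weights[j, col]
        valid &= codes[j : j + n_win] >= 0
    return scores, valid


def scan_sequence(
    seq: str,
    pwm: PWM,
    config: ScanConfig | None = None,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Report every window with relative score >= the threshold.

    Scans the forward strand and, when ``config.both_strands``, the reverse
    complement; minus-strand hits carry forward-axis intervals.  Windows
    containing N are skipped.  Output is sorted by (start, strand).
    """
    if config is None:
        config = ScanConfig()
    codes = _encode(seq.upper())
    L = len(pwm)
    denom = pwm._score_range()
    hits: list[MotifHit] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if config.both_strands else [])
    for strand, matrix in strands:
        scores, valid = _window_scores(codes, matrix.weights)
        rel = (scores - pwm.min_score) / denom
        keep = valid & (rel >= config.relative_threshold - 1e-12)
        for i in np.nonzero(keep)[0]:
            word = seq[i : i + L].upper()
            hits.append(
                MotifHit(
                    interval=GenomicInterval(chrom, offset + int(i), offset + int(i) + L, strand),
                    raw_score=float(scores[i]),
                    relative_score=float(min(1.0, max(0.0, rel[i]))),
                    matched_sequence=word if strand == "+" else reverse_complement(word),
                    motif_id=pwm.matrix_id,
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_genome(
    genome,
    pwms: Sequence[PWM] | PWM,
    config: ScanConfig | None = None,
) -> list[MotifHit]:
    """Scan every chromosome of a genome with one or more PWMs."""
    if isinstance(pwms, PWM):
        pwms = [pwms]
    hits: list[MotifHit] = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        for pwm in pwms:
            hits.extend(scan_sequence(seq, pwm, config, chrom=chrom, offset=0))
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Probe comparison

def diff_blocks(a: str, b: str) -> list[tuple[int, int]]:
    """Maximal runs of mismatching positions between two equal-length strings.

    Returns ``(start, length)`` pairs in ascending order; used to locate the
    substituted binding-site bases between wild-type and mutated EMSA probes.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    blocks: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            blocks.append((run_start, i - run_start))
            run_start = None
    if run_start is not None:
        blocks.append((run_start, len(a) - run_start))
    return blocks
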