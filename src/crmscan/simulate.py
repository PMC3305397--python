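"""Seeded simulator of small annotated genomes with planted ground truth.

The generator emulates the statistical structure the landscape analysis
assumes: a genome whose designated "enhancer" regions are (a) more
conserved than background and (b) enriched in strong binding-site
instances of a chosen motif, while the rest of the non-coding genome shows
background conservation and only sparse decoy sites.  Every run is fully
determined by one integer seed and records exact ground truth (planted
site positions/strands/words, enhancer intervals with their realised
conservation means, gene/exon geometry), so each pipeline stage can be
scored for recovery without any external data.

Model choices
-------------
* Background sequence is i.i.d. with a configurable GC content.
* Genes are regular exon/intron ladders; exons (like enhancers) receive
  elevated conservation so that the exon-complement extraction is exercised
  against a realistic mask.
* Per-base conservation is Beta-distributed i.i.d. within a region class
  (background vs elevated); the class Beta parameters set the region-mean
  separation.
* Planted sites are sampled per column from the motif's frequency model,
  accepted only if their relative score reaches ``planted_min_relative_score``
  (default 0.95) — near-consensus words, not always the consensus itself, so
  threshold behaviour near the 0.90 cut-off is exercised.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conservation import ConservationConfig
from .genome_io import (
    AnnotationSet,
    Feature,
    GenomeSequence,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .intervals import GenomicInterval
from .landscape import LandscapeDistribution, landscape_percentile, region_stats
from .motifs import PFM, MotifHit, pfm_to_pwm, relative_score
from .tracks import ConservationTrack, write_bedgraph

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "PlantedEnhancer",
    "SimulationTruth",
    "SimulatedGenome",
    "simulate_genome",
    "worked_example_config",
    "default_site_pfm",
    "truth_recovery_report",
    "RecoveryReport",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_site_pfm() -> PFM:
    """A sharp 8-bp AT-rich homeodomain-style matrix used for planting.

    The first five columns are near-degenerate (TTTAT core, the classic
    Abd-B/Hox preference); the 3' columns are softer so that near-consensus
    variants can still clear high relative-score cut-offs.
    """
    counts = np.array(
        [
            #  A    C    G    T
            [2, 2, 2, 94],
            [2, 2, 2, 94],
            [5, 5, 5, 85],
            [85, 5, 5, 5],
            [5, 5, 5, 85],
            [10, 10, 70, 10],
            [15, 10, 65, 10],
            [40, 20, 20, 20],
        ],
        dtype=float,
    )
    return PFM(counts, matrix_id="SYNTH_HOX8", name="synthetic-hox-like")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated genome (all per chromosome).

    Defaults mirror the worked-example geometry: 571 bp enhancers whose
    3 planted sites sit inside a 400 bp core, elevated conservation
    (Beta mean 0.8) against a 0.2-mean background.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    gc_content: float = 0.42
    n_genes: int = 6
    n_exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 400
    n_enhancers: int = 1
    enhancer_length: int = 571
    enhancer_core_bp: int = 400
    planted_sites_per_enhancer: int = 3
    planted_min_relative_score: float = 0.95
    background_site_rate: float = 0.05  # decoy sites per kb of intergenic gap
    enhancer_conservation: tuple[float, float] = (8.0, 2.0)  # Beta(a, b), mean 0.8
    background_conservation: tuple[float, float] = (2.0, 8.0)  # Beta(a, b), mean 0.2
    min_gap: int = 200
    enhancer_downstream_gap: int | None = None  # fixed gene-end -> enhancer distance

    def __post_init__(self):
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "exon_length",
            "intron_length",
            "enhancer_length",
            "enhancer_core_bp",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for a, b in (self.enhancer_conservation, self.background_conservation):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        if self.enhancer_downstream_gap is not None and self.n_enhancers > self.n_genes:
            raise ValueError(
                "enhancer_downstream_gap pairing requires n_enhancers <= n_genes"
            )

    @property
    def gene_span(self) -> int:
        return (
            self.n_exons_per_gene * self.exon_length
            + (self.n_exons_per_gene - 1) * self.intron_length
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def worked_example_config(seed: int = 0) -> SimulationConfig:
    """The fixed worked-example preset: one chromosome, a 571 bp enhancer
    with 3 planted sites in its 400 bp core, placed exactly 6 kb downstream
    of a gene, against a genome of ordinary genes and background sequence."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chromosome_length=60_000,
        n_genes=8,
        n_enhancers=1,
        enhancer_length=571,
        enhancer_core_bp=400,
        planted_sites_per_enhancer=3,
        enhancer_downstream_gap=6_000,
    )


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    start: int  # forward-axis start of the planted word
    strand: str
    sequence: str  # motif-oriented word
    relative_score: float
    region_label: str  # "enhancer:<id>" or "background"


@dataclass(frozen=True)
class PlantedEnhancer:
    interval: GenomicInterval
    enhancer_id: str
    true_conservation_mean: float


@dataclass
class SimulationTruth:
    """Ground truth of one simulated genome."""

    sites: list[PlantedSite]
    enhancers: list[PlantedEnhancer]

    def sites_in_enhancers(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.region_label.startswith("enhancer:")]

    @property
    def chromosomes(self) -> set[str]:
        return {s.chrom for s in self.sites} | {e.interval.chrom for e in self.enhancers}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "kind": "site",
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.start + len(s.sequence),
                    "strand": s.strand,
                    "name": s.region_label,
                    "value": s.relative_score,
                    "sequence": s.sequence,
                }
            )
        for e in self.enhancers:
            rows.append(
                {
                    "kind": "enhancer",
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "strand": ".",
                    "name": e.enhancer_id,
                    "value": e.true_conservation_mean,
                    "sequence": "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["kind", "chrom", "start", "end", "strand", "name", "value", "sequence"],
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
        sites, enhancers = [], []
        for _, r in df.iterrows():
            if r["kind"] == "site":
                sites.append(
                    PlantedSite(
                        r["chrom"], int(r["start"]), r["strand"], r["sequence"],
                        float(r["value"]), r["name"],
                    )
                )
            else:
                enhancers.append(
                    PlantedEnhancer(
                        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
                        r["name"], float(r["value"]),
                    )
                )
        return cls(sites, enhancers)


@dataclass
class SimulatedGenome:
    """In-memory bundle of one simulation: sequence, annotation, track, truth."""

    genome: GenomeSequence
    annotation: AnnotationSet
    track: ConservationTrack
    truth: SimulationTruth
    config: SimulationConfig
    pfm: PFM

    def validate(self) -> None:
        """Self-check: the four outputs are mutually consistent."""
        lengths = self.genome.lengths
        for f in self.annotation:
            iv = f.interval
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise AssertionError(f"feature {iv} outside genome bounds")
        for chrom, n in lengths.items():
            if chrom not in self.track or self.track.chrom_length(chrom) != n:
                raise AssertionError(f"track/genome length mismatch on {chrom}")
            if self.track.n_covered(chrom) != n:
                raise AssertionError(f"track does not cover {chrom} fully")
        pwm = pfm_to_pwm(self.pfm)
        for s in self.truth.sites:
            iv = GenomicInterval(s.chrom, s.start, s.start + len(s.sequence))
            word = self.genome.fetch(iv)
            expected = word if s.strand == "+" else reverse_complement(word)
            if expected != s.sequence:
                raise AssertionError(f"planted site sequence mismatch at {iv}")
            if relative_score(pwm, s.sequence) < self.config.planted_min_relative_score - 1e-9:
                raise AssertionError(f"planted site below minimum relative score at {iv}")
        for e in self.truth.enhancers:
            if e.interval.end > lengths[e.interval.chrom]:
                raise AssertionError(f"enhancer {e.interval} outside genome bounds")

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "bedgraph": outdir / "conservation.bedgraph",
            "truth": outdir / "truth.tsv",
            "motif": outdir / "motif.jaspar",
            "config": outdir / "simulation.yaml",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(self.annotation, paths["gff3"])
        write_bedgraph(self.track, paths["bedgraph"])
        self.truth.to_tsv(paths["truth"])
        from .motifs import write_jaspar_pfm

        write_jaspar_pfm([self.pfm], paths["motif"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        return paths


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_BYTES[rng.choice(4, size=n, p=p)]


def _sample_site_word(
    rng: np.random.Generator, pfm: PFM, pwm, min_rel: float, max_tries: int = 1000
) -> str:
    probs = pfm.probabilities(pseudocount=1.0)
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        word = "".join(bases[rng.choice(4, p=probs[j])] for j in range(len(pfm)))
        if relative_score(pwm, word) >= min_rel:
            return word
    return pwm.consensus()


def _place_elements(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[str, int, int]]:
    """Non-overlapping placement of genes/enhancers on one chromosome.

    Returns (kind, start, end) with kind in {"gene", "enhancer"}.  When
    ``enhancer_downstream_gap`` is set, each enhancer is welded to a gene as
    a composite block at exactly that distance downstream of the gene end.
    """
    g, e = config.gene_span, config.enhancer_length
    blocks: list[tuple[str, int]] = []
    if config.enhancer_downstream_gap is not None:
        gap = config.enhancer_downstream_gap
        for _ in range(config.n_enhancers):
            blocks.append(("gene+enh", g + gap + e))
        for _ in range(config.n_genes - config.n_enhancers):
            blocks.append(("gene", g))
    else:
        blocks += [("gene", g)] * config.n_genes
        blocks += [("enh", e)] * config.n_enhancers
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    total = sum(span for _, span in blocks)
    n_gaps = len(blocks) + 1
    slack = config.chromosome_length - total - n_gaps * config.min_gap
    if slack < 0:
        raise ValueError(
            f"infeasible placement: {total} bp of elements + minimum gaps exceed "
            f"chromosome length {config.chromosome_length}"
        )
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps)) if blocks else []
    placed: list[tuple[str, int, int]] = []
    pos = 0
    for (kind, span), pad in zip(blocks, extra):
        pos += config.min_gap + int(pad)
        if kind == "gene+enh":
            placed.append(("gene", pos, pos + g))
            enh_start = pos + g + config.enhancer_downstream_gap
            placed.append(("enhancer", enh_start, enh_start + e))
        elif kind == "gene":
            placed.append(("gene", pos, pos + g))
        else:
            placed.append(("enhancer", pos, pos + e))
        pos += span
    return placed


def simulate_genome(
    config: SimulationConfig, outdir: str | os.PathLike | None = None, pfm: PFM | None = None
) -> SimulatedGenome:
    """Generate a genome, annotation, conservation track and ground truth.

    Deterministic for a fixed config (seed included); when ``outdir`` is
    given, writes FASTA, GFF3, bedGraph, truth TSV, the planting motif and
    the serialized config there.
    """
    rng = np.random.default_rng(config.seed)
    pfm = pfm or default_site_pfm()
    pwm = pfm_to_pwm(pfm)
    L = len(pfm)

    seqs: dict[str, str] = {}
    features: list[Feature] = []
    sites: list[PlantedSite] = []
    enhancers: list[PlantedEnhancer] = []
    values: dict[str, np.ndarray] = {}
    covered: dict[str, np.ndarray] = {}

    a_bg, b_bg = config.background_conservation
    a_el, b_el = config.enhancer_conservation

    enh_counter = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, config.chromosome_length, config.gc_content)
        placed = _place_elements(rng, config)

        cons = rng.beta(a_bg, b_bg, size=config.chromosome_length)

        gene_counter = 0
        elevated: list[tuple[int, int]] = []
        for kind, start, end in placed:
            if kind == "gene":
                gene_counter += 1
                gid = f"{chrom}_g{gene_counter}"
                strand = "+" if rng.random() < 0.5 else "-"
                features.append(
                    Feature(GenomicInterval(chrom, start, end, strand), "gene", gid, gid)
                )
                for xi in range(config.n_exons_per_gene):
                    xs = start + xi * (config.exon_length + config.intron_length)
                    xe = xs + config.exon_length
                    features.append(
                        Feature(
                            GenomicInterval(chrom, xs, xe, strand),
                            "exon",
                            f"{gid}_e{xi + 1}",
                            gid,
                        )
                    )
                    elevated.append((xs, xe))
            else:
                enh_counter += 1
                eid = f"enh{enh_counter}"
                elevated.append((start, end))
                core_len = min(config.enhancer_core_bp, end - start)
                core_start = start + (end - start - core_len) // 2
                taken: list[tuple[int, int]] = []
                for _ in range(config.planted_sites_per_enhancer):
                    for _try in range(1000):
                        s0 = core_start + int(rng.integers(0, core_len - L + 1))
                        if all(s0 + L <= ts or s0 >= te for ts, te in taken):
                            break
                    else:
                        raise ValueError(
                            f"cannot place {config.planted_sites_per_enhancer} "
                            f"non-overlapping sites in a {core_len} bp core"
                        )
                    taken.append((s0, s0 + L))
                    strand = "+" if rng.random() < 0.5 else "-"
                    word = _sample_site_word(
                        rng, pfm, pwm, config.planted_min_relative_score
                    )
                    insert = word if strand == "+" else reverse_complement(word)
                    seq[s0 : s0 + L] = np.frombuffer(insert.encode(), dtype=np.uint8)
                    sites.append(
                        PlantedSite(
                            chrom, s0, strand, word,
                            relative_score(pwm, word), f"enhancer:{eid}",
                        )
                    )
                enh_vals = rng.beta(a_el, b_el, size=end - start)
                cons[start:end] = enh_vals
                enhancers.append(
                    PlantedEnhancer(
                        GenomicInterval(chrom, start, end), eid, float(enh_vals.mean())
                    )
                )

        # exon conservation drawn after the enhancer loop so exons stay elevated
        for f in features:
            if f.feature_type == "exon" and f.interval.chrom == chrom:
                xs, xe = f.interval.start, f.interval.end
                cons[xs:xe] = rng.beta(a_el, b_el, size=xe - xs)

        # decoy sites in intergenic gaps (background conservation, true word)
        if config.background_site_rate > 0:
            occupied = sorted((s, e) for _, s, e in placed)
            gaps = []
            pos = 0
            for s, e in occupied:
                if s - pos >= L:
                    gaps.append((pos, s))
                pos = max(pos, e)
            if config.chromosome_length - pos >= L:
                gaps.append((pos, config.chromosome_length))
            for gs, ge in gaps:
                lam = config.background_site_rate * (ge - gs) / 1000.0
                n_decoys = int(rng.poisson(lam))
                decoy_taken: list[tuple[int, int]] = []
                for _ in range(n_decoys):
                    for _try in range(100):
                        s0 = gs + int(rng.integers(0, ge - gs - L + 1))
                        if all(s0 + L <= ts or s0 >= te for ts, te in decoy_taken):
                            break
                    else:
                        continue
                    decoy_taken.append((s0, s0 + L))
                    strand = "+" if rng.random() < 0.5 else "-"
                    word = _sample_site_word(
                        rng, pfm, pwm, config.planted_min_relative_score
                    )
                    insert = word if strand == "+" else reverse_complement(word)
                    seq[s0 : s0 + L] = np.frombuffer(insert.encode(), dtype=np.uint8)
                    sites.append(
                        PlantedSite(
                            chrom, s0, strand, word,
                            relative_score(pwm, word), "background",
                        )
                    )

        seqs[chrom] = seq.tobytes().decode("ascii")
        values[chrom] = cons
        covered[chrom] = np.ones(config.chromosome_length, dtype=bool)

    sim = SimulatedGenome(
        genome=GenomeSequence(seqs),
        annotation=AnnotationSet(features),
        track=ConservationTrack(values, covered),
        truth=SimulationTruth(sorted(sites, key=lambda s: (s.chrom, s.start)), enhancers),
        config=config,
        pfm=pfm,
    )
    sim.validate()
    if outdir is not None:
        sim.write(outdir)
    return sim


# ---------------------------------------------------------------------------
# Truth recovery

@dataclass
class RecoveryReport:
    """Site-level precision/recall plus enhancer percentile ranks."""

    n_true_sites: int
    n_predicted: int
    n_matched: int
    recall: float
    precision: float | None  # None ("not applicable") when nothing predicted
    enhancer_percentiles: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": "site_recall",
                "value": self.recall,
            },
            {
                "metric": "site_precision",
                "value": float("nan") if self.precision is None else self.precision,
            },
        ]
        for eid, pcts in self.enhancer_percentiles.items():
            for m, v in pcts.items():
                rows.append({"metric": f"{eid}:{m}_percentile", "value": v})
        return pd.DataFrame(rows)


def truth_recovery_report(
    truth: SimulationTruth,
    hits: list[MotifHit],
    *,
    match_strand: bool = True,
    distribution: LandscapeDistribution | None = None,
    track: ConservationTrack | None = None,
    conservation_config: ConservationConfig | None = None,
    conserved_hit_pool: list[MotifHit] | None = None,
    chromosomes: set[str] | None = None,
) -> RecoveryReport:
    """Score pipeline hits against planted truth.

    A planted site is recovered if a hit starts at exactly its forward-axis
    start (and on the same strand unless ``match_strand=False``).  When a
    landscape ``distribution`` and ``track`` are supplied, each planted
    enhancer is percentile-ranked for both landscape metrics using
    ``conserved_hit_pool`` (or ``hits``) for its motif count.
    """
    truth_chroms = truth.chromosomes
    hit_chroms = {h.interval.chrom for h in hits}
    if chromosomes is None:
        chromosomes = truth_chroms
    if chromosomes and not hit_chroms <= set(chromosomes):
        raise ValueError(
            f"hit chromosomes {sorted(hit_chroms - set(chromosomes))} absent from truth"
        )

    def key(chrom: str, start: int, strand: str):
        return (chrom, start, strand) if match_strand else (chrom, start)

    true_keys = {key(s.chrom, s.start, s.strand) for s in truth.sites}
    pred_keys = {key(h.interval.chrom, h.interval.start, h.interval.strand) for h in hits}
    matched = true_keys & pred_keys
    n_true, n_pred = len(true_keys), len(pred_keys)
    recall = len(matched) / n_true if n_true else 1.0
    precision = len(matched) / n_pred if n_pred else None

    enhancer_percentiles: dict[str, dict[str, float]] = {}
    if distribution is not None and track is not None:
        cc = conservation_config or ConservationConfig()
        pool = conserved_hit_pool if conserved_hit_pool is not None else hits
        for enh in truth.enhancers:
            stats = region_stats(enh.interval, track, pool, cc, hits_are_conserved=conserved_hit_pool is not None)
            enhancer_percentiles[enh.enhancer_id] = {
                "mean_conservation": landscape_percentile(distribution, stats, "mean_conservation"),
                "motif_density": landscape_percentile(distribution, stats, "motif_density"),
            }
    return RecoveryReport(
        n_true_sites=n_true,
        n_predicted=n_pred,
        n_matched=len(matched),
        recall=recall,
        precision=precision,
        enhancer_percentiles=enhancer_percentiles,
    )
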