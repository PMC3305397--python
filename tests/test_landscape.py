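"""Non-coding region extraction, per-region stats and percentile ranking."""

import numpy as np
import pytest

from crmscan import (
    AnnotationSet,
    ConservationConfig,
    ConservationTrack,
    Feature,
    GenomicInterval,
    LandscapeConfig,
    LandscapeDistribution,
    MotifHit,
    RegionStats,
    extract_noncoding,
    landscape_percentile,
    region_stats,
    run_landscape,
)


def ann(features):
    return AnnotationSet(
        [Feature(iv, t, f"f{i}", f"g{i}") for i, (iv, t) in enumerate(features)]
    )


def hit_at(start, L=8, chrom="c"):
    return MotifHit(
        GenomicInterval(chrom, start, start + L, "+"),
        raw_score=0.0, relative_score=0.95, matched_sequence="A" * L, motif_id="m",
    )


class TestExtractNoncoding:
    def test_single_exon_complement(self):
        a = ann([(GenomicInterval("c", 100, 200), "exon")])
        got = extract_noncoding(a, {"c": 1000}, LandscapeConfig(min_region_length=1))
        assert got == [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 1000)]

    def test_empty_annotation_gives_whole_chromosomes(self):
        got = extract_noncoding(ann([]), {"a": 500, "b": 300}, LandscapeConfig(min_region_length=1))
        assert got == [GenomicInterval("a", 0, 500), GenomicInterval("b", 0, 300)]

    def test_unknown_chromosome_named_in_error(self):
        a = ann([(GenomicInterval("weird", 0, 10), "exon")])
        with pytest.raises(ValueError, match="weird"):
            extract_noncoding(a, {"c": 100})

    def test_gene_complement_masks_introns_too(self):
        feats = [
            (GenomicInterval("c", 100, 500), "gene"),
            (GenomicInterval("c", 100, 200), "exon"),
            (GenomicInterval("c", 400, 500), "exon"),
        ]
        exonc = extract_noncoding(ann(feats), {"c": 1000}, LandscapeConfig(min_region_length=1))
        genec = extract_noncoding(
            ann(feats), {"c": 1000},
            LandscapeConfig(noncoding_definition="gene_complement", min_region_length=1),
        )
        assert GenomicInterval("c", 200, 400) in exonc  # intron kept
        assert genec == [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 1000)]

    def test_overlapping_isoform_exons_match_per_base_mask_oracle(self):
        rng = np.random.default_rng(14)
        n = 5000
        feats = []
        mask = np.zeros(n, bool)
        for _ in range(30):
            s = int(rng.integers(0, n - 100))
            e = s + int(rng.integers(20, 100))
            feats.append((GenomicInterval("c", s, e), "exon"))
            mask[s:e] = True
        got = extract_noncoding(ann(feats), {"c": n}, LandscapeConfig(min_region_length=1))
        runs = []
        i = 0
        while i < n:
            if not mask[i]:
                j = i
                while j < n and not mask[j]:
                    j += 1
                runs.append(GenomicInterval("c", i, j))
                i = j
            else:
                i += 1
        assert got == runs
        # partition property: masked + extracted cover the chromosome exactly
        total = sum(iv.length() for iv in got) + int(mask.sum())
        assert total == n

    def test_min_length_filter(self):
        feats = [(GenomicInterval("c", 10, 990), "exon")]
        assert extract_noncoding(ann(feats), {"c": 1000}) == []  # flanks are 10 bp


class TestRegionStats:
    def test_571bp_region_density_arithmetic(self):
        region = GenomicInterval("c", 0, 571)
        track = ConservationTrack.constant({"c": 571}, 0.8)
        hits = [hit_at(s) for s in (10, 100, 300, 500)]
        rs = region_stats(region, track, hits, ConservationConfig())
        assert rs.n_conserved_motifs == 4
        assert rs.motif_density == pytest.approx(4 / 571 * 1000)

    def test_region_without_hits(self):
        region = GenomicInterval("c", 0, 200)
        track = ConservationTrack.constant({"c": 200}, 0.4)
        rs = region_stats(region, track, [], ConservationConfig())
        assert rs.n_conserved_motifs == 0 and rs.motif_density == 0.0

    def test_start_assignment_matches_recount_oracle(self):
        rng = np.random.default_rng(19)
        track = ConservationTrack({"c": rng.random(4000)}, {"c": np.ones(4000, bool)})
        hits = [hit_at(int(s)) for s in rng.integers(0, 3990, size=150)]
        cfg = ConservationConfig(site_conserved_threshold=0.4)
        from crmscan import conserved_hits, mean_conservation

        kept = conserved_hits(hits, track, cfg)
        for s, e in [(0, 1000), (1000, 2500), (2500, 4000)]:
            region = GenomicInterval("c", s, e)
            rs = region_stats(region, track, kept, cfg, hits_are_conserved=True)
            assert rs.n_conserved_motifs == sum(1 for h in kept if s <= h.interval.start < e)
            assert rs.mean_conservation == pytest.approx(mean_conservation(track, region))


class TestPercentile:
    def _dist(self, metrics):
        regions = [
            RegionStats(GenomicInterval("c", i * 100, i * 100 + 50), m, 0)
            for i, m in enumerate(metrics)
        ]
        return LandscapeDistribution(regions)

    def test_strict_dominance_is_100(self):
        dist = self._dist([0.1, 0.2, 0.3])
        q = RegionStats(GenomicInterval("q", 0, 50), 0.9, 0)
        assert landscape_percentile(dist, q, "mean_conservation") == 100.0

    def test_minimum_is_0(self):
        dist = self._dist([0.1, 0.2, 0.3])
        q = RegionStats(GenomicInterval("q", 0, 50), 0.1, 0)
        assert landscape_percentile(dist, q, "mean_conservation") == 0.0

    def test_member_query_excluded_from_denominator(self):
        dist = self._dist([0.1, 0.2, 0.3, 0.4])
        member = dist.regions[2]  # 0.3: two of the other three are below
        pct = landscape_percentile(dist, member, "mean_conservation")
        assert pct == pytest.approx(100 * 2 / 3)

    def test_empty_distribution_rejected(self):
        q = RegionStats(GenomicInterval("q", 0, 50), 0.5, 0)
        with pytest.raises(ValueError):
            landscape_percentile(LandscapeDistribution([]), q, "mean_conservation")

    def test_matches_brute_force_strict_less_count(self):
        rng = np.random.default_rng(25)
        metrics = rng.random(1000)
        dist = self._dist(metrics.tolist())
        for _ in range(100):
            qv = float(rng.random())
            q = RegionStats(GenomicInterval("q", 0, 50), qv, 0)
            expected = 100.0 * float((metrics < qv).sum()) / 1000
            assert landscape_percentile(dist, q, "mean_conservation") == pytest.approx(expected)

    def test_adding_lower_region_never_decreases_percentile(self):
        dist = self._dist([0.2, 0.4, 0.6])
        q = RegionStats(GenomicInterval("q", 0, 50), 0.5, 0)
        before = landscape_percentile(dist, q, "mean_conservation")
        bigger = self._dist([0.2, 0.4, 0.6, 0.1])
        after = landscape_percentile(bigger, q, "mean_conservation")
        assert after >= before


class TestRunLandscape:
    def test_composition_on_constructed_genome(self):
        """A query built to dominate reports 100% on conservation; with no
        plantable motif anywhere, every density is 0 and the density
        percentile is 0%."""
        from crmscan import GenomeSequence, default_site_pfm, pfm_to_pwm

        rng = np.random.default_rng(31)
        n = 6000
        seq = "".join(rng.choice(list("AC"), size=n))  # consensus TTTATGGA cannot occur
        genome = GenomeSequence({"c": seq})
        feats = ann(
            [(GenomicInterval("c", s, s + 200), "exon") for s in range(500, 5500, 1000)]
        )
        vals = np.full(n, 0.2)
        vals[2000:2500] = 0.95  # the dominating query block
        track = ConservationTrack({"c": vals}, {"c": np.ones(n, bool)})
        pwm = pfm_to_pwm(default_site_pfm())
        query = GenomicInterval("c", 2000, 2500)
        report = run_landscape(genome, feats, track, pwm, query)
        assert report.conservation_percentile == 100.0
        assert report.density_percentile == 0.0
        assert all(r.motif_density == 0 for r in report.distribution.regions)
        # every applied threshold is recorded
        for key in ("relative_threshold", "site_conserved_threshold",
                    "region_conserved_threshold", "noncoding_definition",
                    "min_region_length", "missing_policy"):
            assert key in report.thresholds

    def test_unknown_query_chromosome_rejected(self):
        from crmscan import GenomeSequence, default_site_pfm, pfm_to_pwm

        genome = GenomeSequence({"c": "ACGT" * 100})
        track = ConservationTrack.constant({"c": 400}, 0.5)
        pwm = pfm_to_pwm(default_site_pfm())
        with pytest.raises(ValueError, match="nope"):
            run_landscape(genome, ann([]), track, pwm, GenomicInterval("nope", 0, 10))
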