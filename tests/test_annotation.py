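"""TSS association, location classification, homology Venn, metaprofiles."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from chipconcord import (
    GeneModel,
    Interval,
    OrthologPair,
    Peak,
    Tag,
    associate_peaks_tss,
    bound_genes,
    classify_locations,
    homology_venn,
    tss_count_distribution,
    tss_metaprofile,
    window_around,
)


def mkpeak(chrom, start, end):
    return Peak(Interval(chrom, start, end), 0.0, 0.0)


def mkgene(gid, chrom, strand, start, end):
    return GeneModel(gid, Interval(chrom, start, end), strand)


class TestAssociatePeaksTss:
    def test_window_edge_cases(self):
        gene = mkgene("g1", "chr1", "+", 2000, 6000)  # TSS 2000, window [750, 3251)
        inside = mkpeak("chr1", 3000, 3500)
        outside = mkpeak("chr1", 3300, 3500)
        gene_map, peak_map = associate_peaks_tss([inside, outside], [gene], 1250)
        assert gene_map == {"g1": [inside]}
        assert peak_map == [["g1"], []]

    def test_many_to_many(self):
        g1 = mkgene("g1", "chr1", "+", 2000, 4000)
        g2 = mkgene("g2", "chr1", "-", 500, 2500)  # TSS 2499
        peak = mkpeak("chr1", 2100, 2200)
        gene_map, peak_map = associate_peaks_tss([peak], [g1, g2], 1250)
        assert peak_map == [["g1", "g2"]]
        assert set(gene_map) == {"g1", "g2"}

    def test_matches_brute_force(self, rng):
        genes = [
            mkgene(
                f"g{i}",
                "chr1",
                "+" if rng.random() < 0.5 else "-",
                s := int(rng.integers(2000, 80_000)),
                s + int(rng.integers(1000, 5000)),
            )
            for i in range(100)
        ]
        peaks = [
            mkpeak("chr1", s := int(rng.integers(0, 85_000)), s + int(rng.integers(50, 600)))
            for _ in range(100)
        ]
        _, peak_map = associate_peaks_tss(peaks, genes, 1250)
        for p, hits in zip(peaks, peak_map):
            expected = sorted(
                g.gene_id
                for g in genes
                if p.interval.overlaps(window_around("chr1", g.tss, 1250))
            )
            assert hits == expected


class TestClassifyLocations:
    def test_priority_tss_over_intragenic(self):
        gene = mkgene("g1", "chr1", "+", 2000, 9000)
        in_window_and_body = mkpeak("chr1", 2500, 2700)
        categories, breakdown = classify_locations([in_window_and_body], [gene], 1250)
        assert categories == ["tss_proximal"]
        assert breakdown.n_tss_proximal == 1

    def test_mid_gene_is_intragenic(self):
        gene = mkgene("g1", "chr1", "+", 2000, 9000)
        mid = mkpeak("chr1", 6000, 6300)
        categories, _ = classify_locations([mid], [gene], 1250)
        assert categories == ["intragenic"]

    def test_exhaustive_and_conserved(self, rng):
        genes = [mkgene(f"g{i}", "chr1", "+", 2000 + 10_000 * i, 8000 + 10_000 * i) for i in range(5)]
        peaks = [
            mkpeak("chr1", s := int(rng.integers(0, 60_000)), s + 200) for _ in range(200)
        ]
        categories, breakdown = classify_locations(peaks, genes, 1250)
        assert breakdown.total == len(peaks)
        assert sum(breakdown.fractions) == pytest.approx(1.0, abs=1e-12)
        for p, cat in zip(peaks, categories):
            near_tss = any(
                p.interval.overlaps(window_around("chr1", g.tss, 1250)) for g in genes
            )
            in_body = any(p.interval.overlaps(g.interval) for g in genes)
            expected = "tss_proximal" if near_tss else "intragenic" if in_body else "intergenic"
            assert cat == expected

    def test_planted_tss_fraction_recovered(self, default_sims):
        """Truth-planted peaks classify ~frac_tss_peaks TSS-proximal."""
        fractions = []
        for sim in default_sims[:3]:
            peaks = [
                mkpeak(r.chrom, r.start, r.end) for r in sim.truth.peaks.itertuples()
            ]
            _, breakdown = classify_locations(peaks, sim.genes, 1250)
            fractions.append(breakdown.fractions[0])
        n = len(sim.truth.peaks)
        sd = np.sqrt(0.8 * 0.2 / n)
        assert all(abs(f - 0.8) <= 3 * sd + 1 / n for f in fractions)


class TestBoundGenes:
    def test_set_semantics(self):
        gene = mkgene("g1", "chr1", "+", 2000, 9000)
        peaks = [mkpeak("chr1", 1800, 1900), mkpeak("chr1", 2100, 2300)]
        assert bound_genes(peaks, [gene], 1250) == {"g1"}

    def test_monotone_in_half_window(self, rng):
        genes = [mkgene(f"g{i}", "chr1", "+", 5000 + 30_000 * i, 12_000 + 30_000 * i) for i in range(8)]
        peaks = [
            mkpeak("chr1", s := int(rng.integers(0, 250_000)), s + 300) for _ in range(60)
        ]
        narrow = bound_genes(peaks, genes, 1250)
        wide = bound_genes(peaks, genes, 10_000)
        assert narrow <= wide
        expected = {
            g.gene_id
            for g in genes
            if any(p.interval.overlaps(window_around("chr1", g.tss, 1250)) for p in peaks)
        }
        assert narrow == expected


class TestHomologyVenn:
    def test_basic_cells(self):
        pairs = [OrthologPair("a1", "b1")]
        hv = homology_venn({"a1"}, {"b1"}, pairs)
        assert (hv.n_both, hv.n_a_only, hv.n_b_only) == (1, 0, 0)
        hv = homology_venn({"a2"}, set(), pairs)
        assert hv.n_a_specific == 1

    def test_removing_pairs_moves_everything_to_specific(self):
        bound_a, bound_b = {"a1", "a2"}, {"b1"}
        hv = homology_venn(bound_a, bound_b, [])
        assert (hv.n_both, hv.n_a_only, hv.n_b_only) == (0, 0, 0)
        assert (hv.n_a_specific, hv.n_b_specific) == (2, 1)

    def test_random_tally_matches_brute_force(self, rng):
        pairs = [OrthologPair(f"a{i}", f"b{i}") for i in range(100)]
        bound_a = {f"a{i}" for i in rng.choice(100, 40, replace=False)} | {"extraA"}
        bound_b = {f"b{i}" for i in rng.choice(100, 30, replace=False)} | {"extraB"}
        hv = homology_venn(bound_a, bound_b, pairs)
        both = sum(1 for p in pairs if p.gene_a in bound_a and p.gene_b in bound_b)
        a_only = sum(1 for p in pairs if p.gene_a in bound_a and p.gene_b not in bound_b)
        assert (hv.n_both, hv.n_a_only) == (both, a_only)
        assert hv.n_both + hv.n_a_only <= len(bound_a & {p.gene_a for p in pairs})
        assert (hv.n_a_specific, hv.n_b_specific) == (1, 1)


class TestTssMetaprofile:
    def test_zero_tags_zero_profile(self):
        genes = [mkgene("g1", "chr1", "+", 50_000, 60_000)]
        profile = tss_metaprofile([], genes, library_size=1_000_000)
        assert all(v == 0.0 for v in profile.values)
        assert len(profile.values) == 200

    def test_duplication_invariance_is_exact(self, rng):
        genes = [mkgene(f"g{i}", "chr1", "+" if i % 2 else "-", 20_000 * (i + 1), 20_000 * (i + 1) + 5000) for i in range(4)]
        tags = [
            Tag("chr1", int(rng.integers(10_000, 120_000)), "+" if rng.random() < 0.5 else "-")
            for _ in range(2000)
        ]
        base = tss_metaprofile(tags, genes, library_size=len(tags))
        doubled = tss_metaprofile(tags + tags, genes, library_size=2 * len(tags))
        assert doubled.values == base.values  # bit-for-bit

    def test_hand_pileup_plus_strand(self):
        gene = mkgene("g1", "chr1", "+", 50_000, 60_000)
        tag = Tag("chr1", 50_000, "+")  # elongated footprint covers offsets [0, 200)
        profile = tss_metaprofile([tag], [gene], library_size=20_000_000)
        values = np.array(profile.values)
        offsets = np.array(profile.bin_offsets)
        covered = (offsets >= 0) & (offsets < 200)
        assert np.allclose(values[covered], 1.0)
        assert np.allclose(values[~covered], 0.0)

    def test_minus_strand_orientation_flipped(self):
        gene = mkgene("g1", "chr1", "-", 40_000, 50_000)  # TSS 49_999
        tag = Tag("chr1", 49_999, "-")  # downstream of the - TSS in gene orientation
        profile = tss_metaprofile([tag], [gene], library_size=20_000_000)
        values = np.array(profile.values)
        offsets = np.array(profile.bin_offsets)
        covered = (offsets >= 0) & (offsets < 200)
        assert np.allclose(values[covered], 1.0)
        assert np.allclose(values[~covered], 0.0)


class TestTssCountDistribution:
    def test_single_tss(self):
        gene = mkgene("g1", "chr1", "+", 5000, 9000)
        tags = [Tag("chr1", 5000 + i, "+") for i in range(5)]
        dist = tss_count_distribution(tags, {"only": ["g1"]}, [gene])
        df = dist["only"]
        assert df.tag_count.tolist() == [5]
        assert df.cumulative_fraction.tolist() == [1.0]

    def test_counts_match_brute_force(self, rng):
        genes = [mkgene(f"g{i}", "chr1", "+", 5000 * (i + 1), 5000 * (i + 1) + 2000) for i in range(10)]
        tags = [Tag("chr1", int(rng.integers(0, 60_000)), "+") for _ in range(800)]
        dist = tss_count_distribution(tags, {"all": [g.gene_id for g in genes]}, genes)
        expected = sorted(
            sum(
                1
                for t in tags
                if window_around("chr1", g.tss, 1250).contains(t.five_prime)
            )
            for g in genes
        )
        assert dist["all"].tag_count.tolist() == expected

    def test_bound_tss_dominate_in_synthetic_data(self, default_sims, filtered_sims):
        """TSSs carrying planted peaks show higher tag counts than all TSSs."""
        sim, filtered, _ = filtered_sims[0]
        bound = [r.gene_id for r in sim.truth.genes.itertuples() if r.bound_1250]
        dist = tss_count_distribution(
            filtered["endogenous"],
            {"all": [g.gene_id for g in sim.genes], "bound": bound},
            sim.genes,
        )
        stat = mannwhitneyu(
            dist["bound"].tag_count, dist["all"].tag_count, alternative="greater"
        )
        assert stat.pvalue < 0.01
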