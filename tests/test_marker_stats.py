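"""Diversity statistics: binary/codominant PIC, EMR/MI, Ho, dosage trends."""

import itertools

import numpy as np
import pytest

from musadiv.distance_clustering import to_binary
from musadiv.marker_stats import (
    dosage_frequency_trend,
    locus_summaries,
    marker_index,
    observed_heterozygosity,
    pic_binary,
    pic_codominant,
    summarize_allele_counts,
)
from musadiv.pipeline_io import GenotypeTable
from musadiv.synthetic_data import generate_dosage_population


class TestPicBinary:
    @pytest.mark.parametrize("f,expected", [(0.5, 0.5), (0.0, 0.0), (0.2, 0.32), (1.0, 0.0)])
    def test_values(self, f, expected):
        assert pic_binary(f) == pytest.approx(expected)

    def test_symmetric_and_maximized_at_half(self):
        grid = np.linspace(0, 1, 10_001)
        values = np.array([pic_binary(float(f)) for f in grid])
        assert values.max() == pytest.approx(0.5)
        assert grid[values.argmax()] == pytest.approx(0.5)
        assert pic_binary(0.3) == pytest.approx(pic_binary(0.7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pic_binary(1.2)


class TestMarkerIndex:
    @pytest.mark.parametrize(
        "pic,nb,npoly,emr,mi",
        [(0.2, 10, 10, 10, 2.0), (0.3, 12, 6, 6, 1.8), (0.25, 8, 0, 0, 0.0)],
    )
    def test_arithmetic(self, pic, nb, npoly, emr, mi):
        got_emr, got_mi = marker_index(pic, nb, npoly)
        assert got_emr == pytest.approx(emr)
        assert got_mi == pytest.approx(mi)

    def test_zero_bands_rejected(self):
        with pytest.raises(ValueError):
            marker_index(0.2, 0, 0)


def _pic_codominant_bruteforce(p):
    total = 1.0 - sum(x * x for x in p)
    for i, j in itertools.combinations(range(len(p)), 2):
        total -= 2.0 * p[i] ** 2 * p[j] ** 2
    return total


class TestPicCodominant:
    def test_monomorphic_and_biallelic(self):
        assert pic_codominant([1.0]) == pytest.approx(0.0)
        assert pic_codominant([0.5, 0.5]) == pytest.approx(0.375)

    @pytest.mark.parametrize("m", range(2, 11))
    def test_uniform_matches_bruteforce_double_sum(self, m):
        p = [1.0 / m] * m
        assert pic_codominant(p) == pytest.approx(_pic_codominant_bruteforce(p), abs=1e-12)

    @pytest.mark.parametrize("m", range(2, 11))
    def test_bounded_by_expected_heterozygosity(self, m):
        assert pic_codominant([1.0 / m] * m) <= 1.0 - 1.0 / m + 1e-12

    def test_random_frequencies_match_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.dirichlet(np.ones(rng.integers(2, 8)))
            assert pic_codominant(p) == pytest.approx(_pic_codominant_bruteforce(p), abs=1e-12)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            pic_codominant([1.2, -0.2])


class TestObservedHeterozygosity:
    def test_degenerate_tables(self):
        assert observed_heterozygosity([(1, 2)] * 5) == 1.0
        assert observed_heterozygosity([(1,)] * 5) == 0.0
        assert observed_heterozygosity([(1,), (1, 2), None, (2, 2)]) == pytest.approx(1 / 3)

    def test_hardy_weinberg_two_equifrequent_alleles(self):
        rng = np.random.default_rng(11)
        genos = [tuple(sorted(set(rng.choice([101, 105], 2)))) for _ in range(10_000)]
        # expected Ho = 2pq = 0.5; binomial s.e. ~ 0.005
        assert observed_heterozygosity(genos) == pytest.approx(0.5, abs=0.02)

    def test_triallelic_genotype_rejected(self):
        with pytest.raises(ValueError):
            observed_heterozygosity([(1, 2, 3)])


class TestLocusSummaries:
    def test_identities_and_ordering_invariance(self, small_table):
        summary = locus_summaries(to_binary(small_table))
        for _, row in summary.iterrows():
            assert row["mi"] == pytest.approx(row["pic_binary_mean"] * row["emr"], abs=1e-12)
            assert row["emr"] == pytest.approx(row["n_alleles"] * row["beta"], abs=1e-12)
        # permuting accessions must not change per-locus statistics
        perm = GenotypeTable(
            accessions=list(reversed(small_table.accessions)),
            locus_names=small_table.locus_names,
            calls=list(reversed(small_table.calls)),
        )
        assert locus_summaries(to_binary(perm)).equals(summary)

    def test_monomorphic_locus_has_zero_mi(self):
        table = GenotypeTable(["x", "y"], ["L01"], [[(101,)], [(101,)]])
        summary = locus_summaries(to_binary(table))
        assert summary.loc["L01", "beta"] == 0.0
        assert summary.loc["L01", "mi"] == 0.0


class TestAlleleCountProfiles:
    def test_degenerate_profiles(self):
        homo = GenotypeTable(["x", "y"], ["L01", "L02"], [[(1,), (2,)], [(1,), (2,)]])
        prof = summarize_allele_counts(homo, {"x": "g", "y": "g"})
        assert prof.loc[1, "g"] == pytest.approx(100.0)
        het = GenotypeTable(["x"], ["L01", "L02"], [[(1, 2), (3, 4)]])
        prof = summarize_allele_counts(het, {"x": "g"})
        assert prof.loc[2, "g"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_over_non_missing(self, small_table):
        prof = summarize_allele_counts(
            small_table, {a: "all" for a in small_table.accessions}
        )
        assert prof["all"].sum() == pytest.approx(100.0, abs=0.1)

    def test_tetraploids_show_more_triallelic_cells_than_diploids(self):
        table, labels = generate_dosage_population(
            {"AA": (2, 0, 60), "AAAA": (4, 0, 60)}, seed=99
        )
        prof = summarize_allele_counts(table, labels)
        assert prof.loc[3, "AAAA"] > prof.loc[3, "AA"]


class TestDosageFrequencyTrend:
    def test_reference_against_itself_is_identity(self, small_table):
        groups = {a: "g" for a in small_table.accessions}
        trend = dosage_frequency_trend(small_table, groups, "g", top_n=3)
        # allele 101 at L01 is carried by 3 of 4 accessions
        row = trend[(trend["locus"] == "L01") & (trend["allele"] == 101)]
        assert row["g"].iloc[0] == pytest.approx(0.75)

    def test_absent_allele_scores_zero(self):
        table = GenotypeTable(["x", "y"], ["L01"], [[(101,)], [(105,)]])
        trend = dosage_frequency_trend(table, {"x": "a", "y": "b"}, "a", top_n=1)
        assert trend["b"].iloc[0] == 0.0

    def test_a_pool_alleles_rise_with_a_dosage(self):
        table, labels = generate_dosage_population(
            {"BB": (0, 2, 40), "ABB": (1, 2, 40), "AAB": (2, 1, 40), "AAA": (3, 0, 40)},
            seed=23,
        )
        trend = dosage_frequency_trend(table, labels, "AAA", top_n=20)
        means = trend[["BB", "ABB", "AAB", "AAA"]].mean()
        assert means["BB"] <= means["ABB"] <= means["AAB"] <= means["AAA"]
        assert means["BB"] == 0.0  # disjoint pools: A alleles never appear in BB
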