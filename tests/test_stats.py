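import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from editome import stats
from editome.model import ContractViolation, SiteKey, Stratum


def stratum(n, t, p, label="g"):
    return Stratum(label=label, population=n, tested=t, positive=p)


class TestWeightedValidationRatio:
    def test_two_strata_worked_example(self):
        # 62.7% (69/110) and 24.2% (52/215) ratios weighted by populations
        # 3196 and 8724 combine to 34.5%
        ratio = stats.weighted_validation_ratio(
            [stratum(3196, 110, 69, "annotated"), stratum(8724, 215, 52, "unannotated")]
        )
        assert round(100 * ratio, 1) == 34.5

    def test_single_stratum_reduces_to_simple_ratio(self):
        assert stats.weighted_validation_ratio([stratum(50, 10, 5)]) == pytest.approx(0.5)

    def test_zero_tested_names_the_stratum(self):
        with pytest.raises(ContractViolation, match="bad_stratum"):
            stats.weighted_validation_ratio([stratum(10, 0, 0, "bad_stratum")])

    def test_matches_population_expansion_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            strata = []
            members = []
            for g in range(int(rng.integers(1, 6))):
                n = int(rng.integers(1, 200))
                t = int(rng.integers(1, 50))
                p = int(rng.integers(0, t + 1))
                strata.append(stratum(n, t, p, f"g{g}"))
                members.extend([p / t] * n)  # assign each member its stratum ratio
            expected = sum(members) / len(members)
            assert stats.weighted_validation_ratio(strata) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 1000), st.integers(1, 100), st.floats(0, 1)
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_result_lies_between_extreme_stratum_ratios(self, raw):
        strata = [
            stratum(n, t, int(round(frac * t)), f"g{i}")
            for i, (n, t, frac) in enumerate(raw)
        ]
        ratios = [s.ratio for s in strata]
        value = stats.weighted_validation_ratio(strata)
        assert min(ratios) - 1e-12 <= value <= max(ratios) + 1e-12

    def test_population_weighted_ratio_of_quoted_percentages(self):
        combined = stats.population_weighted_ratio([(3160, 0.745), (989, 0.735)])
        assert round(100 * combined) == 74


class TestMinFalseFraction:
    def test_tested_plus_untested_strata_worked_example(self):
        # 25.5% of 3160 (806) plus 76.5% of 2630 (2012) over 5790 -> 48.7%
        value = stats.estimate_min_false_fraction((3160, 0.255), (2630, 0.765))
        assert round(3160 * 0.255) == 806 and round(2630 * 0.765) == 2012
        assert round(100 * value, 1) == 48.7

    def test_accepts_stratum_arms(self):
        value = stats.estimate_min_false_fraction(
            stratum(100, 10, 5), (100, 0.5)
        )
        assert value == pytest.approx(100 / 200)

    @pytest.mark.parametrize("rate,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_rates(self, rate, expected):
        assert stats.estimate_min_false_fraction((100, rate), (50, rate)) == expected

    def test_monotone_in_each_fail_rate(self):
        base = stats.estimate_min_false_fraction((1000, 0.3), (500, 0.6))
        assert stats.estimate_min_false_fraction((1000, 0.4), (500, 0.6)) > base
        assert stats.estimate_min_false_fraction((1000, 0.3), (500, 0.7)) > base


class TestOddsRatioEnrichment:
    def test_null_enrichment_gives_unit_odds_ratio(self):
        results = stats.odds_ratio_enrichment(
            {"intron": 10, "other": 90}, {"intron": 100, "other": 900}
        )
        by = {r.element: r for r in results}
        assert by["intron"].odds_ratio == pytest.approx(1.0)

    def test_cross_product_of_the_2x2_table(self):
        results = stats.odds_ratio_enrichment(
            {"X": 10, "rest": 90}, {"X": 1000, "rest": 99000}
        )
        by = {r.element: r for r in results}
        assert by["X"].odds_ratio == pytest.approx(11.0)

    def test_zero_site_count_gives_zero(self):
        results = stats.odds_ratio_enrichment(
            {"X": 0, "rest": 10}, {"X": 100, "rest": 900}
        )
        by = {r.element: r for r in results}
        assert by["X"].odds_ratio == 0.0 and by["X"].defined

    def test_zero_denominator_is_flagged_not_fatal(self):
        results = stats.odds_ratio_enrichment(
            {"X": 10, "rest": 0}, {"X": 100, "rest": 900}
        )
        by = {r.element: r for r in results}
        assert not by["X"].defined

    def test_invariant_under_uniform_background_scaling(self):
        sites = {"X": 7, "Y": 13, "rest": 80}
        bg = {"X": 500, "Y": 1500, "rest": 8000}
        bg10 = {k: 10 * v for k, v in bg.items()}
        a = {r.element: r.odds_ratio for r in stats.odds_ratio_enrichment(sites, bg)}
        b = {r.element: r.odds_ratio for r in stats.odds_ratio_enrichment(sites, bg10)}
        assert a == pytest.approx(b)


class FakeGenome:
    """Minimal genome mapping for motif tests."""

    def __init__(self, seqs):
        self._seqs = seqs

    def __getitem__(self, chrom):
        return _FakeContig(self._seqs[chrom])


class _FakeContig:
    def __init__(self, seq):
        self.seq = seq

    def __len__(self):
        return len(self.seq)

    def __getitem__(self, item):
        return self.seq[item]


class TestMotifProfile:
    def test_identical_sequences_give_unit_fractions(self):
        genome = FakeGenome({"c": "TTTTTAGGGGG" * 3})
        # edited A at 0-based 5, 16, 27 -> 1-based 6, 17, 28
        sites = [SiteKey("c", p, "+") for p in (6, 17, 28)]
        profile = stats.motif_profile(sites, genome, halfwidth=5)
        assert profile.n == 3
        for offset in range(-5, 0):
            assert profile.fraction(offset, "U") == 1.0
        assert profile.fraction(0, "A") == 1.0
        for offset in range(1, 6):
            assert profile.fraction(offset, "G") == 1.0

    def test_minus_strand_sites_are_reverse_complemented(self):
        # forward CCCCCTAAAAA: the minus-strand read is TTTTTAGGGGG
        genome = FakeGenome({"c": "CCCCCTAAAAA"})
        profile = stats.motif_profile([SiteKey("c", 6, "-")], genome, halfwidth=5)
        assert profile.n == 1
        assert profile.fraction(0, "A") == 1.0
        assert profile.fraction(-1, "U") == 1.0
        assert profile.fraction(1, "G") == 1.0

    def test_fractions_sum_to_one_at_every_position(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACGT"), 500))
        genome = FakeGenome({"c": seq})
        sites = [
            SiteKey("c", i + 1, "+")
            for i in range(10, 490)
            if seq[i] == "A"
        ][:50]
        profile = stats.motif_profile(sites, genome)
        assert profile.n == 50
        np.testing.assert_allclose(profile.fractions.sum(axis=1), 1.0)

    def test_non_adenosine_sites_are_excluded_and_counted(self):
        genome = FakeGenome({"c": "GGGGGGGGGGGG"})
        profile = stats.motif_profile([SiteKey("c", 6, "+")], genome)
        assert profile.n == 0 and profile.n_non_adenosine == 1

    def test_short_flank_sites_are_skipped(self):
        genome = FakeGenome({"c": "AAAAAAAA"})
        profile = stats.motif_profile([SiteKey("c", 2, "+")], genome, halfwidth=5)
        assert profile.n == 0 and profile.n_skipped_flank == 1


class TestMotifDifference:
    def build(self, seq, positions):
        genome = FakeGenome({"c": seq})
        return stats.motif_profile(
            [SiteKey("c", p, "+") for p in positions], genome, halfwidth=2
        )

    def test_identical_profiles_difference_is_zero(self):
        profile = self.build("GGAGGGGAGG", (3, 8))
        np.testing.assert_allclose(stats.motif_difference(profile, profile), 0.0)

    def test_per_position_differences_sum_to_zero(self):
        pos = self.build("TTATTGGAGG", (3, 8))
        neg = self.build("GGAGGCCACC", (3, 8))
        diff = stats.motif_difference(pos, neg)
        np.testing.assert_allclose(diff.sum(axis=1), 0.0, atol=1e-12)

    def test_u_enrichment_at_minus_one_is_positive(self):
        pos = self.build("TTATTTTATT", (3, 8))  # U at -1 in the positive set
        neg = self.build("GGAGGGGAGG", (3, 8))
        diff = stats.motif_difference(pos, neg)
        assert diff[2 - 1, stats.MOTIF_BASES.index("U")] > 0

    def test_halfwidth_mismatch_is_a_contract_violation(self):
        genome = FakeGenome({"c": "TTTTTAGGGGG"})
        p5 = stats.motif_profile([SiteKey("c", 6, "+")], genome, halfwidth=5)
        p3 = stats.motif_profile([SiteKey("c", 6, "+")], genome, halfwidth=3)
        with pytest.raises(ContractViolation):
            stats.motif_difference(p5, p3)
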