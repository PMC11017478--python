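import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavecharr import popgen
from conftest import make_genotypes
from oracles import (dce_oracle, dest_oracle, holm_oracle, rarefied_richness_oracle,
                     wc_theta_oracle)


def two_pop_table(calls_a, calls_b):
    return make_genotypes({"A": calls_a, "B": calls_b})


class TestAlleleFrequencies:
    def test_simple_counts(self):
        gt = make_genotypes({"P": [[(1, 1)], [(1, 2)], [(2, 2)]]})
        freqs = popgen.allele_frequencies(gt)
        pa = freqs.set_index("allele")["frequency"]
        assert pa[1] == 0.5 and pa[2] == 0.5

    def test_fixed_allele(self):
        gt = make_genotypes({"P": [[(1, 1)], [(1, 1)]]})
        freqs = popgen.allele_frequencies(gt)
        assert freqs["frequency"].tolist() == [1.0]

    def test_matches_hand_tally_and_flags_untyped(self):
        rng = np.random.default_rng(3)
        calls = [[(int(rng.integers(1, 4)), int(rng.integers(1, 4)))] for _ in range(10)]
        gt = make_genotypes({"P": calls, "Q": [[None]]})
        freqs = popgen.allele_frequencies(gt)
        hand = {}
        for (a, b), in calls:
            hand[a] = hand.get(a, 0) + 1
            hand[b] = hand.get(b, 0) + 1
        sub = freqs[freqs.population == "P"].set_index("allele")["frequency"]
        for al, cnt in hand.items():
            assert sub[al] == pytest.approx(cnt / 20, abs=1e-15)
        undef = freqs[freqs.population == "Q"]
        assert undef["frequency"].isna().all()


class TestDiversity:
    def test_textbook_heterozygosities(self):
        gt = make_genotypes({"P": [[(1, 1)], [(1, 2)], [(2, 2)]]})
        table = popgen.diversity_summary(gt, g=2).table
        assert table.loc["P", "Ho"] == pytest.approx(1 / 3)
        assert table.loc["P", "He"] == pytest.approx(0.6)  # (6/5)(1 - 0.5)

    def test_all_heterozygotes_give_negative_fis(self):
        gt = make_genotypes({"P": [[(1, 2)]] * 10})
        table = popgen.diversity_summary(gt, g=2).table
        assert table.loc["P", "Ho"] == 1.0
        assert table.loc["P", "Fis"] < 0

    def test_fis_centred_on_zero_under_random_mating(self):
        rng = np.random.default_rng(7)
        fis = []
        for _ in range(30):
            calls = [[tuple(rng.integers(1, 5, size=2))] for _ in range(200)]
            gt = make_genotypes({"P": calls})
            fis.append(popgen.diversity_summary(gt, g=2).table.loc["P", "Fis"])
        se = np.std(fis, ddof=1) / np.sqrt(len(fis))
        assert abs(np.mean(fis)) < 3 * se + 1e-3


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        gt = make_genotypes({"P": [[(1, 1)]] * 8})
        assert popgen.allelic_richness(gt, g=4).loc["P", "Ar"] == pytest.approx(1.0)

    def test_g_equal_n_returns_observed_count(self):
        gt = make_genotypes({"P": [[(1, 2)], [(2, 3)], [(3, 4)]]})
        assert popgen.allelic_richness(gt, g=6).loc["P", "Ar"] == pytest.approx(4.0)

    def test_closed_form_even_split(self):
        gt = make_genotypes({"P": [[(1, 2)]] * 10})
        expect = 2 * (1 - math.comb(10, 2) / math.comb(20, 2))
        assert popgen.allelic_richness(gt, g=2).loc["P", "Ar"] == pytest.approx(expect, abs=1e-15)

    @pytest.mark.parametrize("seed,g", [(0, 2), (1, 4), (2, 6)])
    def test_matches_exhaustive_enumeration(self, seed, g):
        rng = np.random.default_rng(seed)
        calls = [[tuple(rng.integers(1, 5, size=2))] for _ in range(6)]
        gt = make_genotypes({"P": calls})
        genes = [a for (pair,) in calls for a in pair]
        expect = rarefied_richness_oracle(genes, g)
        assert popgen.allelic_richness(gt, g=g).loc["P", "Ar"] == pytest.approx(expect, abs=1e-12)

    def test_private_richness_no_sharing(self):
        # population P's allele 9 is absent from Q: private Ar equals its own Ar term
        gt = make_genotypes({"P": [[(9, 9)]] * 5, "Q": [[(1, 1)]] * 5})
        par = popgen.allelic_richness(gt, g=4)
        assert par.loc["P", "PAr"] == pytest.approx(1.0)
        assert par.loc["Q", "PAr"] == pytest.approx(1.0)


class TestHWE:
    def test_heterozygote_deficit_detected(self):
        calls = [[(1, 1)]] * 25 + [[(2, 2)]] * 25
        gt = make_genotypes({"P": calls})
        p = popgen.hwe_test(gt, n_perm=500, seed=0).loc["P", "L1"]
        assert p < 0.01

    def test_monomorphic_undefined(self):
        gt = make_genotypes({"P": [[(1, 1)]] * 10})
        assert np.isnan(popgen.hwe_test(gt, n_perm=100, seed=0).loc["P", "L1"])

    def test_type_one_error_rate_calibrated(self):
        rng = np.random.default_rng(42)
        n_loci, n = 500, 40
        alleles = rng.integers(1, 4, size=(n, n_loci, 2))
        gt = make_genotypes({"P": [[tuple(alleles[i, l]) for l in range(n_loci)]
                                   for i in range(n)]})
        pvals = popgen.hwe_test(gt, n_perm=200, seed=1).loc["P"].to_numpy()
        rate = np.mean(pvals <= 0.05)
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_loci)
        assert 0.05 - half <= rate <= 0.05 + half


class TestWeirCockerham:
    def test_identical_populations_near_zero(self):
        calls = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]]
        gt = two_pop_table(calls, calls)
        res = popgen.pairwise_fst(gt, n_resample=200, seed=0)
        row = res.pairs.iloc[0]
        assert row.theta == pytest.approx(0.0, abs=1e-12) or row.theta < 0
        assert not row.differentiated

    def test_fixed_difference_is_one(self):
        gt = two_pop_table([[(1, 1)]] * 6, [[(2, 2)]] * 6)
        theta, _ = popgen.weir_cockerham_theta(gt)
        assert theta == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        n_loci = 3
        calls_a = [[tuple(rng.integers(1, 4, size=2)) for _ in range(n_loci)]
                   for _ in range(4)]
        calls_b = [[tuple(rng.integers(1, 4, size=2)) for _ in range(n_loci)]
                   for _ in range(4)]
        gt = two_pop_table(calls_a, calls_b)
        theta, _ = popgen.weir_cockerham_theta(gt)
        pop1 = [[ind[l] for ind in calls_a] for l in range(n_loci)]
        pop2 = [[ind[l] for ind in calls_b] for l in range(n_loci)]
        assert theta == pytest.approx(wc_theta_oracle(pop1, pop2), abs=1e-12)

    @given(st.permutations([1, 2, 3, 4]))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_allele_relabelling(self, relabel):
        rng = np.random.default_rng(9)
        calls_a = [[tuple(rng.integers(1, 5, size=2))] for _ in range(6)]
        calls_b = [[tuple(rng.integers(1, 5, size=2))] for _ in range(6)]
        gt = two_pop_table(calls_a, calls_b)
        mapping = {i + 1: relabel[i] for i in range(4)}
        gt2 = two_pop_table(
            [[(mapping[a], mapping[b]) for a, b in ind] for ind in calls_a],
            [[(mapping[a], mapping[b]) for a, b in ind] for ind in calls_b],
        )
        t1, _ = popgen.weir_cockerham_theta(gt)
        t2, _ = popgen.weir_cockerham_theta(gt2)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_single_locus_has_no_ci(self):
        gt = two_pop_table([[(1, 2)], [(1, 1)]], [[(2, 2)], [(1, 2)]])
        res = popgen.pairwise_fst(gt, n_resample=100, seed=0)
        row = res.pairs.iloc[0]
        assert np.isnan(row.ci_low) and not np.isnan(row.theta)


class TestDest:
    def test_identical_populations_zero(self):
        calls = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]]
        d = popgen.pairwise_dest(two_pop_table(calls, calls))
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_non_overlapping_alleles_approach_one(self):
        n = 200
        gt = two_pop_table([[(1, 1)]] * n + [[(1, 2)]] * n,
                           [[(3, 3)]] * n + [[(3, 4)]] * n)
        assert popgen.pairwise_dest(gt).data[0, 1] > 0.99

    def test_matches_published_formula(self):
        rng = np.random.default_rng(21)
        calls_a = [[tuple(rng.integers(1, 4, size=2)) for _ in range(2)] for _ in range(8)]
        calls_b = [[tuple(rng.integers(2, 5, size=2)) for _ in range(2)] for _ in range(6)]
        gt = two_pop_table(calls_a, calls_b)
        pop1 = [[ind[l] for ind in calls_a] for l in range(2)]
        pop2 = [[ind[l] for ind in calls_b] for l in range(2)]
        assert popgen.pairwise_dest(gt).data[0, 1] == pytest.approx(
            dest_oracle(pop1, pop2), abs=1e-12)


class TestChordDistance:
    def test_identical_zero_and_symmetric(self):
        calls = [[(1, 2)], [(2, 2)]]
        d = popgen.chord_distance(two_pop_table(calls, calls))
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.data[0, 1] == d.data[1, 0]

    def test_disjoint_fixed_alleles_closed_form(self):
        gt = two_pop_table([[(1, 1)]] * 3, [[(2, 2)]] * 3)
        assert popgen.chord_distance(gt).data[0, 1] == pytest.approx(
            2 * np.sqrt(2) / np.pi, abs=1e-14)

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(8)
        calls_a = [[tuple(rng.integers(1, 5, size=2)) for _ in range(3)] for _ in range(7)]
        calls_b = [[tuple(rng.integers(1, 5, size=2)) for _ in range(3)] for _ in range(5)]
        gt = two_pop_table(calls_a, calls_b)

        def freq_dicts(calls, n_loci):
            out = []
            for l in range(n_loci):
                genes = [a for ind in calls for a in ind[l]]
                out.append({al: genes.count(al) / len(genes) for al in set(genes)})
            return out

        expect = dce_oracle(freq_dicts(calls_a, 3), freq_dicts(calls_b, 3))
        assert popgen.chord_distance(gt).data[0, 1] == pytest.approx(expect, abs=1e-12)


class TestHeterogeneity:
    def test_identical_populations_not_significant(self):
        calls = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(1, 1)]]
        p = popgen.heterogeneity_test(two_pop_table(calls, calls), ("A", "B"),
                                      n_perm=200, seed=0)
        assert p > 0.2

    def test_fixed_difference_highly_significant(self):
        gt = two_pop_table([[(1, 1)]] * 20, [[(2, 2)]] * 20)
        p = popgen.heterogeneity_test(gt, ("A", "B"), n_perm=1000, seed=0)
        assert p <= 0.001

    def test_holm_step_down_matches_hand_rule(self):
        pvals = [0.001, 0.04, 0.2]
        reject, adjusted = popgen.sequential_bonferroni(pvals, alpha=0.05)
        assert reject.tolist() == holm_oracle(pvals)
        assert adjusted[0] == pytest.approx(0.003)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_holm_agrees_with_oracle(self, pvals):
        reject, _ = popgen.sequential_bonferroni(pvals, alpha=0.05)
        assert reject.tolist() == holm_oracle(pvals)


def test_pair_count_for_26_populations():
    """26 sampled populations give 325 unordered pairwise comparisons."""
    from itertools import combinations
    assert sum(1 for _ in combinations(range(26), 2)) == 325
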