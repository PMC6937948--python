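"""Diversity indices, neutrality tests, ΦST and AMOVA."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from mesophylo.popdata import (
    HaplotypeTable,
    PopulationAssignment,
    SequenceAlignment,
    collapse_haplotypes,
)
from mesophylo import sumstats
from mesophylo.sumstats import (
    amova,
    ewens_log_pmf,
    fus_fs,
    haplotype_diversity,
    neutrality_significance,
    nucleotide_diversity,
    pairwise_fst,
    summarize,
    tajimas_d,
)

from conftest import random_alignment


def table(*counts):
    haps = ["ACGT", "AGGT", "ATGT", "ACCT", "ACGA", "TCGA", "GGGG", "CCCC"]
    return HaplotypeTable(tuple(haps[: len(counts)]), tuple(counts), "complete-deletion")


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, hd, sd",
        [
            ((4, 1), 0.4, 0.237),  # n=5, two haplotypes
            ((3, 1), 0.5, 0.265),  # n=4, two haplotypes
            ((1, 1, 1, 1, 1), 1.0, 0.1265),  # n=5, all distinct
        ],
    )
    def test_published_configurations(self, counts, hd, sd):
        got_hd, got_sd = haplotype_diversity(table(*counts))
        assert got_hd == pytest.approx(hd, abs=5e-4)
        assert got_sd == pytest.approx(sd, abs=5e-4)

    def test_single_haplotype_is_zero(self):
        hd, sd = haplotype_diversity(table(7))
        assert hd == 0.0

    def test_n_below_two_not_available(self):
        hd, sd = haplotype_diversity(table(1))
        assert math.isnan(hd) and math.isnan(sd)

    def test_brute_force_oracle(self, rng):
        """Hd equals the bias-corrected probability that two draws differ,
        by direct enumeration over ordered pairs."""
        for _ in range(20):
            counts = rng.integers(1, 6, size=rng.integers(2, 5))
            n = counts.sum()
            if n < 2:
                continue
            labels = np.repeat(np.arange(len(counts)), counts)
            differ = sum(
                labels[i] != labels[j] for i in range(n) for j in range(n) if i != j
            )
            expect = differ / (n * (n - 1))  # already the unbiased estimator
            hd, _ = haplotype_diversity(table(*counts))
            assert hd == pytest.approx(expect, abs=1e-12)


class TestNucleotideDiversity:
    def test_singleton_site(self, tiny_alignment):
        k, pi = nucleotide_diversity(tiny_alignment)
        assert k == pytest.approx(0.4)  # 4 of 10 pairs differ at one site
        assert pi == pytest.approx(0.0004)

    def test_identical_sequences(self):
        aln = SequenceAlignment.from_strings([("a", "ACGT"), ("b", "ACGT")])
        assert nucleotide_diversity(aln) == (0.0, 0.0)

    def test_two_sequences_three_diffs(self):
        aln = SequenceAlignment.from_strings([("a", "AAAAAAAAAA"), ("b", "CCCAAAAAAA")])
        k, pi = nucleotide_diversity(aln)
        assert k == 3.0 and pi == pytest.approx(0.3)

    def test_brute_force_hamming_oracle(self, rng):
        aln = random_alignment(rng, 6, 40)
        k, pi = nucleotide_diversity(aln)
        dists = [
            sum(a != b for a, b in zip(aln.matrix[i], aln.matrix[j]))
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert k == pytest.approx(np.mean(dists))


class TestTajimasD:
    @pytest.mark.parametrize(
        "n, S, k, expect",
        [
            (5, 1, 0.4, -0.816),  # one singleton among five
            (4, 3, 1.5, -0.75445),  # three private sites on one of four
        ],
    )
    def test_published_values(self, n, S, k, expect):
        assert tajimas_d(n, S, k) == pytest.approx(expect, abs=5e-4)

    def test_no_segregating_sites_is_na(self):
        assert math.isnan(tajimas_d(5, 0, 0.0))

    def test_independent_transcription_oracle(self, rng):
        """Match a second, independently written evaluation of the 1989
        constants on random (n, S, k) configurations."""

        def oracle(n, S, k):
            a1 = np.sum(1.0 / np.arange(1, n))
            a2 = np.sum(1.0 / np.arange(1, n) ** 2)
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            return (k - S / a1) / np.sqrt(
                (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
            )

        for _ in range(30):
            n = int(rng.integers(4, 9))
            S = int(rng.integers(1, 20))
            k = float(rng.uniform(0.0, S))
            assert tajimas_d(n, S, k) == pytest.approx(oracle(n, S, k), rel=1e-12)

    def test_statistic_from_alignment_matches_components(self, rng):
        """D computed inside summarize() equals D from independently
        extracted (n, S, k)."""
        aln = random_alignment(rng, 7, 60)
        st = summarize(aln)
        k, _ = nucleotide_diversity(aln)
        S, _ = sumstats.segregating_sites(aln)
        assert st.D == pytest.approx(tajimas_d(7, S, k))
        assert st.FS == pytest.approx(
            fus_fs(7, k, collapse_haplotypes(aln).k_obs)
        )


def brute_force_stirling(n):
    """|s(n, k)| by the textbook integer recurrence."""
    s = [[0] * (n + 1) for _ in range(n + 1)]
    s[0][0] = 1
    for m in range(1, n + 1):
        for k in range(1, m + 1):
            s[m][k] = s[m - 1][k - 1] + (m - 1) * s[m - 1][k]
    return s[n]


class TestFusFs:
    @pytest.mark.parametrize(
        "n, k, K_obs, expect",
        [
            (5, 0.4, 2, 0.09),
            (4, 1.5, 2, 1.716),
        ],
    )
    def test_published_values(self, n, k, K_obs, expect):
        assert fus_fs(n, k, K_obs) == pytest.approx(expect, abs=5e-3)

    def test_undefined_cases(self):
        assert math.isnan(fus_fs(5, 0.4, 1))
        assert math.isnan(fus_fs(5, 0.0, 3))

    @pytest.mark.parametrize("n", range(2, 11))
    def test_ewens_pmf_sums_to_one(self, n):
        for theta in (0.1, 0.7, 2.3, 11.0):
            total = np.exp(ewens_log_pmf(n, theta)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n", [3, 6, 9])
    def test_matches_integer_stirling_recurrence(self, n):
        theta = 1.3
        exact = brute_force_stirling(n)
        rising = math.prod(theta + i for i in range(n))
        expected = np.array([exact[j] * theta**j / rising for j in range(1, n + 1)])
        got = np.exp(ewens_log_pmf(n, theta))
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_tail_probability_against_enumeration(self):
        n, k, K_obs = 6, 0.9, 3
        exact = brute_force_stirling(n)
        rising = math.prod(k + i for i in range(n))
        sp = sum(exact[j] * k**j / rising for j in range(K_obs, n + 1))
        assert fus_fs(n, k, K_obs) == pytest.approx(math.log(sp / (1 - sp)), rel=1e-9)


class TestNeutralitySignificance:
    def test_extreme_observation_has_tiny_p(self, rng):
        p = neutrality_significance("D", -10.0, 8, 2.0, reps=200, rng=rng)
        assert p < 0.02

    def test_extreme_positive_fs_has_large_p(self, rng):
        p = neutrality_significance("FS", 30.0, 8, 2.0, reps=200, rng=rng)
        assert p > 0.95

    def test_null_p_values_roughly_uniform(self, rng):
        """Lower-tail p of statistics drawn from the null should be ~U(0,1)."""
        from mesophylo.coalsim import simulate_infinite_sites_stats

        pvals = []
        for _ in range(120):
            S, k, K = simulate_infinite_sites_stats(8, 3.0, rng)
            d = sumstats.tajimas_d(8, S, k)
            if not math.isfinite(d):
                continue
            pvals.append(neutrality_significance("D", d, 8, 3.0, reps=150, rng=rng))
        stat, p = sps.kstest(pvals, "uniform")
        assert p > 0.01


def block_alignment(blocks):
    """Alignment from (prefix, n_copies, sequence) blocks."""
    recs = []
    for prefix, n, seq in blocks:
        recs.extend((f"{prefix}{i}", seq) for i in range(n))
    return SequenceAlignment.from_strings(recs)


class TestPairwiseFst:
    def test_identical_compositions_give_zero(self, rng):
        aln = block_alignment([("a", 2, "AAAA"), ("a_", 2, "CCAA"),
                               ("b", 2, "AAAA"), ("b_", 2, "CCAA")])
        assign = PopulationAssignment(
            {"a0": "P", "a1": "P", "a_0": "P", "a_1": "P",
             "b0": "Q", "b1": "Q", "b_0": "Q", "b_1": "Q"},
            {"P": "P", "Q": "Q"},
        )
        phist, p = pairwise_fst(aln, assign, "P", "Q", permutations=200, rng=rng)
        # identical compositions: at or below zero (negative values are
        # reported as computed, not clamped) and clearly non-significant
        assert phist <= 0.05
        assert p > 0.3

    def test_fixed_difference_monomorphic_pops(self, rng):
        aln = block_alignment([("a", 3, "AAAA"), ("b", 3, "CCCC")])
        assign = PopulationAssignment(
            {f"a{i}": "P" for i in range(3)} | {f"b{i}": "Q" for i in range(3)},
            {"P": "P", "Q": "Q"},
        )
        phist, p = pairwise_fst(aln, assign, "P", "Q", permutations=300, rng=rng)
        assert phist == pytest.approx(1.0)
        assert p < 0.2  # only 10 distinct splits of 6 into 3+3

    def test_zero_variance_flagged(self, rng):
        aln = block_alignment([("a", 2, "AAAA"), ("b", 2, "AAAA")])
        assign = PopulationAssignment(
            {"a0": "P", "a1": "P", "b0": "Q", "b1": "Q"}, {"P": "P", "Q": "Q"}
        )
        phist, p = pairwise_fst(aln, assign, "P", "Q", permutations=50, rng=rng)
        assert math.isnan(phist) and math.isnan(p)


class TestAmova:
    @staticmethod
    def design():
        # 2 groups x 2 populations x 2 individuals
        seqs = {
            "g1p1": "AAAAAAAAAA",
            "g1p2": "CCAAAAAAAA",  # 2 diffs from g1p1
            "g2p1": "GGGGGGGGAA",  # 8+ diffs across groups
            "g2p2": "GGGGGGGGCC",
        }
        recs, pop_of = [], {}
        for pop, seq in seqs.items():
            for i in range(2):
                recs.append((f"{pop}_{i}", seq))
                pop_of[f"{pop}_{i}"] = pop
        aln = SequenceAlignment.from_strings(recs)
        assign = PopulationAssignment(
            pop_of, {"g1p1": "G1", "g1p2": "G1", "g2p1": "G2", "g2p2": "G2"}
        )
        return aln, assign

    def test_component_additivity_and_percentages(self, rng):
        aln, assign = self.design()
        res = amova(aln, assign, permutations=100, rng=rng)
        assert sum(res.percent) == pytest.approx(100.0, abs=0.01)
        # the sums of squares decompose the total exactly
        d2 = sumstats.pairwise_difference_matrix(aln)
        n = aln.n_samples
        ssd_total = d2.sum() / (2 * n)
        assert sum(res.ss) == pytest.approx(ssd_total, rel=1e-9)
        # fixation indices are ratios of the (non-negative here) components
        assert 0 <= res.f_ct <= 1 and 0 <= res.f_sc <= 1 and 0 <= res.f_st <= 1

    def test_hand_worked_moment_solution(self, rng):
        """Within-population distances 0, between-population-within-group
        distance 2, between-group distance ~10: components reproduce the
        hand-solved moment equations for the balanced 2x2x2 design."""
        aln, assign = self.design()
        res = amova(aln, assign, permutations=100, rng=rng)
        d2 = sumstats.pairwise_difference_matrix(aln)
        # hand computation (balanced sizes: n=2 per pop, 4 per group, N=8)
        pops = [[0, 1], [2, 3], [4, 5], [6, 7]]
        groups = [[0, 1, 2, 3], [4, 5, 6, 7]]
        ssd_wp = sum(d2[np.ix_(p, p)].sum() / (2 * len(p)) for p in pops)
        ssd_wg = sum(d2[np.ix_(g, g)].sum() / (2 * len(g)) for g in groups)
        ssd_tot = d2.sum() / (2 * 8)
        sigma_c = ssd_wp / (8 - 4)
        sigma_b = ((ssd_wg - ssd_wp) / (4 - 2) - sigma_c) / 2.0
        sigma_a = ((ssd_tot - ssd_wg) / (2 - 1) - sigma_c - 2 * sigma_b) / 4.0
        assert res.sigma2 == pytest.approx((sigma_a, sigma_b, sigma_c))
        tot = sigma_a + sigma_b + sigma_c
        assert res.f_ct == pytest.approx(sigma_a / tot)
        assert res.f_sc == pytest.approx(sigma_b / (sigma_b + sigma_c))
        assert res.f_st == pytest.approx((sigma_a + sigma_b) / tot)

    def test_all_identical_sequences_flagged(self, rng):
        aln = block_alignment([("a", 2, "AAAA"), ("b", 2, "AAAA"),
                               ("c", 2, "AAAA"), ("d", 2, "AAAA")])
        assign = PopulationAssignment(
            {f"{p}{i}": p for p in "abcd" for i in range(2)},
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2"},
        )
        res = amova(aln, assign, permutations=50, rng=rng)
        assert res.sigma2 == (0.0, 0.0, 0.0)
        assert "zero_total_variance" in res.flags

    def test_group_permutation_count_limits_fct_p(self, rng):
        """With K groups of single populations the number of distinct
        reassignments is small, structurally bounding the F_CT p-value."""
        aln, assign = self.design()
        # regroup: every population its own group -> 4 groups of 1 pop each
        assign_single = PopulationAssignment(
            assign.population_of, {p: p.upper() for p in assign.populations}
        )
        res = amova(aln, assign_single, permutations=200, rng=rng)
        # 4 populations into 4 labelled singleton groups: 4! = 24 distinct
        assert res.n_distinct_group_permutations == 24
        assert res.p_ct >= 1.0 / 24


class TestSummarize:
    def test_na_convention_single_haplotype(self):
        aln = SequenceAlignment.from_strings([(f"s{i}", "ACGT") for i in range(3)])
        st = summarize(aln)
        assert st.K_obs == 1
        assert st.is_na("Hd") and st.is_na("D") and st.is_na("FS")
        assert st.S == 0

    def test_tiny_alignment_full_vector(self, tiny_alignment):
        st = summarize(tiny_alignment)
        assert (st.n, st.S, st.K_obs) == (5, 1, 2)
        assert st.k == pytest.approx(0.4)
        assert st.Hd == pytest.approx(0.4)
        assert st.sd_Hd == pytest.approx(0.237, abs=5e-4)
        assert st.D == pytest.approx(-0.816, abs=5e-4)
        assert st.FS == pytest.approx(0.09, abs=5e-3)
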