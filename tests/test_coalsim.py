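"""Coalescent genealogies, HKY mutation, and demographic scenarios."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from mesophylo.coalsim import (
    Admixture,
    DemographicScenario,
    MutationModel,
    ScenarioError,
    SizeChange,
    Split,
    effective_size_from_theta,
    mutate_hky,
    scenario_from_dict,
    simulate_dataset,
    simulate_genealogy,
    simulate_infinite_sites_stats,
    theta_from,
)
from mesophylo import sumstats


def one_pop(n, N):
    return DemographicScenario("one", {"p": n}, {"p": float(N)}, ())


def split_scenario(t, n=5, N=10_000.0):
    return DemographicScenario(
        "split",
        {"A": n, "B": n},
        {"A": N, "B": N},
        (Split(float(t), ("A", "B"), "anc", N),),
    )


class TestScenarioValidation:
    def test_decreasing_event_times_rejected(self):
        scen = DemographicScenario(
            "bad", {"A": 2, "B": 2, "C": 2},
            {"A": 1e4, "B": 1e4, "C": 1e4},
            (
                Split(2000.0, ("A", "B"), "ab", 1e4),
                Split(1000.0, ("ab", "C"), "root", 1e4),
            ),
        )
        with pytest.raises(ScenarioError, match="non-decreasing"):
            scen.validate()

    def test_dead_population_referenced(self):
        scen = DemographicScenario(
            "bad", {"A": 2, "B": 2},
            {"A": 1e4, "B": 1e4},
            (
                Split(1000.0, ("A", "B"), "anc", 1e4),
                SizeChange(2000.0, "A", 5e3),
            ),
        )
        with pytest.raises(ScenarioError, match="dead population"):
            scen.validate()

    def test_more_than_one_population_left(self):
        scen = DemographicScenario("bad", {"A": 2, "B": 2}, {"A": 1e4, "B": 1e4}, ())
        with pytest.raises(ScenarioError, match="exactly one"):
            scen.validate()

    def test_parameter_resolution(self):
        scen = DemographicScenario(
            "templ", {"A": 2, "B": 2}, {"A": "N", "B": "N"},
            (Split("t_split", ("A", "B"), "anc", "N"),),
        )
        concrete = scen.resolve({"N": 2e4, "t_split": 5e4})
        assert concrete.sizes["A"] == 2e4
        assert concrete.events[0].time == 5e4
        with pytest.raises(ScenarioError, match="unresolved"):
            scen.resolve({"N": 2e4})

    def test_yaml_round_trip_shape(self):
        d = {
            "name": "s",
            "samples": {"A": 3, "B": 3},
            "sizes": {"A": 1e4, "B": 1e4},
            "events": [
                {"kind": "split", "time": 1e4, "children": ["A", "B"], "ancestor": "anc", "ancestor_size": 1e4}
            ],
        }
        scen = scenario_from_dict(d)
        scen.validate()
        assert isinstance(scen.events[0], Split)


class TestGenealogy:
    def test_pair_coalescence_time_is_2n(self, rng):
        """E[T2] = 2N generations under the haploid-scaled convention."""
        N = 5_000.0
        times = []
        scen = one_pop(2, N)
        for _ in range(4000):
            g = simulate_genealogy(scen, rng)
            times.append(g.time.max())
        se = np.std(times) / math.sqrt(len(times))
        assert np.mean(times) == pytest.approx(2 * N, abs=3 * se)

    def test_watterson_total_length(self, rng):
        """E[total length] = 4N·a1(n); with θ = 4Nu this yields E[S] = θ·a1."""
        N, n = 5_000.0, 10
        a1 = sum(1.0 / i for i in range(1, n))
        lengths = [
            simulate_genealogy(one_pop(n, N), rng).total_branch_length()
            for _ in range(3000)
        ]
        se = np.std(lengths) / math.sqrt(len(lengths))
        assert np.mean(lengths) == pytest.approx(4 * N * a1, abs=3 * se)

    def test_split_at_zero_equals_panmixia(self, rng):
        """Two populations merging at t=0 are indistinguishable from one."""
        split_h = [
            simulate_genealogy(split_scenario(0.0, n=3), rng).time.max()
            for _ in range(1500)
        ]
        pan_h = [
            simulate_genealogy(one_pop(6, 10_000.0), rng).time.max()
            for _ in range(1500)
        ]
        _, p = sps.ks_2samp(split_h, pan_h)
        assert p > 0.01

    def test_admixture_r1_equals_pure_split(self, rng):
        """Admixture routing every lineage to one source reduces to a split."""
        N = 10_000.0
        adm = DemographicScenario(
            "adm", {"A": 4, "B": 4}, {"A": N, "B": N, "Bcont": N},
            (
                Admixture(1000.0, "B", ("A", "Bcont"), 1.0),
                Split(50_000.0, ("A", "Bcont"), "anc", N),
            ),
        )
        # with r=1 all B lineages join A at t=1000; Bcont is empty until the split
        pure = DemographicScenario(
            "pure", {"A": 4, "B": 4}, {"A": N, "B": N},
            (Split(1000.0, ("A", "B"), "A2", N),
             Split(50_000.0, ("A2",), "anc", N)),
        )
        k_adm, k_pure = [], []
        model = MutationModel(u=4e-8)
        for _ in range(600):
            a1 = mutate_hky(simulate_genealogy(adm, rng), model, 300, rng)
            a2 = mutate_hky(simulate_genealogy(pure, rng), model, 300, rng)
            k_adm.append(sumstats.nucleotide_diversity(a1)[0])
            k_pure.append(sumstats.nucleotide_diversity(a2)[0])
        _, p = sps.ks_2samp(k_adm, k_pure)
        assert p > 0.01


class TestMutateHky:
    def test_zero_rate_gives_identical_sequences(self, rng):
        g = simulate_genealogy(one_pop(5, 1e4), rng)
        aln = mutate_hky(g, MutationModel(u=0.0), 100, rng)
        assert len(set("".join(r) for r in aln.matrix)) == 1

    def test_large_kappa_suppresses_transversions(self, rng):
        g = simulate_genealogy(one_pop(2, 5e4), rng)
        aln = mutate_hky(g, MutationModel(kappa=5e3, u=2e-6), 2000, rng)
        a, b = aln.matrix[0], aln.matrix[1]
        diff = a != b
        purine = np.isin(aln.matrix, ["A", "G"])
        transversion = diff & (purine[0] != purine[1])
        assert transversion.sum() <= max(1, 0.05 * diff.sum())

    def test_jc_expected_divergence(self, rng):
        """κ=1 equal frequencies equals Jukes–Cantor: observed p-distance on
        a fixed two-leaf tree matches p = 3/4(1 − e^{−4ut/3})."""
        from mesophylo.coalsim import Genealogy

        t, u, L = 40_000.0, 1e-6, 4000
        expect = 0.75 * (1.0 - math.exp(-8.0 * u * t / 3.0))  # branch sum 2t
        g = Genealogy(
            2,
            np.array([2, 2, -1]),
            np.array([0.0, 0.0, t]),
            ("A", "A"),
        )
        props = []
        model = MutationModel(kappa=1.0, u=u)
        for _ in range(40):
            aln = mutate_hky(g, model, L, rng)
            props.append(float((aln.matrix[0] != aln.matrix[1]).mean()))
        se = np.std(props) / math.sqrt(len(props))
        assert np.mean(props) == pytest.approx(expect, abs=max(3 * se, 0.004))

    def test_exchangeability_of_sample_labels(self, rng):
        """Permuting samples within a population leaves statistics invariant."""
        scen = split_scenario(30_000.0, n=4)
        ds = simulate_dataset(scen, {}, MutationModel(u=4e-8), 500, rng)
        st = sumstats.summarize(ds.alignment)
        perm = list(ds.alignment.sample_ids)
        perm[0], perm[3] = perm[3], perm[0]  # swap within population A
        st_perm = sumstats.summarize(ds.alignment.subset(perm))
        assert (st.S, st.K_obs) == (st_perm.S, st_perm.K_obs)
        assert st.k == pytest.approx(st_perm.k)
        np.testing.assert_equal(st.Hd, st_perm.Hd)  # nan-safe
        np.testing.assert_equal(st.D, st_perm.D)


class TestSimulateDataset:
    def test_seed_reproducibility(self):
        scen = split_scenario(20_000.0)
        model = MutationModel(u=4e-8)
        a = simulate_dataset(scen, {}, model, 400, np.random.default_rng(5))
        b = simulate_dataset(scen, {}, model, 400, np.random.default_rng(5))
        assert np.array_equal(a.alignment.matrix, b.alignment.matrix)

    @pytest.mark.parametrize(
        "t_factor, check",
        [(10.0, lambda f: f > 0.7), (0.01, lambda f: abs(f) < 0.35)],
    )
    def test_split_depth_drives_phist(self, rng, t_factor, check):
        """Deep splits (t >> 4N) give ΦST near 1; shallow ones near 0."""
        N = 10_000.0
        scen = split_scenario(t_factor * 4 * N, n=5, N=N)
        model = MutationModel(u=4e-8)
        vals = []
        for _ in range(150):
            ds = simulate_dataset(scen, {}, model, 500, rng)
            d2 = sumstats.pairwise_difference_matrix(ds.alignment)
            phist = sumstats._two_level_phist(
                d2, [np.arange(5), np.arange(5, 10)]
            )
            if math.isfinite(phist):
                vals.append(phist)
        assert check(float(np.mean(vals)))


class TestInfiniteSitesNull:
    def test_watterson_expectation(self, rng):
        """E[S] = θ·a1(n) and E[k] = θ for the neutral null generator."""
        theta, n, reps = 5.0, 10, 5000
        a1 = sum(1.0 / i for i in range(1, n))
        S, K = [], []
        for _ in range(reps):
            s, k, _ = simulate_infinite_sites_stats(n, theta, rng)
            S.append(s)
            K.append(k)
        se_s = np.std(S) / math.sqrt(reps)
        se_k = np.std(K) / math.sqrt(reps)
        assert np.mean(S) == pytest.approx(theta * a1, abs=3 * se_s)
        assert np.mean(K) == pytest.approx(theta, abs=3 * se_k)

    def test_msprime_cross_check(self, rng):
        """Independent oracle: S distribution matches msprime's neutral
        single-population simulator at the same θ."""
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 4.0, 8, 1200
        ours = [simulate_infinite_sites_stats(n, theta, rng)[0] for _ in range(reps)]
        # msprime haploid: pair rate 1/N, so N = θ/2 and unit mutation rate
        # reproduce E[S] = θ·a1
        ts_reps = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=theta / 2, num_replicates=reps,
            random_seed=42,
        )
        theirs = []
        for ts in ts_reps:
            mts = msprime.sim_mutations(
                ts, rate=1.0, random_seed=int(rng.integers(1, 2**31)),
                discrete_genome=False,
            )
            theirs.append(mts.num_sites)
        _, p = sps.ks_2samp(ours, theirs)
        assert p > 0.01


def test_theta_conversion_helpers():
    assert theta_from(25_000.0, 4e-8) == pytest.approx(0.004)
    assert effective_size_from_theta(0.004, 4e-8) == pytest.approx(25_000.0)
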