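"""Priors, reference tables, scenario choice and parameter estimation."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate, stats as sps

from mesophylo import abc_select as A
from mesophylo.coalsim import DemographicScenario, Split


@pytest.fixture(scope="module")
def toy():
    """Two clearly distinct two-population scenarios plus a shared prior."""
    N = "N"
    s_recent = DemographicScenario(
        "recent", {"A": 4, "B": 4}, {"A": N, "B": N},
        (Split("t_recent", ("A", "B"), "anc", N),),
    )
    s_old = DemographicScenario(
        "old", {"A": 4, "B": 4}, {"A": N, "B": N},
        (Split("t_old", ("A", "B"), "anc", N),),
    )
    priors = A.PriorSet(
        {
            "N": A.Uniform(5e3, 5e4, "log"),
            "t_recent": A.Uniform(100.0, 3e3, "log"),
            "t_old": A.Uniform(8e4, 5e5, "log"),
            "mu": A.TruncatedGamma(4e-8, 3.2e-8, 5.8e-8),
        }
    )
    cfg = A.SimulationConfig(L=400)
    rng = np.random.default_rng(99)
    table = A.build_reference_table([s_recent, s_old], priors, 600, cfg, rng)
    return s_recent, s_old, priors, cfg, table


class TestPriors:
    def test_truncated_gamma_bounds_and_mean(self, rng):
        prior = A.TruncatedGamma(2.0e-8, 1.6e-8, 2.9e-8)
        draws = np.array([prior.sample(rng) for _ in range(10_000)])
        assert draws.min() >= 1.6e-8 and draws.max() <= 2.9e-8
        # oracle: numeric integration of the truncated density
        dist = sps.gamma(2.0, scale=1.0e-8)
        z = dist.cdf(2.9e-8) - dist.cdf(1.6e-8)
        expected_mean = integrate.quad(
            lambda x: x * dist.pdf(x), 1.6e-8, 2.9e-8
        )[0] / z
        assert prior.mean() == pytest.approx(expected_mean, rel=1e-6)
        se = draws.std() / math.sqrt(len(draws))
        assert draws.mean() == pytest.approx(expected_mean, abs=2.5 * se)

    def test_order_constraints_always_hold(self, rng):
        ps = A.PriorSet(
            {"t1": A.Uniform(0, 10), "t2": A.Uniform(0, 10)},
            order_constraints=(("t1", "t2"),),
        )
        draws = [A.sample_prior(ps, rng) for _ in range(10_000)]
        assert all(d["t1"] < d["t2"] for d in draws)

    def test_degenerate_uniform(self, rng):
        ps = A.PriorSet({"x": A.Uniform(3.0, 3.0)})
        assert all(A.sample_prior(ps, rng)["x"] == 3.0 for _ in range(100))

    def test_impossible_constraints_raise(self, rng):
        ps = A.PriorSet(
            {"a": A.Uniform(5, 6), "b": A.Uniform(0, 1)},
            order_constraints=(("a", "b"),),
        )
        with pytest.raises(RuntimeError, match="revise"):
            A.sample_prior(ps, rng, max_tries=500)

    def test_constraint_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            A.PriorSet(
                {"a": A.Uniform(0, 1), "b": A.Uniform(0, 1)},
                order_constraints=(("a", "b"), ("b", "a")),
            )


class TestReferenceTable:
    def test_balanced_rows_and_layout(self, toy):
        *_, table = toy
        assert table.n_rows == 1200
        counts = np.bincount(table.scenario_idx)
        assert list(counts) == [600, 600]
        assert len(table.stat_names) == table.stats.shape[1]

    def test_mad_scaling_normalises_columns(self, toy):
        *_, table = toy
        scaled = table.scaled()
        mads = np.median(np.abs(scaled - np.median(scaled, axis=0)), axis=0)
        varying = np.ptp(table.stats, axis=0) > 0
        np.testing.assert_allclose(mads[varying], 1.0, rtol=1e-9)

    def test_distance_invariant_to_raw_units(self, toy):
        """Rescaling a raw statistic column leaves acceptance unchanged
        because MAD scaling absorbs the units."""
        *_, table = toy
        obs = table.stats[10]
        idx1, _ = A._accepted_indices(table, obs, 0.05)
        stats2 = table.stats.copy()
        stats2[:, 0] *= 1e3
        scales2 = table.scales.copy()
        scales2[0] *= 1e3
        table2 = A.ReferenceTable(
            table.scenario_names, table.scenario_idx, table.params,
            stats2, table.stat_names, scales2,
        )
        obs2 = obs.copy()
        obs2[0] *= 1e3
        idx2, _ = A._accepted_indices(table2, obs2, 0.05)
        np.testing.assert_array_equal(np.sort(idx1), np.sort(idx2))


class TestSelectScenario:
    def test_self_selection(self, toy):
        """An actual row of scenario 'old' selects 'old' with PP ~ 1."""
        *_, table = toy
        row = np.flatnonzero(table.scenario_idx == 1)[7]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = A.select_scenario(table, table.stats[row], tolerance=10 / table.n_rows)
        assert post.scenario_names[post.selected] == "old"
        assert post.regression_pp[1] > 0.8

    def test_probabilities_sum_to_one(self, toy):
        *_, table = toy
        obs = np.median(table.stats, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = A.select_scenario(table, obs, tolerance=0.05)
        assert post.rejection_pp.sum() == pytest.approx(1.0)
        assert post.regression_pp.sum() == pytest.approx(1.0, abs=1e-6)
        assert post.ci_low <= post.regression_pp[post.selected] <= post.ci_high

    def test_accept_all_recovers_prior_frequencies(self, toy):
        """With tolerance 1 the rejection posterior equals the (balanced)
        prior scenario frequencies."""
        *_, table = toy
        obs = np.median(table.stats, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = A.select_scenario(table, obs, tolerance=1.0)
        np.testing.assert_allclose(post.rejection_pp, [0.5, 0.5], atol=1e-12)

    def test_identical_scenarios_are_symmetric(self, rng):
        """Two copies of the same scenario split the posterior ~50/50 on
        average over replicate observed draws."""
        N = "N"
        scn = DemographicScenario(
            "same", {"A": 4, "B": 4}, {"A": N, "B": N},
            (Split("t", ("A", "B"), "anc", N),),
        )
        scn2 = DemographicScenario(
            "same2", scn.samples, scn.sizes, scn.events
        )
        priors = A.PriorSet(
            {"N": A.Uniform(1e4, 3e4, "log"), "t": A.Uniform(1e4, 1e5, "log"),
             "mu": A.Uniform(3e-8, 5e-8, "log")}
        )
        cfg = A.SimulationConfig(L=300)
        table = A.build_reference_table([scn, scn2], priors, 400, cfg, rng)
        pps = []
        for row in rng.integers(0, table.n_rows, size=30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = A.select_scenario(table, table.stats[row], tolerance=0.1)
            pps.append(post.rejection_pp[0])
        assert np.mean(pps) == pytest.approx(0.5, abs=0.12)


class TestEstimateParameters:
    def test_noiseless_linear_statistic_collapses_to_truth(self):
        """When a statistic is an exact linear function of the parameter the
        regression-adjusted posterior collapses on the true value."""
        rng = np.random.default_rng(3)
        n = 500
        t = rng.uniform(1.0, 2.0, size=n)
        stats = np.column_stack([3.0 * t + 1.0, rng.normal(size=n)])
        table = A.ReferenceTable(
            ("s",), np.zeros(n, dtype=int),
            tuple({"t": float(v)} for v in t),
            stats, ("lin", "noise"), np.ones(2),
        )
        truth = 1.5
        obs = np.array([3.0 * truth + 1.0, 0.0])
        priors = A.PriorSet({"t": A.Uniform(1.0, 2.0)})
        post = A.estimate_parameters(table, obs, priors, 0, tolerance=0.2)
        assert post.samples["t"].std() < 0.02
        assert post.point["t"]["median"] == pytest.approx(truth, abs=0.02)

    def test_posterior_respects_prior_support(self, toy):
        _, s_old, priors, cfg, table = toy
        obs = table.stats[np.flatnonzero(table.scenario_idx == 1)[0]]
        post = A.estimate_parameters(table, obs, priors, 1, tolerance=0.05)
        lo, hi = priors.priors["t_old"].support
        assert post.samples["t_old"].min() >= lo
        assert post.samples["t_old"].max() <= hi
        assert post.transforms["t_old"] == "log"


class TestModelCheckPca:
    def test_table_mean_projects_near_origin(self, toy):
        *_, table = toy
        obs = table.stats.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            check = A.model_check_pca(table, obs, table.stats[:200])
        spread = np.abs(check.reference_coords).max(axis=0)
        assert np.all(np.abs(check.observed_coords) < 0.2 * spread)
        assert check.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_well_specified_observed_is_enveloped(self, toy):
        *_, table = toy
        row = 42
        obs = table.stats[row]
        same = table.stats[table.scenario_idx == table.scenario_idx[row]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            check = A.model_check_pca(table, obs, same)
        assert np.all(check.observed_percentile >= 0.5)
        assert np.all(check.observed_percentile <= 99.5)

    def test_constant_column_dropped_with_notice(self, toy):
        *_, table = toy
        stats2 = table.stats.copy()
        stats2[:, 3] = 7.0
        table2 = A.ReferenceTable(
            table.scenario_names, table.scenario_idx, table.params,
            stats2, table.stat_names, np.ones_like(table.scales),
        )
        with pytest.warns(UserWarning, match="constant"):
            check = A.model_check_pca(table2, stats2[0], stats2[:50])
        assert 3 in check.dropped_columns


class TestGenerationConversion:
    def test_study_scale_value(self):
        assert A.convert_generations_to_years(664_000, 2.0) == 1_328_000

    def test_zero_and_identity(self):
        assert A.convert_generations_to_years(0.0) == 0.0
        assert A.convert_generations_to_years(123.0, 1.0) == 123.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            A.convert_generations_to_years(-1.0)
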