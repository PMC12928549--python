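"""Tornado analysis, moment matching, PSA, CEAC and ICE-scatter checks."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from iudcea import (
    CostSet,
    DistributionSpec,
    ModelConfig,
    ParamRange,
    ParameterSet,
    ScenarioSpec,
    TransitionParams,
    UtilitySet,
    ValidationError,
    ceac,
    ice_scatter,
    moment_match,
    run_psa,
    run_scenario,
    sample_dist,
    tornado,
    wtp_grid,
)
from iudcea.sensitivity import PSADraws, _pair_icer


@pytest.fixture()
def toy_ps():
    """Two-strategy toy model with hand-computable cost and QALYs.

    No pregnancy risk. The reference never provides an IUD; the target
    provides it with certainty in the first cycle. Over 2 cycles:
    reference cost = 2 consultations, QALY = 2 x 0.8/12;
    target cost = 1 consultation + 1 insertion, QALY = (0.8 + 1.0)/12.
    """
    return ParameterSet(
        scenarios=(
            ScenarioSpec("ref", p_provision=0.0, cohort_size=1, n_professionals=0),
            ScenarioSpec("tgt", p_provision=1.0, cohort_size=1, n_professionals=0),
        ),
        transitions=TransitionParams(p_preg_no_iud=0.0, p_preg_iud=0.0),
        utilities=UtilitySet(1.0, 0.8, 0.0, 0.8),
        costs=CostSet(
            c_training_per_professional=0.0,
            c_insertion=120.0,
            c_consultation_no_iud=30.0,
            c_unintended_pregnancy=0.0,
        ),
        config=ModelConfig(n_cycles=2),
    )


def toy_icer(c_insertion, c_consultation):
    # delta cost = insertion - one consultation; delta QALY = 0.2/12
    return (c_insertion - c_consultation) / (0.2 / 12.0)


class TestTornado:
    def test_degenerate_ranges_reproduce_base_icer(self, toy_ps):
        base_icer = _pair_icer(toy_ps, "ref", "tgt")
        ranges = [
            ParamRange(p, base, base, base)
            for p, base in [
                ("costs.c_insertion", 120.0),
                ("costs.c_consultation_no_iud", 30.0),
                ("utilities.u_no_iud_no_preg", 0.8),
            ]
        ]
        rows = tornado(toy_ps, ranges, reference="ref", target="tgt")
        for row in rows:
            assert row.spread == 0.0
            assert row.icer_at_low == pytest.approx(base_icer, abs=1e-9)

    def test_two_parameter_toy_matches_hand_arithmetic(self, toy_ps):
        ranges = [
            ParamRange("costs.c_insertion", 100.0, 120.0, 150.0),
            ParamRange("costs.c_consultation_no_iud", 10.0, 30.0, 40.0),
        ]
        rows = {r.param_path: r for r in tornado(toy_ps, ranges, "ref", "tgt")}
        ins = rows["costs.c_insertion"]
        assert ins.icer_at_low == pytest.approx(toy_icer(100, 30), abs=1e-9)
        assert ins.icer_at_high == pytest.approx(toy_icer(150, 30), abs=1e-9)
        con = rows["costs.c_consultation_no_iud"]
        assert con.icer_at_low == pytest.approx(toy_icer(120, 10), abs=1e-9)
        assert con.icer_at_high == pytest.approx(toy_icer(120, 40), abs=1e-9)
        # sorted by descending spread: insertion swing 50/dE > consultation 30/dE
        assert [r.param_path for r in tornado(toy_ps, ranges, "ref", "tgt")] == [
            "costs.c_insertion",
            "costs.c_consultation_no_iud",
        ]

    def test_invalid_range_fails_before_any_model_run(self, toy_ps):
        with pytest.raises(ValidationError, match="u_no_iud_no_preg"):
            tornado(
                toy_ps,
                [ParamRange("utilities.u_no_iud_no_preg", 0.8, 0.8, 1.2)],
                "ref",
                "tgt",
            )

    def test_endpoints_bracket_base_for_monotone_parameter(self, toy_ps):
        base = _pair_icer(toy_ps, "ref", "tgt")
        (row,) = tornado(
            toy_ps, [ParamRange("costs.c_insertion", 100.0, 120.0, 150.0)], "ref", "tgt"
        )
        assert row.icer_at_low <= base <= row.icer_at_high


class TestMomentMatch:
    def test_gamma_closed_form(self):
        params = moment_match(
            DistributionSpec("costs.c_insertion", "gamma", mean=91.02, sd=9.102)
        )
        assert params["shape"] == pytest.approx(100.0)
        assert params["scale"] == pytest.approx(0.9102)

    def test_beta_recovers_moments(self):
        spec = DistributionSpec("utilities.u_no_iud_no_preg", "beta", 0.8, 0.05)
        p = moment_match(spec)
        a, b = p["alpha"], p["beta"]
        assert a / (a + b) == pytest.approx(0.8)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(0.05**2)

    def test_beta_degenerate_limit_concentrates_at_mean(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec("transitions.p_loss", "beta", 0.5, 1e-5)
        draws, n_bad = sample_dist(spec, rng, 1000)
        assert n_bad == 0
        np.testing.assert_allclose(draws, 0.5, atol=1e-3)

    def test_fixed_family_degenerate(self):
        rng = np.random.default_rng(0)
        draws, _ = sample_dist(
            DistributionSpec("utilities.u_no_iud_no_preg", "fixed", 0.8), rng, 50
        )
        assert (draws == 0.8).all()

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            moment_match(DistributionSpec("transitions.p_loss", "beta", 0.5, 0.6))

    def test_negative_mean_beta_negated_for_disutility(self):
        rng = np.random.default_rng(3)
        spec = DistributionSpec("utilities.disutility_preg_iud", "beta", -0.1, 0.02)
        draws, _ = sample_dist(spec, rng, 2000)
        assert ((-1 <= draws) & (draws <= 0)).all()
        assert draws.mean() == pytest.approx(-0.1, abs=0.002)

    def test_normal_resampling_counts_truncation(self):
        rng = np.random.default_rng(4)
        spec = DistributionSpec("costs.c_insertion", "normal", mean=5.0, sd=10.0)
        draws, n_bad = sample_dist(spec, rng, 2000)
        assert n_bad > 0
        assert (draws >= 0).all()


class TestRunPSA:
    def test_all_fixed_equals_deterministic_run(self, fixture_ps):
        dists = [
            DistributionSpec("costs.c_insertion", "fixed", 91.02),
            DistributionSpec("utilities.u_no_iud_no_preg", "fixed", 0.8),
        ]
        draws = run_psa(fixture_ps, dists, n_iter=5, seed=1)
        assert draws.n_resampled == 0
        for j, name in enumerate(draws.strategies):
            trace = run_scenario(fixture_ps, name)
            np.testing.assert_allclose(draws.costs[:, j], trace.cost_total)
            np.testing.assert_allclose(draws.effects[:, j], trace.qaly_total)

    def test_seed_reproducibility_byte_exact(self, fixture_ps):
        dists = [
            DistributionSpec("costs.c_insertion", "gamma", 91.02, 9.102),
            DistributionSpec("utilities.u_no_iud_no_preg", "beta", 0.8, 0.05),
        ]
        a = run_psa(fixture_ps, dists, n_iter=50, seed=123)
        b = run_psa(fixture_ps, dists, n_iter=50, seed=123)
        assert a.costs.tobytes() == b.costs.tobytes()
        assert a.effects.tobytes() == b.effects.tobytes()
        c = run_psa(fixture_ps, dists, n_iter=50, seed=124)
        assert a.costs.tobytes() != c.costs.tobytes()

    def test_sampled_beta_mean_within_clt_band(self, fixture_ps):
        sd = 0.05
        dists = [DistributionSpec("utilities.u_no_iud_no_preg", "beta", 0.8, sd)]
        draws = run_psa(fixture_ps, dists, n_iter=10_000, seed=9)
        sample = draws.sampled["utilities.u_no_iud_no_preg"]
        se = sd / np.sqrt(10_000)
        assert abs(sample.mean() - 0.8) < 3 * se

    def test_unknown_parameter_path_rejected(self, fixture_ps):
        with pytest.raises(KeyError):
            run_psa(fixture_ps, [DistributionSpec("costs.nope", "fixed", 1.0)], 2, 0)


def _draws_from_arrays(costs, effects, names):
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    return PSADraws(
        strategies=tuple(names),
        costs=costs,
        effects=effects,
        seed=0,
        n_iter=costs.shape[0],
    )


class TestCEAC:
    def test_single_strategy_constant_one(self):
        draws = _draws_from_arrays([[10.0]] * 4, [[1.0]] * 4, ["only"])
        curve = ceac(draws, wtp_grid())
        np.testing.assert_array_equal(curve.probability, 1.0)

    def test_identical_strategies_split_ties(self):
        draws = _draws_from_arrays(
            [[10.0, 10.0]] * 5, [[1.0, 1.0]] * 5, ["a", "b"]
        )
        curve = ceac(draws, wtp_grid())
        np.testing.assert_allclose(curve.probability, 0.5)

    def test_zero_variance_step_at_deterministic_icer(self):
        # frontier pair: ICER = (200-100)/(3-1) = 50 per QALY
        draws = _draws_from_arrays(
            [[100.0, 200.0]] * 3, [[1.0, 3.0]] * 3, ["cheap", "dear"]
        )
        grid = np.array([0.0, 49.0, 50.0, 51.0, 100.0])
        curve = ceac(draws, grid)
        np.testing.assert_array_equal(curve.probability[:, 0], [1, 1, 0.5, 0, 0])
        np.testing.assert_array_equal(curve.probability[:, 1], [0, 0, 0.5, 1, 1])

    def test_normalization_and_monotone_acceptability(self, fixture_ps):
        from iudcea import default_distributions

        draws = run_psa(fixture_ps, default_distributions(fixture_ps), 400, seed=2)
        curve = ceac(draws, wtp_grid())
        np.testing.assert_allclose(curve.probability.sum(axis=1), 1.0, atol=1e-9)
        assert ((curve.probability >= 0) & (curve.probability <= 1)).all()
        # with effectiveness ordered a.s., the most effective strategy's
        # acceptability is non-decreasing in willingness to pay
        most_effective = int(np.argmax(draws.effects.mean(axis=0)))
        if (draws.effects.argmax(axis=1) == most_effective).all():
            assert (np.diff(curve.probability[:, most_effective]) >= -1e-12).all()


class TestICEScatter:
    def test_reference_equals_target_rejected(self):
        draws = _draws_from_arrays([[1.0, 2.0]], [[1.0, 2.0]], ["a", "b"])
        with pytest.raises(ValidationError):
            ice_scatter(draws, "a", "a")

    def test_identical_copies_give_zero_cloud(self):
        draws = _draws_from_arrays(
            [[10.0, 10.0]] * 6, [[1.0, 1.0]] * 6, ["a", "b"]
        )
        scatter = ice_scatter(draws, "a", "b")
        assert (scatter.delta_e == 0).all() and (scatter.delta_c == 0).all()
        np.testing.assert_array_equal(scatter.semi_axes, 0.0)

    def test_zero_variance_single_point(self):
        draws = _draws_from_arrays(
            [[100.0, 160.0]] * 8, [[1.0, 1.5]] * 8, ["a", "b"]
        )
        scatter = ice_scatter(draws, "a", "b")
        np.testing.assert_allclose(scatter.center, [0.5, 60.0])
        assert scatter.fraction_cost_effective(wtp=200.0) == 1.0
        assert scatter.fraction_cost_effective(wtp=100.0) == 0.0

    def test_ellipse_covers_95pct_of_bivariate_normal(self):
        rng = np.random.default_rng(8)
        n = 4000
        cov = np.array([[2.0, 1.2], [1.2, 3.0]])
        pts = rng.multivariate_normal([0.3, -1.0], cov, size=n)
        effects = np.column_stack([np.zeros(n), pts[:, 0]])
        costs = np.column_stack([np.zeros(n), pts[:, 1]])
        scatter = ice_scatter(_draws_from_arrays(costs, effects, ["r", "t"]), "r", "t")
        inside = scatter.contains(scatter.delta_e, scatter.delta_c).mean()
        # binomial tolerance: 3 sigma around 0.95
        tol = 3 * np.sqrt(0.95 * 0.05 / n)
        assert abs(inside - 0.95) < tol + 0.005

    def test_ellipse_axes_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(21)
        n = 2000
        pts = rng.multivariate_normal([0, 0], [[4.0, 0.0], [0.0, 1.0]], size=n)
        effects = np.column_stack([np.zeros(n), pts[:, 0]])
        costs = np.column_stack([np.zeros(n), pts[:, 1]])
        scatter = ice_scatter(_draws_from_arrays(costs, effects, ["r", "t"]), "r", "t")
        q95 = stats.chi2.ppf(0.95, 2)
        expect = np.sqrt(np.sort(np.linalg.eigvalsh(scatter.covariance)) * q95)
        np.testing.assert_allclose(scatter.semi_axes, expect, rtol=1e-10)
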