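"""Replicator flow: closed-form oracle, conservation, equilibria, Fisher."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocontinuum import (
    FitnessModel,
    PopulationState,
    Scenario,
    constant_fitness_closed_form,
    find_equilibria,
    fitness_variance,
    lotka_volterra_rhs,
    mean_fitness,
    replicator_rhs,
    simulate,
    simulate_lv_normalized,
    validate_distribution,
)
from biocontinuum.scenarios_io import generate_random_scenario
from conftest import RPS_PAYOFF


class TestMeanFitnessAndVariance:
    @pytest.mark.parametrize(
        "p,f,expected",
        [
            ([0.5, 0.5], [1.0, 0.0], 0.5),
            ([1.0, 0.0], [3.0, 7.0], 3.0),
            ([0.2, 0.3, 0.5], [1.0, 2.0, 3.0], 2.3),
        ],
    )
    def test_weighted_average(self, p, f, expected):
        assert mean_fitness(
            validate_distribution(p), FitnessModel.constant(f)
        ) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p,f,expected",
        [
            ([0.5, 0.5], [1.0, 0.0], 0.25),
            ([0.3, 0.7], [2.0, 2.0], 0.0),
            ([0.2, 0.3, 0.5], [1.0, 2.0, 3.0], 0.61),
        ],
    )
    def test_variance(self, p, f, expected):
        var = fitness_variance(validate_distribution(p), FitnessModel.constant(f))
        assert var == pytest.approx(expected, abs=1e-12)
        assert var >= 0.0


class TestRightHandSides:
    def test_excess_fitness_times_share(self):
        rhs = replicator_rhs(
            validate_distribution([0.5, 0.5]), FitnessModel.constant([1.0, 0.0])
        )
        assert rhs == pytest.approx([0.25, -0.25])

    def test_vertex_is_fixed_point(self):
        rhs = replicator_rhs(
            validate_distribution([1.0, 0.0]), FitnessModel.constant([2.0, 5.0])
        )
        assert rhs == pytest.approx([0.0, 0.0], abs=1e-15)

    def test_neutral_fitness_gives_zero(self):
        rhs = replicator_rhs(
            validate_distribution([0.2, 0.3, 0.5]),
            FitnessModel.constant([4.0, 4.0, 4.0]),
        )
        assert rhs == pytest.approx([0.0, 0.0, 0.0], abs=1e-15)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(-3.0, 3.0), min_size=6, max_size=6),
    )
    @settings(deadline=None, max_examples=100)
    def test_shares_conserved_infinitesimally(self, raw_p, raw_f):
        p = validate_distribution(np.array(raw_p) / np.sum(raw_p))
        f = FitnessModel.constant(raw_f[: p.n])
        assert abs(replicator_rhs(p, f).sum()) < 1e-14

    @pytest.mark.parametrize(
        "P,f,expected",
        [
            ([1.0, 1.0], [1.0, 0.0], [1.0, 0.0]),
            ([2.0, 3.0], [0.0, 0.0], [0.0, 0.0]),
            ([1.0, 2.0], [1.0, 1.0], [1.0, 2.0]),
        ],
    )
    def test_lotka_volterra_componentwise_growth(self, P, f, expected):
        rhs = lotka_volterra_rhs(PopulationState(np.array(P)), FitnessModel.constant(f))
        assert rhs == pytest.approx(expected)


class TestClosedForm:
    def test_exponential_weighting_at_ln3(self):
        p = constant_fitness_closed_form(
            validate_distribution([0.5, 0.5]), np.array([1.0, 0.0]), np.log(3.0)
        )
        assert p.probs == pytest.approx([0.75, 0.25], abs=1e-14)

    def test_identity_at_t0(self):
        p0 = validate_distribution([0.2, 0.3, 0.5])
        p = constant_fitness_closed_form(p0, np.array([1.0, -2.0, 0.5]), 0.0)
        assert p.probs == pytest.approx(p0.probs, abs=1e-15)

    def test_common_growth_cancels(self):
        p0 = validate_distribution([0.3, 0.7])
        p = constant_fitness_closed_form(p0, np.array([5.0, 5.0]), 12.3)
        assert p.probs == pytest.approx(p0.probs, abs=1e-12)

    def test_stable_at_large_time(self):
        p = constant_fitness_closed_form(
            validate_distribution([0.5, 0.5]), np.array([1.0, 0.0]), 800.0
        )
        assert p.probs == pytest.approx([1.0, 0.0], abs=1e-300)


class TestSimulate:
    def test_matches_closed_form_spot_value(self):
        scen = Scenario(
            fitness=FitnessModel.constant([1.0, 0.0]),
            p0=validate_distribution([0.5, 0.5]),
            t_span=(0.0, np.log(3.0)),
            n_points=51,
        )
        traj = simulate(scen)
        assert traj.final_state().probs == pytest.approx([0.75, 0.25], abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_along_grid(self, seed):
        scen = generate_random_scenario(4, "constant", seed, t_span=(0.0, 6.0), n_points=61)
        traj = simulate(scen)
        f = scen.fitness.f_const
        exact = np.vstack(
            [constant_fitness_closed_form(scen.p0, f, t).probs for t in traj.times]
        )
        assert np.max(np.abs(traj.state_matrix() - exact)) < 1e-6

    def test_neutral_fitness_keeps_state(self):
        p0 = validate_distribution([0.2, 0.3, 0.5])
        scen = Scenario(
            fitness=FitnessModel.constant([2.0, 2.0, 2.0]),
            p0=p0,
            t_span=(0.0, 10.0),
            n_points=21,
        )
        traj = simulate(scen)
        assert np.max(np.abs(traj.state_matrix() - p0.probs)) < 1e-9

    def test_vertex_is_stationary(self):
        scen = Scenario(
            fitness=FitnessModel.constant([0.0, 4.0]),
            p0=validate_distribution([1.0, 0.0]),
            t_span=(0.0, 5.0),
            n_points=11,
        )
        traj = simulate(scen)
        assert np.max(np.abs(traj.state_matrix() - [1.0, 0.0])) < 1e-9

    @pytest.mark.parametrize("kind", ["constant", "linear-symmetric", "linear-zero-sum"])
    def test_states_stay_on_simplex(self, kind):
        for seed in range(5):
            scen = generate_random_scenario(3, kind, seed, n_points=51)
            X = simulate(scen).state_matrix()
            assert np.max(np.abs(X.sum(axis=1) - 1.0)) < 1e-8
            assert X.min() >= 0.0

    def test_monotone_fixation_of_unique_argmax(self):
        scen = generate_random_scenario(4, "constant", 11, t_span=(0.0, 4.0), n_points=101)
        f = scen.fitness.f_const
        k = int(np.argmax(f))
        assert np.sort(f)[-1] - np.sort(f)[-2] > 1e-6  # unique argmax
        pk = simulate(scen).state_matrix()[:, k]
        inside = (pk > 0) & (pk < 1)
        assert np.all(np.diff(pk)[inside[:-1]] > 0)


class TestLotkaVolterraEquivalence:
    def test_two_type_oracle(self):
        scen = Scenario(
            fitness=FitnessModel.constant([1.0, 0.0]),
            p0=validate_distribution([0.5, 0.5]),
            t_span=(0.0, np.log(3.0)),
            n_points=31,
        )
        traj = simulate_lv_normalized(scen, PopulationState(np.array([1.0, 1.0])))
        assert traj.final_state().probs == pytest.approx([0.75, 0.25], abs=1e-6)

    def test_neutral_counts_keep_normalized_state(self):
        scen = Scenario(
            fitness=FitnessModel.constant([3.0, 3.0]),
            p0=validate_distribution([0.25, 0.75]),
            t_span=(0.0, 8.0),
            n_points=21,
        )
        traj = simulate_lv_normalized(scen, PopulationState(np.array([1.0, 3.0])))
        assert np.max(np.abs(traj.state_matrix() - [0.25, 0.75])) < 1e-9

    @pytest.mark.parametrize("kind", ["constant", "linear-symmetric", "linear-zero-sum"])
    def test_matches_replicator_on_random_scenarios(self, kind, rng):
        for seed in range(3):
            scen = generate_random_scenario(3, kind, 100 + seed, n_points=51)
            P0 = PopulationState(scen.p0.probs * rng.uniform(1.0, 10.0))
            gap = np.max(
                np.abs(
                    simulate_lv_normalized(scen, P0).state_matrix()
                    - simulate(scen).state_matrix()
                )
            )
            assert gap < 1e-6

    def test_requires_consistent_initial_state(self):
        scen = Scenario(
            fitness=FitnessModel.constant([1.0, 0.0]),
            p0=validate_distribution([0.5, 0.5]),
            t_span=(0.0, 1.0),
        )
        with pytest.raises(ValueError):
            simulate_lv_normalized(scen, PopulationState(np.array([1.0, 3.0])))

    def test_long_horizon_growth_does_not_overflow(self):
        scen = Scenario(
            fitness=FitnessModel.constant([5.0, 0.0]),
            p0=validate_distribution([0.5, 0.5]),
            t_span=(0.0, 200.0),
            n_points=21,
        )
        traj = simulate_lv_normalized(scen, PopulationState(np.array([1.0, 1.0])))
        assert np.all(np.isfinite(traj.state_matrix()))
        assert traj.final_state().probs[0] == pytest.approx(1.0, abs=1e-12)


class TestEquilibria:
    def test_constant_distinct_fitness_has_only_vertices(self):
        rep = find_equilibria(FitnessModel.constant([1.0, 0.0]), 2)
        assert rep.kinds == ("vertex", "vertex")
        assert not rep.neutral
        assert max(rep.residuals) < 1e-8

    def test_rock_paper_scissors_interior(self):
        rep = find_equilibria(FitnessModel.linear(RPS_PAYOFF), 3)
        interior = [p for p, k in zip(rep.points, rep.kinds) if k == "interior"]
        assert len(interior) == 1
        assert interior[0].probs == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-12)
        assert max(rep.residuals) < 1e-8

    def test_neutral_landscape_flagged(self):
        rep = find_equilibria(FitnessModel.constant([2.0, 2.0, 2.0]), 3)
        assert rep.neutral
        assert rep.kinds == ("vertex",) * 3

    def test_singular_linear_system_flagged(self):
        rep = find_equilibria(FitnessModel.linear(np.zeros((3, 3))), 3)
        assert rep.singular
        assert rep.kinds == ("vertex",) * 3


class TestFisherFundamentalTheorem:
    def test_mean_fitness_rate_equals_variance(self):
        """d<f>/dt (central differences) equals Var(f) for constant fitness."""
        scen = Scenario(
            fitness=FitnessModel.constant([1.0, 0.3, -0.5]),
            p0=validate_distribution([0.2, 0.3, 0.5]),
            t_span=(0.0, 5.0),
            n_points=5001,
        )
        traj = simulate(scen)
        mf = traj.observables["mean_fitness"].to_numpy()
        var = traj.observables["fitness_variance"].to_numpy()
        dt = traj.times[1] - traj.times[0]
        dmf = np.gradient(mf, dt)
        assert np.max(np.abs(dmf[1:-1] - var[1:-1])) < 1e-5
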