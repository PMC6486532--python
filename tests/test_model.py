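"""Core probability mathematics: graded-response curves, generators,
transition kernels and the MET reparameterisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from irtmarkov import (
    ItemSpec,
    PopulationParams,
    SubjectEffects,
    build_generator,
    latent_severity,
    met_at_time,
    prob_at_or_above,
    rate_constants,
    stationary_distribution,
    steady_state_probs,
    transition_kernel,
)

from conftest import random_item


class TestLatentSeverity:
    @pytest.mark.parametrize(
        "d0,slope,t,expected",
        [
            (0.0, 0.0, 200.0, 0.0),
            (1.0, 0.365, 365.0, 1.365),
            (-0.5, 0.007, 182.5, -0.4965),
        ],
    )
    def test_linear_trajectory(self, d0, slope, t, expected):
        eff = SubjectEffects(d0=d0, slope=slope, eta_met=0.0)
        assert latent_severity(eff, t) == pytest.approx(expected, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            latent_severity(SubjectEffects(0, 0, 0), -1.0)


class TestGradedResponse:
    def test_probability_half_at_difficulty(self):
        item = ItemSpec(1, 2, 2.0, (0.0,))
        assert prob_at_or_above(item, 0.0) == pytest.approx([0.5])

    def test_cumulative_example(self, item3):
        np.testing.assert_allclose(
            prob_at_or_above(item3, 0.0), [0.7310585786, 0.2689414214], atol=1e-9
        )

    def test_saturation_at_extreme_severity(self, item3):
        np.testing.assert_allclose(prob_at_or_above(item3, 50.0), [1.0, 1.0], atol=1e-12)

    def test_category_probabilities_example(self, item3):
        np.testing.assert_allclose(
            steady_state_probs(item3, 0.0), [0.26894, 0.46212, 0.26894], atol=1e-5
        )

    def test_symmetry_of_symmetric_item(self, item3):
        p = steady_state_probs(item3, 0.0)
        assert p[0] == pytest.approx(p[2], abs=1e-14)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.2, 4.0),
        d=st.floats(-4.0, 4.0),
        seed=st.integers(0, 10_000),
    )
    def test_normalisation_and_nonnegativity(self, a, d, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 7))
        b = np.sort(rng.uniform(-3, 3, K - 1))
        item = ItemSpec(1, K, a, tuple(b))
        p = steady_state_probs(item, d)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_cumulative_monotone_in_severity(self, item3):
        D = np.linspace(-4, 4, 50)
        curves = np.array([prob_at_or_above(item3, d) for d in D])
        assert (np.diff(curves, axis=0) > 0).all()

    def test_difficulty_ordering_enforced(self):
        with pytest.raises(ValueError):
            ItemSpec(1, 3, 1.0, (1.0, -1.0))
        with pytest.raises(ValueError):
            ItemSpec(1, 3, -1.0, (-1.0, 1.0))


class TestRateConstants:
    def test_symmetric_two_state(self):
        up, down = rate_constants(np.array([0.5, 0.5]), met=2.0)
        assert up[0] == pytest.approx(0.25, abs=1e-14)
        assert down[0] == pytest.approx(0.25, abs=1e-14)

    def test_detailed_balance_ratio(self):
        up, down = rate_constants(np.array([0.9, 0.1]), met=1.0)
        assert up[0] == pytest.approx(0.1, abs=1e-14)
        assert down[0] == pytest.approx(0.9, abs=1e-14)

    def test_adjacent_rates_sum_to_inverse_met(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            K = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(K))
            met = float(rng.uniform(0.05, 10))
            up, down = rate_constants(p, met)
            np.testing.assert_allclose(up + down, 1.0 / met, rtol=1e-12)

    def test_nonpositive_met_rejected(self):
        with pytest.raises(ValueError):
            rate_constants(np.array([0.5, 0.5]), met=0.0)


class TestGenerator:
    def test_two_state_example(self):
        Q = build_generator(np.array([0.5, 0.5]), met=2.0)
        np.testing.assert_allclose(Q, [[-0.25, 0.25], [0.25, -0.25]], atol=1e-14)

    def test_rows_sum_to_zero_and_tridiagonal(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(5))
        Q = build_generator(p, 1.3)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert Q.shape == (5, 5)
        for i in range(5):
            for j in range(5):
                if abs(i - j) > 1:
                    assert Q[i, j] == 0.0

    def test_stationary_distribution_matches_input(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            K = int(rng.integers(2, 6))
            p = np.maximum(rng.dirichlet(np.ones(K)), 1e-12)
            p /= p.sum()
            Q = build_generator(p, float(rng.uniform(0.1, 5)))
            np.testing.assert_allclose(p @ Q, 0.0, atol=1e-12)
            np.testing.assert_allclose(stationary_distribution(Q), p, atol=1e-10)

    def test_four_category_item_has_four_states(self, small_items):
        item = small_items[1]  # K = 4
        p = steady_state_probs(item, 0.3)
        Q = build_generator(p, 2.0)
        assert Q.shape == (4, 4)


class TestTransitionKernel:
    def test_two_state_closed_form(self):
        # relaxation to equilibrium: P[0,1] = pss_1 * (1 - exp(-dt/MET))
        pss = np.array([0.5, 0.5])
        P = transition_kernel(build_generator(pss, 2.0), dt=2.0)
        assert P[0, 1] == pytest.approx(0.5 * (1 - np.exp(-1.0)), abs=1e-12)

    def test_short_time_limit_is_identity(self):
        p = np.array([0.2, 0.5, 0.3])
        P = transition_kernel(build_generator(p, 1.0), dt=1e-9)
        np.testing.assert_allclose(P, np.eye(3), atol=1e-8)

    def test_equilibrium_limit(self):
        # without probability bottlenecks every relaxation mode decays on
        # the MET scale, so 100 equilibrium times reach the stationary law
        p = np.array([0.3, 0.25, 0.25, 0.2])
        met = 0.7
        P = transition_kernel(build_generator(p, met), dt=100 * met)
        np.testing.assert_allclose(P, np.tile(p, (4, 1)), atol=1e-8)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            transition_kernel(np.zeros((2, 2)), 0.0)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            K = int(rng.integers(2, 6))
            p = np.maximum(rng.dirichlet(np.ones(K)), 1e-12)
            p /= p.sum()
            Q = build_generator(p, float(rng.uniform(0.2, 5)))
            dt1, dt2 = rng.uniform(0.1, 5, 2)
            P12 = transition_kernel(Q, dt1) @ transition_kernel(Q, dt2)
            np.testing.assert_allclose(P12, transition_kernel(Q, dt1 + dt2), atol=1e-10)

    def test_matches_ode_integration(self):
        # the kernel solves the forward probability ODEs from unit vectors
        rng = np.random.default_rng(6)
        for _ in range(10):
            item = random_item(rng)
            K = item.n_categories
            p = steady_state_probs(item, float(rng.uniform(-2, 2)))
            met = float(rng.uniform(0.3, 5))
            dt = float(rng.uniform(0.5, 4))
            Q = build_generator(np.maximum(p, 1e-12), met)
            P = transition_kernel(Q, dt)
            for r in range(K):
                sol = solve_ivp(
                    lambda t, y: y @ Q, (0, dt), np.eye(K)[r],
                    rtol=1e-10, atol=1e-12, dense_output=False,
                )
                np.testing.assert_allclose(P[r], sol.y[:, -1], atol=1e-6)


class TestMetAtTime:
    def test_linear_profile_endpoints(self):
        pop = PopulationParams(
            items=(ItemSpec(1, 3, 1.0, (-1, 1)),),
            met0=1.2,
            met_tslope=(5.1 - 1.2) / 365.0,
            met_time_mode="linear",
        )
        eff = SubjectEffects(0, 0, 0)
        assert met_at_time(pop, eff, 0.0) == pytest.approx(1.2)
        assert met_at_time(pop, eff, 365.0) == pytest.approx(5.1)

    def test_constant_mode_ignores_time(self):
        pop = PopulationParams(items=(ItemSpec(1, 3, 1.0, (-1, 1)),), met0=2.5)
        eff = SubjectEffects(0, 0, 0)
        assert met_at_time(pop, eff, 123.0) == pytest.approx(2.5)

    def test_log_deviation_doubles_met(self):
        pop = PopulationParams(items=(ItemSpec(1, 3, 1.0, (-1, 1)),), met0=2.0)
        eff = SubjectEffects(0, 0, eta_met=np.log(2.0))
        assert met_at_time(pop, eff, 10.0) == pytest.approx(4.0)

    def test_power_mode(self):
        pop = PopulationParams(
            items=(ItemSpec(1, 3, 1.0, (-1, 1)),),
            met0=1.0, met_tslope=0.5, met_time_mode="power",
        )
        assert met_at_time(pop, SubjectEffects(0, 0, 0), 3.0) == pytest.approx(2.0)

    def test_invalid_region_rejected(self):
        pop = PopulationParams(
            items=(ItemSpec(1, 3, 1.0, (-1, 1)),),
            met0=1.0, met_tslope=-0.1, met_time_mode="linear",
        )
        with pytest.raises(ValueError):
            met_at_time(pop, SubjectEffects(0, 0, 0), 50.0)

    def test_negative_time_rejected(self):
        pop = PopulationParams(items=(ItemSpec(1, 3, 1.0, (-1, 1)),), met0=1.0)
        with pytest.raises(ValueError):
            met_at_time(pop, SubjectEffects(0, 0, 0), -2.0)


def test_no_markov_limit_kernel_rows_reach_steady_state():
    rng = np.random.default_rng(7)
    for _ in range(20):
        item = random_item(rng)
        p = np.maximum(steady_state_probs(item, float(rng.uniform(-2, 2))), 1e-12)
        p /= p.sum()
        P = transition_kernel(build_generator(p, met=1e-3), dt=1.0)
        np.testing.assert_allclose(P, np.tile(p, (item.n_categories, 1)), atol=1e-6)
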