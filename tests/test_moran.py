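"""Unit and property tests for the two-type Moran chain and its solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonefix import moran
from clonefix.errors import InvalidParameterError
from clonefix.moran import (
    MoranParameters,
    exact_conditional_fixation_time,
    exact_fixation_probability,
    exact_unconditional_absorption_time,
    simulate_agentwise,
    simulate_fixation,
    simulate_trajectory,
    step_probabilities,
)

from conftest import dense_conditional_time, dense_fixation_probability


class TestStepProbabilities:
    def test_direct_substitution(self):
        # N=2, k=1, r=3: divide-mutant prob 3/4, die-mutant prob 1/2
        p_up, p_down, p_stay = step_probabilities(MoranParameters(N=2, r=3.0), 1)
        assert p_up == pytest.approx(0.375)
        assert p_down == pytest.approx(0.125)
        assert p_stay == pytest.approx(0.5)

    def test_neutral_symmetry(self):
        params = MoranParameters(N=10, r=1.0)
        for k in range(1, 10):
            p_up, p_down, _ = step_probabilities(params, k)
            assert p_up == pytest.approx(p_down) == pytest.approx(k * (10 - k) / 100)

    def test_boundaries_absorbing(self):
        params = MoranParameters(N=10, r=2.0)
        assert step_probabilities(params, 0) == (0.0, 0.0, 1.0)
        assert step_probabilities(params, 10) == (0.0, 0.0, 1.0)

    def test_out_of_range_k(self):
        with pytest.raises(InvalidParameterError):
            step_probabilities(MoranParameters(N=10, r=2.0), 11)

    @given(
        N=st.integers(2, 200),
        r=st.floats(0.1, 10.0, allow_nan=False),
        frac=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_ratio_law(self, N, r, frac):
        """p_up / p_down equals r at every interior state."""
        k = min(max(int(frac * N), 1), N - 1)
        p_up, p_down, p_stay = step_probabilities(MoranParameters(N=N, r=r), k)
        assert p_up / p_down == pytest.approx(r, rel=1e-12)
        assert 0 <= p_stay <= 1


class TestExactFixationProbability:
    @pytest.mark.parametrize("N", range(2, 51))
    def test_neutral_closed_form(self, N):
        assert exact_fixation_probability(MoranParameters(N=N, r=1.0)) == 1 / N

    @pytest.mark.parametrize(
        "N,r", [(4, 1.5), (10, 2.0), (6, 0.5), (8, 1.1), (12, 3.0)]
    )
    def test_against_dense_linear_solve(self, N, r):
        got = exact_fixation_probability(MoranParameters(N=N, r=r))
        assert got == pytest.approx(dense_fixation_probability(N, r), rel=1e-10)

    def test_known_values(self):
        assert exact_fixation_probability(MoranParameters(N=4, r=1.5)) == pytest.approx(27 / 65)
        assert exact_fixation_probability(MoranParameters(N=10, r=2.0)) == pytest.approx(
            0.50049, abs=5e-6
        )

    def test_general_initial_count(self):
        got = exact_fixation_probability(MoranParameters(N=12, r=1.3, initial_mutants=5))
        assert got == pytest.approx(dense_fixation_probability(12, 1.3, k0=5), rel=1e-10)

    def test_boundary_starts(self):
        assert exact_fixation_probability(MoranParameters(N=10, r=2.0, initial_mutants=0)) == 0.0
        assert exact_fixation_probability(MoranParameters(N=10, r=2.0, initial_mutants=10)) == 1.0

    def test_stable_for_large_N_r_near_1(self):
        p = exact_fixation_probability(MoranParameters(N=1_300_000, r=1.0000001))
        # for Ns << 1 the probability approaches 1/N from above
        assert 1 / 1_300_000 < p < 2 / 1_300_000

    def test_strictly_increasing_in_r(self):
        probs = [
            exact_fixation_probability(MoranParameters(N=100, r=r))
            for r in (0.8, 1.0, 1.05, 1.2, 1.5, 2.0, 5.0)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))


class TestExactConditionalTime:
    @pytest.mark.parametrize("r", [1.0, 1.5, 1e6])
    def test_two_state_compartment_takes_two_iterations(self, r):
        """With N=2 the conditioned chain leaves k=1 upward with prob 1/2
        per iteration regardless of r, so the mean is exactly 2."""
        assert exact_conditional_fixation_time(MoranParameters(N=2, r=r)) == pytest.approx(2.0)

    @pytest.mark.parametrize("N,r", [(6, 1.5), (10, 1.2), (15, 2.0), (8, 1.0)])
    def test_against_dense_h_transform_solve(self, N, r):
        got = exact_conditional_fixation_time(MoranParameters(N=N, r=r))
        assert got == pytest.approx(dense_conditional_time(N, r), rel=1e-8)

    def test_monotone_decreasing_in_r_increasing_in_N(self):
        grid_r = (1.05, 1.2, 1.5, 2.0)
        grid_N = (10, 50, 200)
        times = {
            (N, r): exact_conditional_fixation_time(MoranParameters(N=N, r=r))
            for N in grid_N
            for r in grid_r
        }
        for N in grid_N:
            row = [times[(N, r)] for r in grid_r]
            assert all(a > b for a, b in zip(row, row[1:]))
        for r in grid_r:
            col = [times[(N, r)] for N in grid_N]
            assert all(a < b for a, b in zip(col, col[1:]))

    def test_size_limit_redirects(self):
        with pytest.raises(InvalidParameterError, match="simulate_fixation|analytic"):
            exact_conditional_fixation_time(MoranParameters(N=5_000, r=1.5))

    def test_unconditional_smaller_for_weak_selection(self):
        """Most single founders go extinct fast, so the unconditional
        absorption time sits far below the conditional fixation time."""
        params = MoranParameters(N=100, r=1.1)
        assert exact_unconditional_absorption_time(params) < 0.5 * exact_conditional_fixation_time(params)


class TestSimulation:
    def test_trajectory_deterministic_given_seed(self):
        params = MoranParameters(N=30, r=1.4)
        assert simulate_trajectory(params, 99) == simulate_trajectory(params, 99)

    def test_boundary_start_absorbs_immediately(self):
        params = MoranParameters(N=10, r=2.0, initial_mutants=0)
        assert simulate_trajectory(params, 0) == (0, 0)

    def test_two_cells_huge_fitness_geometric_waiting(self):
        # p_up -> 1/2, p_down -> 0: fixation almost surely, ~2 iterations
        est = simulate_fixation(MoranParameters(N=2, r=1e6), 10_000, 3)
        assert est.fixation_probability > 0.999
        assert est.mean_conditional_iterations == pytest.approx(2.0, rel=0.05)

    def test_monte_carlo_matches_exact_probability(self):
        params = MoranParameters(N=10, r=2.0)
        est = simulate_fixation(params, 20_000, 11)
        exact = exact_fixation_probability(params)
        assert abs(est.fixation_probability - exact) < 3 * est.probability_se

    def test_monte_carlo_matches_exact_conditional_time(self):
        params = MoranParameters(N=20, r=1.5)
        est = simulate_fixation(params, 20_000, 12)
        exact = exact_conditional_fixation_time(params)
        assert abs(est.mean_conditional_iterations - exact) < 3 * est.iterations_se

    def test_no_fixation_warns_and_returns_none(self):
        params = MoranParameters(N=200, r=0.2)
        with pytest.warns(RuntimeWarning, match="no replicate"):
            est = simulate_fixation(params, 20, 4)
        assert est.mean_conditional_iterations is None
        assert est.fixation_probability == 0.0


class TestAgentwise:
    def test_size_limit(self):
        with pytest.raises(InvalidParameterError):
            simulate_agentwise(MoranParameters(N=1000, r=1.5), 0)

    def test_matches_chain_reduction_fixation_frequency(self):
        """Literal N-cell simulation and the k-chain agree distributionally."""
        params = MoranParameters(N=8, r=1.5)
        n = 3_000
        rng = np.random.default_rng(21)
        agent = np.array([simulate_agentwise(params, rng)[0] == 8 for _ in range(n)])
        exact = exact_fixation_probability(params)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(agent.mean() - exact) < 3 * se

    def test_neutral_interchangeable(self):
        params = MoranParameters(N=8, r=1.0)
        n = 3_000
        rng = np.random.default_rng(22)
        freq = np.mean([simulate_agentwise(params, rng)[0] == 8 for _ in range(n)])
        se = np.sqrt((1 / 8) * (7 / 8) / n)
        assert abs(freq - 1 / 8) < 3 * se


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 1, "r": 1.5},
            {"N": 10, "r": 0.0},
            {"N": 10, "r": -1.0},
            {"N": 10, "r": 1.5, "division_rate": 0.0},
            {"N": 10, "r": 1.5, "initial_mutants": 11},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            MoranParameters(**kwargs)
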