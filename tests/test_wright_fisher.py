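"""Unit and property tests for the spectral machinery and the discrete oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from pgsturnover import (
    DiscreteWrightFisher,
    PopGenParams,
    conditional_poly_moment,
    eigenvalue,
    joint_expectation,
    orthonormal_polynomials,
    stationary_moment,
)
from pgsturnover.wright_fisher import (
    MAX_ORACLE_TWO_N,
    UnsupportedConfigurationError,
    propagate_polynomial,
    weighted_frequency_moment,
)

A_VALUES = st.floats(min_value=1e-4, max_value=5.0)


class TestPopGenParams:
    def test_from_scaled_round_trips_a(self):
        params = PopGenParams.from_scaled(0.37, two_N=1234)
        assert params.a == pytest.approx(0.37)

    def test_rejects_nonpositive_population(self):
        with pytest.raises(ValueError):
            PopGenParams(two_N=0, mu=1e-4, nu=1e-4)

    def test_rejects_invalid_mutation_rate(self):
        with pytest.raises(ValueError):
            PopGenParams(two_N=100, mu=1.5, nu=1e-4)

    def test_asymmetric_mutation_has_no_scaled_rate(self):
        params = PopGenParams(two_N=100, mu=1e-3, nu=2e-3)
        with pytest.raises(UnsupportedConfigurationError):
            _ = params.a


class TestStationaryMoments:
    def test_matches_scipy_beta(self, small_params):
        a = small_params.a
        assert stationary_moment(small_params, 1) == pytest.approx(
            beta_dist.mean(a, a)
        )
        assert stationary_moment(small_params, 2) == pytest.approx(
            beta_dist.moment(2, a, a)
        )

    def test_mixed_moment_is_half_expected_heterozygosity(self, small_params):
        a = small_params.a
        assert stationary_moment(small_params, 1, 1) == pytest.approx(
            0.5 * a / (2 * a + 1)
        )

    def test_rejects_negative_order(self, small_params):
        with pytest.raises(ValueError):
            stationary_moment(small_params, -1)

    def test_asymmetric_raises(self):
        params = PopGenParams(two_N=100, mu=1e-3, nu=2e-3)
        with pytest.raises(UnsupportedConfigurationError):
            stationary_moment(params, 1)


class TestSpectrum:
    def test_eigenvalue_closed_forms(self, small_params):
        a = small_params.a
        assert eigenvalue(small_params, 0) == 0.0
        assert eigenvalue(small_params, 1) == pytest.approx(a)
        assert eigenvalue(small_params, 2) == pytest.approx(1.0 + 2.0 * a)

    @settings(deadline=None, derandomize=True)
    @given(a=A_VALUES)
    def test_polynomials_are_orthonormal(self, a):
        params = PopGenParams.from_scaled(a, two_N=500)
        terms = orthonormal_polynomials(params)
        m = np.array([stationary_moment(params, j) for j in range(5)])
        for i, ti in enumerate(terms):
            for j, tj in enumerate(terms):
                idx = np.add.outer(
                    np.arange(ti.poly_coeffs.size), np.arange(tj.poly_coeffs.size)
                )
                inner = np.sum(np.outer(ti.poly_coeffs, tj.poly_coeffs) * m[idx])
                assert inner == pytest.approx(1.0 if i == j else 0.0, abs=1e-9)

    def test_propagation_at_tau_zero_is_identity(self, small_params):
        poly = [0.5, -1.0, 2.0]
        out = propagate_polynomial(small_params, poly, 0.0)
        assert out == pytest.approx(np.array(poly), abs=1e-12)

    def test_propagation_limit_is_stationary_mean(self, small_params):
        poly = [0.0, 1.0, 1.0]
        target = stationary_moment(small_params, 1) + stationary_moment(small_params, 2)
        assert conditional_poly_moment(small_params, poly, 0.9, 2000.0) == pytest.approx(
            target
        )

    def test_mean_decays_at_rate_a(self, small_params):
        a, tau, z0 = small_params.a, 0.7, 0.9
        expected = 0.5 + (z0 - 0.5) * np.exp(-a * tau)
        assert conditional_poly_moment(small_params, [0.0, 1.0], z0, tau) == pytest.approx(
            expected
        )

    def test_degree_three_rejected(self, small_params):
        with pytest.raises(UnsupportedConfigurationError):
            propagate_polynomial(small_params, [0.0, 0.0, 0.0, 1.0], 0.1)

    def test_negative_tau_rejected(self, small_params):
        with pytest.raises(ValueError):
            propagate_polynomial(small_params, [1.0], -0.1)

    def test_accepts_numpy_polynomial_objects(self, small_params):
        poly = np.polynomial.Polynomial([0.0, 1.0, -1.0])
        direct = conditional_poly_moment(small_params, [0.0, 1.0, -1.0], 0.3, 0.2)
        assert conditional_poly_moment(small_params, poly, 0.3, 0.2) == pytest.approx(
            direct
        )


class TestAgainstDiscreteOracle:
    """Spectral results vs dense-chain matrix computations at O(1/N) tolerance."""

    @pytest.mark.parametrize("a", [0.02, 0.2])
    @pytest.mark.parametrize("tau", [0.1, 0.5])
    def test_conditional_moment_matches_chain(self, a, tau):
        two_N = 300
        params = PopGenParams.from_scaled(a, two_N)
        chain = DiscreteWrightFisher(two_N, params.mu, params.mu)
        het = chain.grid * (1 - chain.grid)
        oracle = chain.conditional_expectation(het, chain.generations_for_tau(tau))
        for z0_idx in (30, 150, 290):
            analytic = conditional_poly_moment(
                params, [0.0, 1.0, -1.0], chain.grid[z0_idx], tau
            )
            assert analytic == pytest.approx(
                float(oracle[z0_idx]), rel=0.02 * (2000 / two_N)
            )

    def test_joint_expectation_matches_chain_both_time_directions(self):
        # E[w(D) f(Z_tau)] with D in the present and Z_tau in the past equals,
        # under the reversible stationary diffusion, the same expectation with
        # the roles of the two time points swapped.  The discrete chain is
        # reversible only up to O(1/N), so both orderings are computed from
        # the chain and all three values compared at the O(1/N) tolerance.
        two_N, n, d, tau, a = 300, 100, 10, 0.3, 0.1
        params = PopGenParams.from_scaled(a, two_N)
        chain = DiscreteWrightFisher(two_N, params.mu, params.mu)
        pi = chain.stationary_distribution()
        gens = chain.generations_for_tau(tau)

        from scipy.stats import binom

        D = np.arange(2 * n + 1)
        w = ((D <= d) | (D >= 2 * n - d)).astype(float)
        # E[w(D) | z] for every grid state
        w_of_z = binom.pmf(D[None, :], 2 * n, chain.grid[:, None]) @ w
        het = chain.grid * (1 - chain.grid)

        # forward: condition on the past state, propagate to the present
        het_to_w = chain.conditional_expectation(w_of_z, gens)
        oracle_fwd = float(pi @ (het * het_to_w))
        # backward: condition on the present state, propagate into the past
        w_to_het = chain.conditional_expectation(het, gens)
        oracle_bwd = float(pi @ (w_of_z * w_to_het))

        tol = 0.02 * (2000 / two_N)
        assert oracle_fwd == pytest.approx(oracle_bwd, rel=tol)
        analytic = joint_expectation(params, n, w, [0.0, 1.0, -1.0], tau)
        assert analytic == pytest.approx(oracle_fwd, rel=tol)
        assert analytic == pytest.approx(oracle_bwd, rel=tol)

    def test_stationary_distribution_is_fixed_point(self):
        chain = DiscreteWrightFisher(200, 2e-4, 2e-4)
        pi = chain.stationary_distribution()
        assert pi @ chain.transition_matrix == pytest.approx(pi, abs=1e-12)

    def test_transition_rows_are_distributions(self):
        chain = DiscreteWrightFisher(150, 1e-3, 5e-4, s=0.01)
        T = chain.transition_matrix
        assert np.all(T >= 0)
        assert T.sum(axis=1) == pytest.approx(np.ones(151))

    def test_selection_shifts_expected_frequency_up(self):
        neutral = DiscreteWrightFisher(100, 1e-4, 1e-4)
        selected = DiscreteWrightFisher(100, 1e-4, 1e-4, s=0.05)
        z = np.array([0.2, 0.5, 0.8])
        assert np.all(
            selected.expected_offspring_frequency(z)
            > neutral.expected_offspring_frequency(z)
        )

    def test_oracle_size_guard(self):
        with pytest.raises(ValueError):
            DiscreteWrightFisher(MAX_ORACLE_TWO_N + 1, 1e-4, 1e-4)


class TestWeightedFrequencyMoment:
    def test_matches_betabinom_pmf_sum(self, small_params):
        from scipy.stats import betabinom

        n, a = 30, small_params.a
        rng = np.random.default_rng(7)
        w = rng.uniform(size=2 * n + 1)
        d = np.arange(2 * n + 1)
        pmf = betabinom.pmf(d, 2 * n, a, a)
        for j in (0, 1, 2):
            # E[w(D) Z^j] = sum_d w_d pmf_d E[Z^j | D = d] with the beta
            # posterior mean of Z^j given D
            post = np.ones_like(pmf)
            for i in range(j):
                post *= (a + d + i) / (2 * a + 2 * n + i)
            brute = float(np.sum(w * pmf * post))
            assert weighted_frequency_moment(small_params, n, w, j) == pytest.approx(
                brute
            )

    def test_all_ones_weight_gives_raw_moment(self, small_params):
        n = 25
        w = np.ones(2 * n + 1)
        for j in (0, 1, 2):
            assert weighted_frequency_moment(small_params, n, w, j) == pytest.approx(
                stationary_moment(small_params, j)
            )

    def test_zero_weight_is_zero(self, small_params):
        assert weighted_frequency_moment(small_params, 10, np.zeros(21), 1) == 0.0

    def test_wrong_length_rejected(self, small_params):
        with pytest.raises(ValueError):
            weighted_frequency_moment(small_params, 10, np.ones(20), 1)


class TestJointExpectation:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=A_VALUES, tau=st.floats(min_value=0.0, max_value=2.0))
    def test_unit_weight_reduces_to_stationary_moment(self, a, tau):
        # with w = 1, E[f(Z_tau)] is tau-independent by stationarity
        params = PopGenParams.from_scaled(a, two_N=500)
        n = 20
        got = joint_expectation(params, n, np.ones(2 * n + 1), [0.0, 1.0, -1.0], tau)
        expected = stationary_moment(params, 1) - stationary_moment(params, 2)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_factorizes_in_the_long_time_limit(self, small_params):
        # as tau -> inf, D and Z_tau decorrelate
        n = 20
        w = np.zeros(2 * n + 1)
        w[:5] = 1.0
        got = joint_expectation(small_params, n, w, [0.0, 1.0], 500.0)
        expected = weighted_frequency_moment(small_params, n, w, 0) * stationary_moment(
            small_params, 1
        )
        assert got == pytest.approx(expected, rel=1e-9)
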