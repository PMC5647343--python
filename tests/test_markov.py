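"""Origin-fixation chain: fixation kernels, stationary structure, N_crit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftscape import (
    FixationKind,
    FixationModel,
    MarkovLandscapeSpec,
    TransitionMatrix,
    build_transition_matrix,
    dfe_mutation_rates,
    fixation_probability,
    fixation_ratio,
    n_crit_closed,
    n_crit_numeric,
    occupancy_ratio,
    stationary_distribution,
)
from driftscape.markov import flux_ratio, log_occupancy_ratio

from .conftest import wright_fisher_fixation_frequency

KINDS = [FixationKind.kimura, FixationKind.sella_hirsh]


class TestFixationProbability:
    @pytest.mark.parametrize("kind", KINDS)
    def test_neutral_limit_is_one_over_N(self, kind):
        assert fixation_probability(0.0, FixationModel(kind, 10)) == pytest.approx(0.1)
        # continuity: a tiny effect lands on the neutral limit
        assert fixation_probability(1e-13, FixationModel(kind, 10)) == pytest.approx(0.1)
        assert fixation_probability(1e-9, FixationModel(kind, 10)) == pytest.approx(0.1, rel=1e-6)

    @pytest.mark.parametrize("kind", KINDS)
    @pytest.mark.parametrize("s_eff", [-0.5, 0.0, 0.3])
    def test_sole_individual_always_fixes(self, kind, s_eff):
        assert fixation_probability(s_eff, FixationModel(kind, 1)) == 1.0

    def test_kimura_value_against_wright_fisher_oracle(self):
        """Diffusion result vs a 2e5-trial Wright-Fisher simulation."""
        pi = fixation_probability(0.1, FixationModel(FixationKind.kimura, 10))
        assert pi == pytest.approx(0.20963, abs=1e-4)  # frozen analytic value
        trials = 200_000
        freq = wright_fisher_fixation_frequency(0.1, 10, trials=trials, seed=7)
        sigma = math.sqrt(pi * (1 - pi) / trials)
        assert abs(freq - pi) < 3 * sigma + 0.001  # diffusion approximation slack

    def test_nonviable_mutant_rejected(self):
        with pytest.raises(ValueError):
            fixation_probability(-1.0, FixationModel(FixationKind.kimura, 10))

    def test_deleterious_underflow_is_zero_not_error(self):
        assert fixation_probability(-0.5, FixationModel(FixationKind.kimura, 1e6)) == 0.0


class TestFixationRatio:
    @pytest.mark.parametrize("kind", KINDS)
    def test_matches_exponential_identity(self, kind):
        # pi_ij / pi_ji = e^{2 s (N-1)}, the detailed-balance ratio
        for s_eff, N in [(0.05, 11), (0.1, 47.05), (0.02, 3), (0.3, 2)]:
            expected = math.exp(2 * s_eff * (N - 1))
            assert fixation_ratio(s_eff, FixationModel(kind, N)) == pytest.approx(
                expected, rel=1e-10
            )

    def test_half_peak_step_gives_paper_ratio(self):
        # a step of size s/2 has ratio e^{s (N-1)}
        s, N = 0.1, 21
        assert fixation_ratio(s / 2, FixationModel("kimura", N)) == pytest.approx(
            math.exp(s * (N - 1)), rel=1e-10
        )

    def test_neutral_ratio_is_one(self):
        assert fixation_ratio(0.0, FixationModel("kimura", 10)) == 1.0

    def test_explicit_e_value(self):
        # s=0.05, N=11: e^{2*0.05*10} = e
        assert fixation_ratio(0.05, FixationModel("sella_hirsh", 11)) == pytest.approx(
            math.e, rel=1e-10
        )


class TestMutationRates:
    def test_kappa_and_flux_ratio(self, minimal_spec):
        assert minimal_spec.kappa == pytest.approx(0.01)
        rates = dfe_mutation_rates(minimal_spec)
        assert flux_ratio(minimal_spec, rates) == pytest.approx(0.01, rel=1e-12)

    def test_rate_ordering(self, minimal_spec):
        rates = dfe_mutation_rates(minimal_spec)
        u_robust = rates[(0, 3)]
        u_fragile = rates[(0, 1)]
        assert u_robust < u_fragile < minimal_spec.mu

    def test_mu_cancels_in_flux_ratio(self):
        # M depends on u_b/s_bar only, not on the overall rate mu
        for mu in (1e-3, 1e-2, 0.2):
            spec = MarkovLandscapeSpec(s=0.1, epsilon=0.05, n=2, u_b=1e-3, s_bar=0.1, mu=mu)
            assert flux_ratio(spec) == pytest.approx(0.01, rel=1e-12)

    def test_extended_model_flux_is_kappa_power(self):
        spec = MarkovLandscapeSpec(s=0.2, epsilon=0.05, n=5, u_b=1e-3, s_bar=0.1, mu=0.01)
        assert flux_ratio(spec) == pytest.approx(spec.kappa**4, rel=1e-12)

    def test_degenerate_equal_rates_give_unit_flux(self, minimal_spec):
        mu = minimal_spec.mu
        rates = {edge: mu for edge in dfe_mutation_rates(minimal_spec)}
        assert flux_ratio(minimal_spec, rates) == pytest.approx(1.0)

    def test_kappa_at_least_one_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            MarkovLandscapeSpec(s=0.1, epsilon=0.05, n=2, u_b=0.2, s_bar=0.1, mu=0.01)


class TestTransitionMatrix:
    def test_minimal_model_sparsity_pattern(self, minimal_spec):
        T = build_transition_matrix(minimal_spec, FixationModel("kimura", 20)).T
        # states: wild, fragile_1, fragile_2 (top), robust
        for i, j in [(0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)]:
            assert T[i, j] == 0.0

    @pytest.mark.parametrize("kind", KINDS)
    def test_rows_sum_to_one(self, minimal_spec, kind):
        T = build_transition_matrix(minimal_spec, FixationModel(kind, 35)).T
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_neutral_chain_has_uniform_stationary(self):
        edges = {}
        for i in range(3):
            edges[(i, i + 1)] = (0.01, 0.0)
            edges[(i + 1, i)] = (0.01, 0.0)
        T = TransitionMatrix.from_edges(["a", "b", "c", "d"], edges, FixationModel("kimura", 10))
        x = stationary_distribution(T).x_star
        np.testing.assert_allclose(x, 0.25, atol=1e-12)

    def test_excessive_rates_rejected(self):
        edges = {(0, 1): (2.0, 0.0), (1, 0): (0.01, 0.0)}
        with pytest.raises(ValueError, match="leave"):
            TransitionMatrix.from_edges(["a", "b"], edges, FixationModel("kimura", 1))

    def test_reducible_chain_rejected(self):
        T = np.eye(3)
        with pytest.raises(ValueError):
            stationary_distribution(TransitionMatrix(states=["a", "b", "c"], T=T))


@st.composite
def random_specs(draw):
    # scales chosen so fixation probabilities stay within double-precision
    # range at the N values drawn below (2*N*s <= ~25); larger exponents are
    # exercised through the log-space cycle product in TestCriticalSize
    s = draw(st.floats(0.05, 0.25))
    epsilon = draw(st.floats(0.005, 0.9)) * s
    n = draw(st.integers(2, 6))
    u_b = draw(st.floats(1e-5, 5e-3))
    s_bar = draw(st.floats(0.05, 0.3))
    mu = draw(st.floats(1e-3, 0.05))
    spec = MarkovLandscapeSpec(s=s, epsilon=epsilon, n=n, u_b=u_b, s_bar=s_bar, mu=mu)
    return spec


class TestStationaryProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(spec=random_specs(), N=st.floats(1.5, 50), kind=st.sampled_from(KINDS))
    def test_stationarity_and_reversibility(self, spec, N, kind):
        """x* is stationary, and the peak ratio matches detailed balance."""
        model = FixationModel(kind, N)
        T = build_transition_matrix(spec, model)
        res = stationary_distribution(T)
        assert res.x_star.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(res.x_star @ T.T - res.x_star)) < 1e-10
        # tree-structured chain is reversible: eigenvector ratio equals the
        # independent log-space cycle product
        r_eig = occupancy_ratio(res)
        r_prod = math.exp(log_occupancy_ratio(spec, kind, N))
        assert r_eig == pytest.approx(r_prod, rel=1e-8)

    def test_R_increases_in_N_and_crosses_once(self, minimal_spec):
        M = flux_ratio(minimal_spec)
        ncrit = n_crit_numeric(minimal_spec)
        grid = np.linspace(1, 2 * ncrit, 41)
        logR = [log_occupancy_ratio(minimal_spec, "kimura", N) for N in grid]
        assert logR[0] == pytest.approx(math.log(M), rel=1e-12)  # R(1) = M
        assert np.all(np.diff(logR) > 0)
        signs = np.sign(logR)
        assert np.count_nonzero(np.diff(signs)) == 1  # exactly one crossing


class TestCriticalSize:
    def test_closed_form_value(self):
        assert n_crit_closed(0.01, 0.1, 2) == pytest.approx(1 + math.log(100) / 0.2)
        assert n_crit_closed(0.01, 0.1, 2) == pytest.approx(24.0259, abs=1e-4)

    def test_linear_in_steps(self):
        base = n_crit_closed(0.01, 0.1, 2) - 1
        assert n_crit_closed(0.01, 0.1, 3) - 1 == pytest.approx(2 * base)
        spec2 = MarkovLandscapeSpec(s=0.5, epsilon=0.1, n=2, u_b=1e-3, s_bar=0.1, mu=0.01)
        spec5 = MarkovLandscapeSpec(s=0.5, epsilon=0.1, n=5, u_b=1e-3, s_bar=0.1, mu=0.01)
        assert n_crit_numeric(spec5) - 1 == pytest.approx(4 * (n_crit_numeric(spec2) - 1), rel=1e-5)

    def test_large_epsilon_limit(self):
        assert n_crit_closed(0.01, 1e6, 2) == pytest.approx(1.0, abs=1e-5)

    def test_numeric_matches_closed_form(self):
        spec = MarkovLandscapeSpec(s=0.5, epsilon=0.1, n=2, u_b=1e-3, s_bar=0.1, mu=0.01)
        nc = n_crit_closed(0.01, 0.1, 2)
        for kind in KINDS:
            assert n_crit_numeric(spec, kind) == pytest.approx(nc, rel=1e-6)

    def test_kernels_agree(self):
        spec = MarkovLandscapeSpec(s=0.3, epsilon=0.07, n=3, u_b=5e-4, s_bar=0.08, mu=0.02)
        a = n_crit_numeric(spec, "kimura")
        b = n_crit_numeric(spec, "sella_hirsh")
        assert a == pytest.approx(b, rel=1e-6)

    def test_no_crossing_when_flux_ratio_exceeds_one(self, minimal_spec):
        rates = {edge: minimal_spec.mu for edge in dfe_mutation_rates(minimal_spec)}
        assert flux_ratio(minimal_spec, rates) == 1.0
        with pytest.raises(ValueError):
            n_crit_closed(1.0, 0.1, 2)

    def test_occupancy_ratio_is_M_at_N_1(self, minimal_spec):
        T = build_transition_matrix(minimal_spec, FixationModel("kimura", 1))
        R = occupancy_ratio(stationary_distribution(T))
        assert R == pytest.approx(flux_ratio(minimal_spec), rel=1e-8)


def test_solve_landscape_populates_all_diagnostics(minimal_spec):
    from driftscape import solve_landscape

    res = solve_landscape(minimal_spec, FixationModel("kimura", 30))
    assert res.M == pytest.approx(0.01, rel=1e-12)
    assert res.N_crit_closed == pytest.approx(res.N_crit_numeric, rel=1e-6)
    assert res.R == pytest.approx(
        res.M * math.exp(2 * minimal_spec.epsilon * 29), rel=1e-8
    )
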