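"""Collective-state layer: Dicke operators vs brute force, occupation law,
theta parameterization and the su(2)->e(2) contraction diagnostic."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from laterality.population import (
    InteractionSpec,
    collective_operators,
    contraction_residual,
    asymmetry_measure,
    interaction_energy,
    make_population_state,
    occupation_distribution,
    occupation_probability,
    theta_from_fractions,
)


def full_space_collective(n):
    """Brute-force oracle: S+/-, S3 and the symmetric states in the 2^n product space.

    Bit i set in a basis index means unit i is in |R>.  Returns the Dicke-sector
    matrix elements of the summed single-unit ladder operators together with
    the symmetrized basis built explicitly from itertools combinations.
    """
    dim = 1 << n
    s_plus_full = np.zeros((dim, dim))
    for s in range(dim):
        for i in range(n):
            if not (s >> i) & 1:
                s_plus_full[s | (1 << i), s] += 1.0
    pop = np.array([bin(s).count("1") for s in range(dim)])
    sym = np.zeros((dim, n + 1))
    for ell in range(n + 1):
        for bits in itertools.combinations(range(n), ell):
            sym[sum(1 << b for b in bits), ell] = 1.0
        sym[:, ell] /= np.linalg.norm(sym[:, ell])
    s_plus = sym.T @ s_plus_full @ sym
    s_3 = sym.T @ np.diag(pop - n / 2) @ sym
    return s_plus, s_plus.T, s_3, sym


class TestPopulationState:
    @pytest.mark.parametrize(
        "n,ell,m,x",
        [(2, 1, 0.0, 1.0), (10, 7, 2.0, 3 / 7), (100, 60, 10.0, 40 / 60)],
    )
    def test_counts_order_parameter_and_ratio(self, n, ell, m, x):
        state = make_population_state(n, ell)
        assert state.n_right == ell and state.n_left == n - ell
        assert asymmetry_measure(state) == m
        assert state.ratio == pytest.approx(x, abs=1e-12)

    def test_ratio_flagged_undefined_without_r_units(self):
        state = make_population_state(5, 0)
        assert not state.has_ratio
        with pytest.raises(ValueError, match="undefined"):
            state.ratio

    def test_out_of_range_ell_rejected(self):
        with pytest.raises(ValueError):
            make_population_state(5, 6)
        with pytest.raises(ValueError):
            make_population_state(5, -1)

    def test_both_closed_forms_of_m_agree_exhaustively(self):
        # M = ell - N/2 versus M = (1/2) N_R (1 - X), all interior ell at N = 25
        n = 25
        for ell in range(1, n + 1):
            state = make_population_state(n, ell)
            m = asymmetry_measure(state)
            assert m == pytest.approx(0.5 * ell * (1.0 - state.ratio), abs=1e-10)
            assert m == ell - n / 2

    def test_state_is_s3_eigenvector(self):
        n, ell = 12, 8
        state = make_population_state(n, ell)
        ops = collective_operators(n)
        assert np.allclose(
            ops.s_3 @ state.amplitudes, (ell - n / 2) * state.amplitudes, atol=1e-12
        )


class TestCollectiveOperators:
    @pytest.mark.parametrize("n", [2, 4, 7, 10])
    def test_dicke_elements_match_brute_force_product_space(self, n):
        sp_oracle, sm_oracle, s3_oracle, _ = full_space_collective(n)
        ops = collective_operators(n)
        assert np.allclose(ops.s_plus, sp_oracle, atol=1e-10)
        assert np.allclose(ops.s_minus, sm_oracle, atol=1e-10)
        assert np.allclose(ops.s_3, s3_oracle, atol=1e-10)

    def test_symmetrized_embedding_at_n4(self):
        # |ell> equals the normalized sum over all (4 choose ell) arrangements
        n = 4
        _, _, _, sym = full_space_collective(n)
        for ell in range(n + 1):
            state = make_population_state(n, ell)
            embedded = sym @ state.amplitudes.real
            count = np.count_nonzero(embedded)
            assert count == len(list(itertools.combinations(range(n), ell)))
            assert np.isclose(np.linalg.norm(embedded), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n", [5, 20])
    def test_su2_commutators_exact(self, n):
        ops = collective_operators(n)
        sp, sm, s3 = ops.s_plus, ops.s_minus, ops.s_3
        assert np.allclose(s3 @ sp - sp @ s3, sp, atol=1e-10)
        assert np.allclose(s3 @ sm - sm @ s3, -sm, atol=1e-10)
        assert np.allclose(sp @ sm - sm @ sp, 2.0 * s3, atol=1e-10)

    def test_ladder_shifts_m_by_one(self):
        n, ell = 9, 4
        ops = collective_operators(n)
        state = make_population_state(n, ell)
        up = ops.s_plus @ state.amplitudes
        up /= np.linalg.norm(up)
        assert np.allclose(ops.s_3 @ up, (ell + 1 - n / 2) * up, atol=1e-12)


class TestOccupationLaw:
    def test_printed_values(self):
        assert occupation_probability(0.0, 0) == 1.0
        theta_half = float(np.arctanh(np.sqrt(0.5)))  # tanh^2 theta = 1/2
        for x in range(4):
            assert occupation_probability(theta_half, x) == pytest.approx(
                0.5 ** (x + 1), abs=1e-12
            )

    @given(st.floats(min_value=0.01, max_value=4.0))
    def test_distribution_normalizes_and_is_a_probability(self, theta):
        t2 = np.tanh(theta) ** 2
        x_max = max(10, int(np.ceil(np.log(1e-11) / np.log(t2))))
        w = occupation_distribution(theta, x_max)
        assert np.all(w > 0) and np.all(w < 1)
        assert abs(w.sum() - 1.0) < 1e-10

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            occupation_probability(0.3, -1)


class TestThetaParameterization:
    def test_balanced_composition_closed_form(self):
        theta = theta_from_fractions(5, 10)
        assert theta == pytest.approx(np.arctanh(np.sqrt(0.5)), abs=1e-12)
        assert np.sinh(theta) ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_small_fraction_limit(self):
        assert theta_from_fractions(1, 10**6) < 2e-3

    @given(st.integers(min_value=2, max_value=10_000), st.data())
    def test_round_trip_ratio(self, n, data):
        n_left = data.draw(st.integers(min_value=1, max_value=n - 1))
        theta = theta_from_fractions(n_left, n)
        assert np.sinh(theta) ** 2 == pytest.approx(n_left / (n - n_left), rel=1e-10)

    @pytest.mark.parametrize("n_left", [0, 10])
    def test_boundaries_excluded(self, n_left):
        with pytest.raises(ValueError, match="excluded"):
            theta_from_fractions(n_left, 10)


class TestContraction:
    def test_residual_shrinks_with_population_size(self):
        assert contraction_residual(200, 101) < contraction_residual(20, 11)

    def test_residual_scales_as_inverse_n(self):
        sizes = np.array([20, 40, 80, 160])
        resid = np.array([contraction_residual(n, n // 2 + 1) for n in sizes])
        slope = np.polyfit(np.log(sizes), np.log(resid), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_rotation_generator_untouched(self):
        # [S3, S+/-] = +/- S+/- holds at any N: e(2) keeps the rotation plus
        # two translations, preserving the three-parameter structure
        ops = collective_operators(20)
        assert np.allclose(ops.s_3 @ ops.s_plus - ops.s_plus @ ops.s_3, ops.s_plus, atol=1e-10)

    def test_translation_action_up_to_sqrt_factors(self):
        # S+/- realize N_R -> N_R +/- 1 (N_L the opposite) on the Dicke basis
        n, ell = 30, 17
        ops = collective_operators(n)
        state = make_population_state(n, ell)
        moved = ops.s_plus @ state.amplitudes
        assert np.flatnonzero(np.abs(moved) > 1e-12).tolist() == [ell + 1]
        assert np.linalg.norm(moved) == pytest.approx(
            np.sqrt((n - ell) * (ell + 1)), abs=1e-10
        )

    def test_window_must_fit_in_basis(self):
        with pytest.raises(ValueError, match="window"):
            contraction_residual(10, 1, window=11)


class TestInteraction:
    def test_zero_amplitude_gives_zero_energy(self):
        spec = InteractionSpec(lam=2.0, b_amp=0.0)
        state = make_population_state(8, 4)
        assert interaction_energy(spec, state).value == 0.0

    def test_expectation_real_for_superposition(self, rng):
        n = 6
        amp = rng.normal(size=n + 1) + 1j * rng.normal(size=n + 1)
        amp /= np.linalg.norm(amp)
        from laterality.population import PopulationState

        state = PopulationState(n=n, ell=3, amplitudes=amp)
        res = interaction_energy(InteractionSpec(lam=1.3, b_amp=0.7 + 0.2j), state)
        assert np.isfinite(res.value)

    def test_collective_matrix_elements_scale_linearly_in_n(self):
        # strong-coupling regime: max element of (S+ + S-) doubles from N=20 to 40
        def peak(n):
            ops = collective_operators(n)
            return np.max(np.abs(ops.s_plus + ops.s_minus))

        assert peak(40) / peak(20) == pytest.approx(2.0, rel=0.05)

    def test_coupling_scale_reporting(self):
        spec = InteractionSpec(lam=0.5)
        state = make_population_state(40, 20)
        assert interaction_energy(spec, state, collective=True).coupling_scale == 20.0
        assert interaction_energy(spec, state, collective=False).coupling_scale == 0.5

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            InteractionSpec(lam=-1.0)
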