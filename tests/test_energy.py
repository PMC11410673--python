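import numpy as np
import pytest

from netctrl.energy import (
    ConditioningError,
    StateMap,
    build_control_weights,
    minimum_energy,
    optimal_transition,
    transition_energies,
    transition_energy_matrix,
)

from conftest import random_states
from _oracles import discrete_qp_energy

SCALAR_MIN_ENERGY = 2 / (1 - np.exp(-2))  # a=-1, x0=0 -> xT=1, T=1


class TestControlWeights:
    def test_uniform_all_ones(self):
        w = build_control_weights("uniform", n=5)
        assert np.all(w.diag == 1.0)

    def test_thickness_delta_bounds(self):
        # Cohen's-d extremes +0.87 / -0.59 bound the inputs in [0.41, 1.87]
        d = np.array([0.87, -0.59, 0.0, 0.2])
        w = build_control_weights("thickness_delta", d)
        assert w.diag.max() == pytest.approx(1.87)
        assert w.diag.min() == pytest.approx(0.41)

    def test_thickness_delta_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            build_control_weights("thickness_delta", np.array([-1.0, 0.5]))

    def test_receptor_minmax_spans_one_to_two(self):
        m = np.linspace(0, 7.3, 6)
        w = build_control_weights("receptor", m)
        assert w.diag.min() == pytest.approx(1.0)
        assert w.diag.max() == pytest.approx(2.0)

    def test_receptor_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_control_weights("receptor", np.full(4, 3.0))

    def test_unit_mean_map(self):
        m = np.array([1.0, 2.0, 3.0])
        w = build_control_weights("unit_mean_map", m)
        assert w.diag.mean() == pytest.approx(1.0)


class TestOptimalTransition:
    def test_zero_endpoints_zero_energy(self, random_system, uniform_b):
        n = random_system.n
        zero = StateMap(np.zeros(n))
        res = optimal_transition(random_system, uniform_b(n), zero, zero)
        assert res.energy == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(res.inputs, 0.0)

    def test_quadratic_scaling(self, random_system, uniform_b):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=3)
        e1 = optimal_transition(random_system, uniform_b(n), x0, xT).energy
        e2 = optimal_transition(
            random_system,
            uniform_b(n),
            StateMap(2 * x0.values),
            StateMap(2 * xT.values),
        ).energy
        assert e2 == pytest.approx(4 * e1, rel=1e-8)

    def test_matches_discretized_qp_oracle(self, random_system, uniform_b):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=4)
        w = uniform_b(n)
        closed = optimal_transition(random_system, w, x0, xT, n_steps=1000).energy
        qp = discrete_qp_energy(random_system.a_norm, w.diag, x0.values, xT.values)
        assert closed == pytest.approx(qp, rel=0.01)

    def test_scalar_high_rho_limit(self, scalar_system, uniform_b):
        res = optimal_transition(
            scalar_system,
            uniform_b(1),
            StateMap([0.0]),
            StateMap([1.0]),
            rho=1e4,
        )
        assert res.energy == pytest.approx(SCALAR_MIN_ENERGY, rel=0.02)

    def test_endpoint_accuracy(self, random_system, uniform_b):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=5)
        res = optimal_transition(random_system, uniform_b(n), x0, xT)
        assert res.endpoint_error < 1e-6
        assert res.warning is None

    def test_heterogeneous_weights_change_energy(self, random_system):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=6)
        w_uni = build_control_weights("uniform", n=n)
        w_het = build_control_weights("receptor", np.arange(n, dtype=float))
        e_uni = optimal_transition(random_system, w_uni, x0, xT).energy
        e_het = optimal_transition(random_system, w_het, x0, xT).energy
        assert e_het != pytest.approx(e_uni, rel=1e-6)
        assert e_het < e_uni  # extra input capacity can only help

    def test_invalid_parameters_rejected(self, scalar_system, uniform_b):
        x0, xT = StateMap([0.0]), StateMap([1.0])
        with pytest.raises(ValueError):
            optimal_transition(scalar_system, uniform_b(1), x0, xT, T=-1)
        with pytest.raises(ValueError):
            optimal_transition(scalar_system, uniform_b(1), x0, xT, n_steps=10)


class TestMinimumEnergy:
    def test_free_drift_endpoint_costs_nothing(self, random_system, uniform_b):
        from scipy.linalg import expm

        n = random_system.n
        x0 = random_states(n, 1, seed=7)[0]
        xT = StateMap(expm(random_system.a_norm) @ x0.values)
        e = minimum_energy(random_system, uniform_b(n), x0, xT)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_scalar_closed_form(self, scalar_system, uniform_b):
        e = minimum_energy(scalar_system, uniform_b(1), StateMap([0.0]), StateMap([1.0]))
        assert e == pytest.approx(SCALAR_MIN_ENERGY, rel=1e-10)

    def test_lower_bounds_optimal_energy(self, random_system, uniform_b):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=8)
        e_min = minimum_energy(random_system, uniform_b(n), x0, xT)
        e_opt = optimal_transition(random_system, uniform_b(n), x0, xT, rho=1.0).energy
        assert e_min <= e_opt

    def test_rho_convergence_monotone_from_above(self, random_system, uniform_b):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=9)
        e_min = minimum_energy(random_system, uniform_b(n), x0, xT)
        energies = [
            optimal_transition(random_system, uniform_b(n), x0, xT, rho=r).energy
            for r in (1.0, 1e2, 1e4)
        ]
        assert energies[0] >= energies[1] >= energies[2] >= e_min
        assert energies[2] == pytest.approx(e_min, rel=0.02)


class TestTransitionMatrix:
    def test_single_pair_consistency(self, random_system, uniform_b):
        n = random_system.n
        x0, xT = random_states(n, 2, seed=10)
        te = transition_energy_matrix(
            random_system, uniform_b(n), [x0], [xT], n_steps=500
        )
        direct = optimal_transition(random_system, uniform_b(n), x0, xT, n_steps=500)
        assert te.energies.shape == (1, 1)
        assert te.energies[0, 0] == pytest.approx(direct.energy, rel=1e-10)

    def test_grid_matches_per_pair_calls(self, random_system, uniform_b):
        n = random_system.n
        states = random_states(n, 3, seed=11)
        te = transition_energy_matrix(
            random_system, uniform_b(n), states, n_steps=400
        )
        for i in range(3):
            for j in range(3):
                direct = optimal_transition(
                    random_system, uniform_b(n), states[i], states[j], n_steps=400
                ).energy
                assert te.energies[i, j] == pytest.approx(direct, rel=1e-9)

    def test_nonnegative_and_finite(self, random_system, uniform_b):
        n = random_system.n
        states = random_states(n, 4, seed=12)
        te = transition_energy_matrix(random_system, uniform_b(n), states, n_steps=300)
        assert np.all(te.energies >= 0)
        assert np.all(np.isfinite(te.energies))

    def test_generic_asymmetry_under_drift(self, random_system, uniform_b):
        # moving with the intrinsic drift costs less than moving against it
        n = random_system.n
        states = random_states(n, 3, seed=13)
        te = transition_energy_matrix(random_system, uniform_b(n), states, n_steps=300)
        assert not np.allclose(te.energies, te.energies.T, rtol=1e-6)

    def test_empty_states_rejected(self, random_system, uniform_b):
        with pytest.raises(ValueError):
            transition_energy_matrix(random_system, uniform_b(random_system.n), [])


class TestStateMap:
    def test_unit_norm_flag(self):
        s = StateMap(np.array([3.0, 4.0]), unit_norm=True)
        assert np.linalg.norm(s.values) == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            StateMap(np.array([1.0, np.nan]))
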