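"""The 8-compartment ODE system: structure, conservation, solver agreement."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from mscpbk import DoseEvent, simulate, state_derivative, venous_outflow_concentration
from mscpbk.kinetics import CellKineticParams, OrganKinetics
from mscpbk.model import N_STATES, build_rate_matrix, mass_weights
from mscpbk.physiology import ORGANS


def uniform_params(p=1.0, k_arrest=0.0, k_release=0.0, k_depletion=0.0, blood_k=0.0):
    return CellKineticParams(
        organs={o: OrganKinetics(p, k_arrest, k_release, k_depletion) for o in ORGANS},
        blood_k_depletion=blood_k,
    )


class TestVenousOutflow:
    def test_identity_partition(self):
        assert venous_outflow_concentration(100.0, 1.0) == 100.0

    def test_zero_concentration(self):
        assert venous_outflow_concentration(0.0, 742.733) == 0.0

    def test_division_by_partition(self):
        assert venous_outflow_concentration(742.733, 742.733) == pytest.approx(1.0)

    def test_nonpositive_partition_rejected(self):
        with pytest.raises(ValueError):
            venous_outflow_concentration(1.0, 0.0)


class TestDerivative:
    def test_zero_state_has_zero_derivative(self, mouse, reference_params):
        dx = state_derivative(np.zeros(N_STATES), reference_params, mouse)
        assert np.all(dx == 0)

    def test_pure_circulation_equilibrium(self, mouse):
        """With all rates 0 and P = 1, a spatially uniform concentration is a
        steady state of the circulation: every inflow matches its outflow."""
        params = uniform_params(p=1.0)
        state = np.zeros(N_STATES)
        state[:8] = 1234.5  # uniform concentration in every vascular space
        dx = state_derivative(state, params, mouse)
        assert np.allclose(dx, 0.0, atol=1e-9 * 1234.5 * mouse.cardiac_output)

    def test_mass_balance_of_derivative(self, mouse, reference_params):
        """Volume-weighted concentration derivatives plus the retained-pool and
        sink derivatives sum to zero: the system only moves cells around."""
        rng = np.random.default_rng(42)
        state = rng.uniform(0.0, 1e6, size=N_STATES)
        dx = state_derivative(state, reference_params, mouse)
        w = mass_weights(mouse)
        assert abs(w @ dx) <= 1e-9 * np.sum(np.abs(w * dx))

    def test_rate_matrix_columns_conserve_mass(self, human, reference_params):
        A = build_rate_matrix(human, reference_params)
        w = mass_weights(human)
        assert np.allclose(w @ A, 0.0, atol=1e-9 * human.cardiac_output)


class TestSimulate:
    def test_zero_dose_gives_zero_trajectory(self, mouse, reference_params, grid_24h):
        result = simulate(mouse, reference_params, [], grid_24h, solver="expm")
        assert np.all(result.states == 0)
        assert result.dose_total == 0

    def test_dose_linearity(self, mouse, reference_params, grid_24h):
        """The system is first order, so trajectories scale exactly with dose."""
        r1 = simulate(mouse, reference_params, [DoseEvent("intravenous", 5e5)], grid_24h, solver="expm")
        r2 = simulate(mouse, reference_params, [DoseEvent("intravenous", 1e6)], grid_24h, solver="expm")
        np.testing.assert_allclose(2 * r1.states, r2.states, rtol=1e-8)

    def test_mass_conservation_along_trajectory(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h)
        total = result.total_live_series() + result.depleted_series()
        np.testing.assert_allclose(total, 5e5, rtol=1e-6)

    def test_nonnegativity(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h)
        floor = -1e-9 * 5e5 / mouse.blood_accessible_volume
        assert np.min(result.states) >= floor

    def test_adaptive_matches_exact_propagator(self, mouse, reference_params, iv_dose, grid_24h):
        """LSODA at rtol 1e-8 and the matrix-exponential propagator agree."""
        r_ode = simulate(mouse, reference_params, iv_dose, grid_24h, solver="lsoda")
        r_exp = simulate(mouse, reference_params, iv_dose, grid_24h, solver="expm")
        scale = 5e5 / mouse.blood_accessible_volume
        np.testing.assert_allclose(r_ode.states, r_exp.states, rtol=1e-5, atol=1e-7 * scale)

    def test_uniform_concentration_limit(self, mouse):
        """With no arrest or depletion and P = 1 everywhere, the dose relaxes
        to a uniform concentration dose / (total blood-accessible volume)."""
        params = uniform_params(p=1.0, k_release=0.5)
        grid = np.array([0.0, 50.0, 100.0])
        result = simulate(mouse, params, [DoseEvent("intravenous", 1e6)], grid, solver="expm")
        expected = 1e6 / mouse.blood_accessible_volume
        np.testing.assert_allclose(result.states[-1, :8], expected, rtol=1e-3)

    def test_time_grid_validation(self, mouse, reference_params):
        with pytest.raises(ValueError, match="increasing"):
            simulate(mouse, reference_params, [], np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="at or before"):
            simulate(mouse, reference_params, [DoseEvent("intravenous", 1e5, 0.0)], np.array([1.0, 2.0]))

    def test_mid_run_dose_event(self, mouse, reference_params):
        """A bolus at t = 1 h raises the total cell count by exactly its amount."""
        grid = np.linspace(0.0, 3.0, 31)
        events = [DoseEvent("intravenous", 1e5, 0.0), DoseEvent("intravenous", 2e5, 1.0)]
        result = simulate(mouse, reference_params, events, grid, solver="expm")
        total = result.total_live_series() + result.depleted_series()
        before = total[grid < 1.0]
        after = total[grid >= 1.0]
        np.testing.assert_allclose(before, 1e5, rtol=1e-9)
        np.testing.assert_allclose(after, 3e5, rtol=1e-9)


class TestDerivedOutputs:
    def test_survival_starts_at_one(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h, solver="expm")
        assert result.survival_fraction(0.0) == pytest.approx(1.0)

    def test_survival_is_one_without_depletion(self, mouse, grid_24h):
        params = uniform_params(p=10.0, k_arrest=1.0, k_release=0.1)
        result = simulate(mouse, params, [DoseEvent("intravenous", 1e6)], grid_24h, solver="expm")
        np.testing.assert_allclose(result.survival_series(), 1.0, rtol=1e-9)

    def test_amounts_sum_to_dose(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h, solver="expm")
        for t in (0.25, 3.0, 24.0):
            from mscpbk.model import COMPARTMENTS

            total = sum(result.amount_in_organ(c, t) for c in COMPARTMENTS)
            assert total + np.interp(t, result.times, result.depleted_series()) == pytest.approx(
                5e5, rel=1e-6
            )

    def test_unknown_compartment_rejected(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h, solver="expm")
        with pytest.raises(KeyError):
            result.amount_in_organ("brain", 1.0)

    def test_time_outside_range_rejected(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h, solver="expm")
        with pytest.raises(ValueError, match="outside"):
            result.survival_fraction(48.0)

    def test_tidy_export_consistency(self, mouse, reference_params, iv_dose, grid_24h):
        result = simulate(mouse, reference_params, iv_dose, grid_24h, solver="expm")
        frame = result.to_frame()
        assert set(frame.columns) == {
            "time_h",
            "compartment",
            "amount_cells",
            "concentration_cells_per_L",
            "concentration_cells_per_kg",
            "arrested_cells",
        }
        lung = frame[frame["compartment"] == "lung"]
        np.testing.assert_allclose(
            lung["concentration_cells_per_kg"].to_numpy(),
            lung["amount_cells"].to_numpy() / mouse.organs["lung"].total_volume,
        )


def test_two_phase_blood_decay(mouse, reference_params, iv_dose):
    """The venous concentration profile is biexponential: a fast distribution
    phase followed by a slower elimination phase, with rate constants
    differing by far more than 2x."""
    grid = np.unique(np.concatenate([np.linspace(0, 1, 201), np.linspace(1, 24, 201)]))
    result = simulate(mouse, reference_params, iv_dose, grid, solver="expm")
    conc = result.concentration_per_kg_series("blood")

    def biexp_log(t, log_a1, l1, log_a2, l2):
        return np.log(np.exp(log_a1 - l1 * t) + np.exp(log_a2 - l2 * t))

    p0 = [np.log(conc[0]), 5.0, np.log(conc[200]), 0.06]
    popt, _ = curve_fit(biexp_log, grid, np.log(conc), p0=p0, maxfev=20000)
    fast, slow = sorted([popt[1], popt[3]], reverse=True)
    assert slow > 0
    assert fast / slow > 2.0
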