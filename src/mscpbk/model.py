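"""The 8-compartment whole-body kinetic model of circulating cells.

Model structure
---------------
Compartments: arterial blood, venous blood, and six perfused organs (lung,
liver, spleen, kidney, heart, rest of body), all interconnected by the
systemic circulation. The lung lies in series between the venous and
arterial pools and receives the total cardiac output; the other organs are
perfused in parallel from the arterial pool. The splenic venous outflow
drains into the liver (splanchnic/portal route), so total hepatic outflow
carries the hepatic-artery plus splenic flow.

Within each organ, cells in the vascular space (concentration ``C_V_t``,
volume ``V_V_t``) leave with the venous blood at the partition-limited
concentration ``C_V_t / P_t``, are arrested into an extravascular retained
pool ``A_E_t`` at first order (``k_arrest``), released back (``k_release``)
or irreversibly depleted from the retained pool (``k_depletion``). The
circulating arterial and venous pools are depleted at ``blood_k_depletion``.
Every depletion flux accumulates in a single cumulative sink ``D_cum``, so
live cells + ``D_cum`` = administered dose at all times.

Vascular balance for a parallel organ ``t`` with inflow concentration
``C_in``::

    V_V_t dC_V_t/dt = Q_t (C_in - C_V_t / P_t) - k_arrest_t C_V_t V_V_t
                      + k_release_t A_E_t
    dA_E_t/dt       = k_arrest_t C_V_t V_V_t - (k_release_t + k_depletion_t) A_E_t

The system is linear and time-invariant between dose events, which permits
an exact matrix-exponential propagator alongside the adaptive stiff solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .dosing import DoseEvent, apply_dose
from .kinetics import CellKineticParams
from .physiology import ORGANS, SpeciesPhysiology

__all__ = [
    "N_STATES",
    "IDX_ARTERIAL",
    "IDX_VENOUS",
    "IDX_VASCULAR",
    "IDX_ARRESTED",
    "IDX_DEPLETED",
    "COMPARTMENTS",
    "venous_outflow_concentration",
    "build_rate_matrix",
    "mass_weights",
    "state_derivative",
    "simulate",
    "SimulationResult",
]

# Fixed state layout: [C_A, C_ven, C_V per organ (6), A_E per organ (6), D_cum]
IDX_ARTERIAL = 0
IDX_VENOUS = 1
IDX_VASCULAR = {organ: 2 + i for i, organ in enumerate(ORGANS)}
IDX_ARRESTED = {organ: 8 + i for i, organ in enumerate(ORGANS)}
IDX_DEPLETED = 14
N_STATES = 15

#: Output compartment labels (blood pools + organs) used in tidy exports.
COMPARTMENTS = ("arterial_blood", "venous_blood") + ORGANS


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid trajectory."""


def venous_outflow_concentration(c_vascular: float, partition_coefficient: float) -> float:
    """Concentration in the venous blood leaving an organ, cells/L.

    The partition coefficient ``P`` relates the concentration of cells in
    the blood within the organ to the concentration in the venous blood
    leaving it: ``CV = C_V / P``.
    """
    if not partition_coefficient > 0:
        raise ValueError(f"partition coefficient must be > 0, got {partition_coefficient!r}")
    return c_vascular / partition_coefficient


def build_rate_matrix(physiology: SpeciesPhysiology, params: CellKineticParams) -> np.ndarray:
    """Assemble the (15, 15) rate matrix A such that dx/dt = A @ x.

    State layout: ``[C_A, C_ven, C_V_lung..C_V_rest, A_E_lung..A_E_rest,
    D_cum]`` with concentrations in cells/L and amounts in cells.
    """
    if set(params.organs) != set(physiology.organs):
        raise ValueError("organ sets of params and physiology do not match")
    A = np.zeros((N_STATES, N_STATES))
    V_a = physiology.arterial_blood_volume
    V_v = physiology.venous_blood_volume
    Q_lung = physiology.organs["lung"].blood_flow
    kdb = params.blood_k_depletion

    arterial_organs = ("liver", "spleen", "kidney", "heart", "rest_of_body")
    arterial_outflow = sum(physiology.organs[o].blood_flow for o in arterial_organs)

    def outflow_terms(organ: str) -> tuple[float, float]:
        """(flow leaving the organ, its partition coefficient)."""
        if organ == "liver":
            return physiology.liver_total_flow, params.organs["liver"].partition_coefficient
        return physiology.organs[organ].blood_flow, params.organs[organ].partition_coefficient

    # Arterial pool: fed by lung venous outflow, drained by organ perfusion
    # and blood depletion.
    i_lung = IDX_VASCULAR["lung"]
    A[IDX_ARTERIAL, i_lung] += Q_lung / (params.organs["lung"].partition_coefficient * V_a)
    A[IDX_ARTERIAL, IDX_ARTERIAL] += -(arterial_outflow / V_a + kdb)

    # Venous pool: collects every organ outflow except spleen (drains into
    # liver) and lung (fills the arterial pool); drains into the lung.
    for organ in ("liver", "kidney", "heart", "rest_of_body"):
        Q_out, P = outflow_terms(organ)
        A[IDX_VENOUS, IDX_VASCULAR[organ]] += Q_out / (P * V_v)
    A[IDX_VENOUS, IDX_VENOUS] += -(Q_lung / V_v + kdb)

    for organ in ORGANS:
        ok = params.organs[organ]
        V = physiology.organs[organ].vascular_volume
        i_c, i_a = IDX_VASCULAR[organ], IDX_ARRESTED[organ]
        Q_out, P = outflow_terms(organ)
        # inflow
        if organ == "lung":
            A[i_c, IDX_VENOUS] += Q_lung / V
        elif organ == "liver":
            A[i_c, IDX_ARTERIAL] += physiology.organs["liver"].blood_flow / V
            Q_sp, P_sp = outflow_terms("spleen")
            A[i_c, IDX_VASCULAR["spleen"]] += Q_sp / (P_sp * V)
        else:
            A[i_c, IDX_ARTERIAL] += physiology.organs[organ].blood_flow / V
        # outflow, arrest, release
        A[i_c, i_c] += -(Q_out / (P * V) + ok.k_arrest)
        A[i_c, i_a] += ok.k_release / V
        # retained pool
        A[i_a, i_c] += ok.k_arrest * V
        A[i_a, i_a] += -(ok.k_release + ok.k_depletion)
        # depletion sink
        A[IDX_DEPLETED, i_a] += ok.k_depletion
    A[IDX_DEPLETED, IDX_ARTERIAL] += kdb * V_a
    A[IDX_DEPLETED, IDX_VENOUS] += kdb * V_v
    return A


def mass_weights(physiology: SpeciesPhysiology) -> np.ndarray:
    """Weights w such that w @ state = total cells (live + depleted)."""
    w = np.ones(N_STATES)
    w[IDX_ARTERIAL] = physiology.arterial_blood_volume
    w[IDX_VENOUS] = physiology.venous_blood_volume
    for organ in ORGANS:
        w[IDX_VASCULAR[organ]] = physiology.organs[organ].vascular_volume
    return w


def state_derivative(
    state: np.ndarray, params: CellKineticParams, physiology: SpeciesPhysiology
) -> np.ndarray:
    """Time derivative of the full state vector (cells/L/h and cells/h)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {state.shape}")
    return build_rate_matrix(physiology, params) @ state


@dataclass
class SimulationResult:
    """A simulated trajectory plus derived biodistribution series.

    ``states`` holds the raw state vectors (one row per time point);
    convenience accessors interpolate linearly between grid points.
    """

    times: np.ndarray
    states: np.ndarray
    physiology: SpeciesPhysiology
    params: CellKineticParams
    dose_total: float
    solver: str = "lsoda"

    def _series(self, index: int) -> np.ndarray:
        return self.states[:, index]

    def _check_time(self, t: float) -> None:
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"time {t} h outside simulated range [{self.times[0]}, {self.times[-1]}] h")

    def _interp(self, series: np.ndarray, t: float) -> float:
        self._check_time(t)
        return float(np.interp(t, self.times, series))

    def amount_series(self, compartment: str) -> np.ndarray:
        """Cells in a compartment over the grid (vascular + retained for organs)."""
        if compartment == "arterial_blood":
            return self._series(IDX_ARTERIAL) * self.physiology.arterial_blood_volume
        if compartment == "venous_blood":
            return self._series(IDX_VENOUS) * self.physiology.venous_blood_volume
        if compartment in ORGANS:
            V = self.physiology.organs[compartment].vascular_volume
            return self._series(IDX_VASCULAR[compartment]) * V + self._series(IDX_ARRESTED[compartment])
        raise KeyError(f"unknown compartment {compartment!r}")

    def concentration_per_kg_series(self, compartment: str) -> np.ndarray:
        """Cells per kg of compartment mass (density 1 kg/L).

        ``"blood"`` maps to the venous pool, matching terminal venous
        sampling of biodistribution experiments.
        """
        if compartment == "blood":
            compartment = "venous_blood"
        if compartment == "arterial_blood":
            mass = self.physiology.arterial_blood_volume
        elif compartment == "venous_blood":
            mass = self.physiology.venous_blood_volume
        else:
            mass = self.physiology.organs[compartment].total_volume  # 1 kg/L
        return self.amount_series(compartment) / mass

    def depleted_series(self) -> np.ndarray:
        return self._series(IDX_DEPLETED)

    def survival_series(self) -> np.ndarray:
        """Fraction of the administered dose still alive over the grid."""
        if self.dose_total == 0:
            return np.ones_like(self.times)
        return 1.0 - self.depleted_series() / self.dose_total

    def survival_fraction(self, t: float) -> float:
        """Fraction of administered cells not yet depleted at time ``t`` (h)."""
        return self._interp(self.survival_series(), t)

    def amount_in_organ(self, compartment: str, t: float) -> float:
        """Cells in a compartment at time ``t`` (vascular + retained)."""
        return self._interp(self.amount_series(compartment), t)

    def concentration_per_kg(self, compartment: str, t: float) -> float:
        return self._interp(self.concentration_per_kg_series(compartment), t)

    def total_live_series(self) -> np.ndarray:
        return np.sum([self.amount_series(c) for c in COMPARTMENTS], axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, compartment, amount_cells, concentrations, arrested."""
        frames = []
        for compartment in COMPARTMENTS:
            if compartment in ORGANS:
                conc_L = self._series(IDX_VASCULAR[compartment])
                arrested = self._series(IDX_ARRESTED[compartment])
            else:
                conc_L = self._series(IDX_ARTERIAL if compartment == "arterial_blood" else IDX_VENOUS)
                arrested = np.zeros_like(self.times)
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "compartment": compartment,
                        "amount_cells": self.amount_series(compartment),
                        "concentration_cells_per_L": conc_L,
                        "concentration_cells_per_kg": self.concentration_per_kg_series(compartment),
                        "arrested_cells": arrested,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _rk4_propagate(A: np.ndarray, x0: np.ndarray, t0: float, t_out: np.ndarray, step: float) -> np.ndarray:
    """Classical fixed-step 4th-order Runge-Kutta, used as a reference integrator."""
    rhs: Callable[[np.ndarray], np.ndarray] = lambda x: A @ x
    out = np.empty((len(t_out), len(x0)))
    x = x0.copy()
    t = t0
    for j, t_target in enumerate(t_out):
        while t < t_target - 1e-15:
            h = min(step, t_target - t)
            k1 = rhs(x)
            k2 = rhs(x + 0.5 * h * k1)
            k3 = rhs(x + 0.5 * h * k2)
            k4 = rhs(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[j] = x
    return out


def _expm_propagate(A: np.ndarray, x0: np.ndarray, t0: float, t_out: np.ndarray) -> np.ndarray:
    """Exact propagation of the linear system via matrix exponentials."""
    out = np.empty((len(t_out), len(x0)))
    x = x0.copy()
    t = t0
    cache: dict[float, np.ndarray] = {}
    for j, t_target in enumerate(t_out):
        dt = t_target - t
        if dt > 0:
            Phi = cache.get(dt)
            if Phi is None:
                Phi = expm(A * dt)
                cache[dt] = Phi
            x = Phi @ x
            t = t_target
        out[j] = x
    return out


def _adaptive_propagate(
    A: np.ndarray,
    x0: np.ndarray,
    t0: float,
    t_out: np.ndarray,
    method: str,
    rtol: float,
    atol: float,
) -> np.ndarray:
    if len(t_out) and t_out[-1] > t0:
        sol = solve_ivp(
            lambda t, x: A @ x,
            (t0, t_out[-1]),
            x0,
            method=method,
            t_eval=t_out[t_out > t0],
            jac=(lambda t, x: A) if method == "LSODA" else A,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed on [{t0}, {t_out[-1]}] h: {sol.message}")
    out = np.empty((len(t_out), len(x0)))
    k = 0
    for j, t_target in enumerate(t_out):
        if t_target > t0:
            out[j] = sol.y[:, k]
            k += 1
        else:
            out[j] = x0
    return out


def simulate(
    physiology: SpeciesPhysiology,
    params: CellKineticParams,
    dose_events: Sequence[DoseEvent],
    time_grid: Sequence[float],
    solver: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-6,
    rk4_step: float = 1e-4,
    initial_state: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate the model on a time grid (hours).

    Dose events are instantaneous boluses: at each event time the dose is
    added to the route-specific compartment before any output at that time
    is emitted, so the grid value at a dose time is post-dose.

    Parameters
    ----------
    solver
        ``"lsoda"`` or ``"bdf"`` — adaptive stiff integrators;
        ``"expm"`` — exact matrix-exponential propagation of the linear
        system (used internally by calibration and sensitivity);
        ``"rk4"`` — fixed-step classical Runge-Kutta reference integrator
        with step ``rk4_step`` h.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) < 1:
        raise ValueError("time_grid must be a non-empty 1-D sequence of hours")
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if not (rtol > 0 and atol > 0):
        raise ValueError("solver tolerances must be positive")
    events = sorted(dose_events, key=lambda e: e.time)
    if events and events[0].time < time_grid[0]:
        raise ValueError("time_grid must start at or before the first dose event")

    A = build_rate_matrix(physiology, params)
    x = np.zeros(N_STATES) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    states = np.empty((len(time_grid), N_STATES))

    def propagate(x0: np.ndarray, t0: float, t_out: np.ndarray) -> np.ndarray:
        if solver == "expm":
            return _expm_propagate(A, x0, t0, t_out)
        if solver == "rk4":
            return _rk4_propagate(A, x0, t0, t_out, rk4_step)
        if solver in ("lsoda", "bdf"):
            return _adaptive_propagate(A, x0, t0, t_out, solver.upper(), rtol, atol)
        raise ValueError(f"unknown solver {solver!r}")

    # Piecewise propagation between dose events. Grid points strictly before
    # an event time are emitted pre-dose; a grid point at the event time is
    # emitted post-dose (the "t = 0+" convention for bolus dosing).
    t_cur = time_grid[0]
    cursor = 0
    for event in events:
        seg = time_grid[cursor:][time_grid[cursor:] < event.time]
        if len(seg):
            states[cursor : cursor + len(seg)] = propagate(x, t_cur, seg)
            x = states[cursor + len(seg) - 1].copy()
            t_cur = seg[-1]
            cursor += len(seg)
        if event.time > t_cur:
            x = propagate(x, t_cur, np.array([event.time]))[0]
            t_cur = event.time
        x = apply_dose(x, event, physiology)
    if cursor < len(time_grid):
        seg = time_grid[cursor:]
        states[cursor:] = propagate(x, t_cur, seg)

    dose_total = sum(e.amount for e in events)
    if initial_state is not None:
        dose_total += float(mass_weights(physiology) @ np.asarray(initial_state, dtype=float))
    result = SimulationResult(
        times=time_grid, states=states, physiology=physiology, params=params,
        dose_total=dose_total, solver=solver,
    )
    scale = dose_total / physiology.blood_accessible_volume if dose_total else 1.0
    if np.min(states) < -1e-6 * max(scale, 1.0):
        raise SimulationError(
            f"trajectory went negative beyond tolerance (min {np.min(states):g})"
        )
    return result
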