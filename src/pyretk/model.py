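"""Linear compartmental kinetics: system matrix, simulation, mass balance.

The state is a 21-vector.  For each isomer (cis block first, then trans):

====== =========================================================
offset compartment
====== =========================================================
0      GI    parent bioavailable in the gastrointestinal tract
1      D     parent bioavailable at the skin surface
2      R     parent bioavailable in the respiratory tract
3      B     parent in blood + rapidly-equilibrating tissues
4      S     parent in storage tissues (slow return to blood)
5      M     body burden of the isomer's DCCA metabolite
6      U     cumulative urinary DCCA
7      F     cumulative fecal DCCA
8      NO    cumulative flux into non-observed metabolites (sink)
====== =========================================================

followed by the shared 3-PBA block: 18 M_3PBA, 19 U_3PBA, 20 F_3PBA.

Between dose events the dynamics are ``dy/dt = A y`` with constant ``A``;
dose events and dermal wash-off are discrete state jumps.  Every column of
``A`` sums to zero (each flux leaves one compartment and enters another or a
cumulative sink), which is what makes the mass balance exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, UnsupportedRouteError
from .params import ParameterSet
from .scenario import ExposureScenario

__all__ = [
    "N_STATE",
    "STATE_NAMES",
    "build_system_matrix",
    "derivative_field",
    "simulate",
    "SimulationResult",
    "mass_balance_residual",
]

N_STATE = 21
_ISO = ("cis", "trans")
_OFF = {"cis": 0, "trans": 9}
_I3_M, _I3_U, _I3_F = 18, 19, 20

STATE_NAMES = tuple(
    n for w in _ISO for n in (
        f"GI_{w}", f"D_{w}", f"R_{w}", f"B_{w}", f"S_{w}",
        f"M_{w}DCCA", f"U_{w}DCCA", f"F_{w}DCCA", f"NO_{w}")
) + ("M_3PBA", "U_3PBA", "F_3PBA")

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


def build_system_matrix(params: ParameterSet) -> np.ndarray:
    """The constant 21x21 transfer-rate matrix A (h^-1)."""
    A = np.zeros((N_STATE, N_STATE))
    for which in _ISO:
        iso = params.isomer(which)
        o = _OFF[which]
        gi, d, r, b, s, m, u, f, no = range(o, o + 9)
        k_inh = iso.k_abs_inh if iso.k_abs_inh is not None else 0.0
        A[gi, gi] = -iso.k_abs_oral
        A[d, d] = -iso.k_abs_dermal
        A[r, r] = -k_inh
        A[b, gi] = iso.k_abs_oral
        A[b, d] = iso.k_abs_dermal
        A[b, r] = k_inh
        A[b, b] = -(iso.k_BS + iso.k_metabolism)
        A[b, s] = iso.k_SB
        A[s, b] = iso.k_BS
        A[s, s] = -iso.k_SB
        A[m, b] = iso.k_BM
        A[m, m] = -iso.k_elim
        A[u, m] = iso.k_MU
        A[f, m] = iso.k_MF
        A[no, b] = params.k_BM_NO(which)
        A[_I3_M, b] = params.k_BM_3PBA(which)
    A[_I3_M, _I3_M] = -params.shared.k_elim_3PBA
    A[_I3_U, _I3_M] = params.shared.k_MU_3PBA
    A[_I3_F, _I3_M] = params.shared.k_MF_3PBA
    return A


def _check_routes(params: ParameterSet, scenario: ExposureScenario) -> None:
    if "inhalation" in scenario.routes():
        for which in _ISO:
            if params.isomer(which).k_abs_inh is None:
                raise UnsupportedRouteError(
                    f"scenario contains inhalation events but k_abs_inh_{which} "
                    "is unset"
                )


def derivative_field(params: ParameterSet,
                     scenario: ExposureScenario) -> Callable[[float, np.ndarray], np.ndarray]:
    """The state-derivative function ``f(t, y) = A y``.

    Dose events and wash-off are *not* impulses inside the derivative; they
    are applied as discrete state jumps by :func:`simulate`, so the returned
    field is linear and autonomous.
    """
    _check_routes(params, scenario)
    A = build_system_matrix(params)
    return lambda t, y: A @ y


def _event_jumps(params: ParameterSet, scenario: ExposureScenario):
    """(time, delta-state) dose jumps and (time, depot-indices) wash-offs."""
    jumps: list[tuple[float, np.ndarray]] = []
    washoffs: list[float] = []
    route_idx = {"oral": 0, "dermal": 1, "inhalation": 2}
    for e in scenario.events:
        dy = np.zeros(N_STATE)
        for which, frac in (("cis", e.cis_fraction), ("trans", 1.0 - e.cis_fraction)):
            iso = params.isomer(which)
            f = {"oral": iso.f_abs_oral, "dermal": iso.f_abs_dermal,
                 "inhalation": 1.0}[e.route]
            dy[_OFF[which] + route_idx[e.route]] += e.amount * frac * f
        jumps.append((e.time, dy))
        if e.washoff_time is not None:
            washoffs.append(e.washoff_time)
    return jumps, sorted(set(washoffs))


def _default_grid(scenario: ExposureScenario, jumps, washoffs) -> np.ndarray:
    """A time grid dense enough for sub-minute peak location near events."""
    T = scenario.duration
    pts = [np.linspace(0.0, T, max(2001, min(20001, int(T * 20) + 1)))]
    for te in sorted({t for t, _ in jumps} | set(washoffs)):
        pts.append(np.array([te]))
        fine = te + np.geomspace(1e-4, min(4.0, max(T - te, 1e-3)), 60)
        pts.append(fine[fine <= T])
    grid = np.unique(np.concatenate(pts))
    return grid[(grid >= 0.0) & (grid <= T)]


class _EigPropagator:
    """Exact propagation of dy/dt = A y via eigendecomposition.

    This is the matrix-exponential fast path used inside estimation loops
    and as the independent oracle for the Runge-Kutta solver in tests.
    """

    def __init__(self, A: np.ndarray):
        w, V = np.linalg.eig(A)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e10:
            raise IntegrationError(
                "system matrix is too close to defective for the "
                "eigendecomposition propagator; use the Runge-Kutta solver"
            )
        self.w, self.V = w, V
        self.Vinv = np.linalg.inv(V)

    def states(self, y0: np.ndarray, dts: np.ndarray) -> np.ndarray:
        c = self.Vinv @ y0.astype(complex)
        phases = np.exp(np.outer(dts, self.w)) * c  # (nt, n)
        return np.real(phases @ self.V.T)


@dataclass
class SimulationResult:
    """Time-indexed trajectories of every compartment for one scenario."""

    times: np.ndarray            # (nt,) h
    states: np.ndarray           # (nt, 21) mol
    params: ParameterSet
    scenario: ExposureScenario
    input_times: np.ndarray      # bioavailable bolus jump times
    input_amounts: np.ndarray    # total bioavailable moles per jump
    washoff_times: np.ndarray
    washoff_amounts: np.ndarray  # moles removed from the skin depots

    _CUMULATIVE = tuple(n for n in STATE_NAMES if n[0] in "UFN")

    def _dermal_factor_applies(self) -> bool:
        routes = self.scenario.routes()
        return routes == {"dermal"} and self.params.shared.dermal_3PBA_factor != 1.0

    def series(self, name: str) -> np.ndarray:
        """A named trajectory (mol); also accepts QU_* urinary-rate names.

        The dermal 3-PBA correction factor multiplies the reported urinary
        3-PBA series (U_3PBA, QU_3PBA) for all-dermal scenarios.
        """
        factor = 1.0
        if name in ("U_3PBA", "QU_3PBA") and self._dermal_factor_applies():
            factor = self.params.shared.dermal_3PBA_factor
        if name.startswith("QU_"):
            base = name[3:]
            rate = {
                "cisDCCA": self.params.cis.k_MU,
                "transDCCA": self.params.trans.k_MU,
                "3PBA": self.params.shared.k_MU_3PBA,
            }.get(base)
            if rate is None:
                raise KeyError(f"unknown urinary-rate series {name!r}")
            m = {"cisDCCA": "M_cisDCCA", "transDCCA": "M_transDCCA",
                 "3PBA": "M_3PBA"}[base]
            return factor * rate * self.states[:, _IDX[m]]
        try:
            return factor * self.states[:, _IDX[name]]
        except KeyError:
            raise KeyError(f"unknown series {name!r}; known: {STATE_NAMES}") from None

    def cumulative_urinary(self, analyte: str) -> np.ndarray:
        name = {"cisDCCA": "U_cisDCCA", "transDCCA": "U_transDCCA",
                "PBA3": "U_3PBA"}.get(analyte)
        if name is None:
            raise KeyError(f"unknown analyte {analyte!r}")
        return self.series(name)

    def urinary_rate(self, analyte: str) -> np.ndarray:
        name = {"cisDCCA": "QU_cisDCCA", "transDCCA": "QU_transDCCA",
                "PBA3": "QU_3PBA"}[analyte]
        return self.series(name)

    def total_state(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_h, compartment, amount_mol, pct_of_dose)."""
        dose = self.scenario.total_dose
        frames = []
        for name in STATE_NAMES + ("QU_cisDCCA", "QU_transDCCA", "QU_3PBA"):
            vals = self.series(name)
            frames.append(pd.DataFrame({
                "time_h": self.times, "compartment": name,
                "amount_mol": vals,
                "pct_of_dose": (100.0 * vals / dose) if dose > 0 else np.nan,
            }))
        return pd.concat(frames, ignore_index=True)


def simulate(params: ParameterSet, scenario: ExposureScenario,
             t_grid: Sequence[float] | None = None, *,
             method: str = "DOP853", rtol: float = 1e-9,
             atol: float | None = None) -> SimulationResult:
    """Integrate the model over a scenario.

    ``method`` is any scipy ``solve_ivp`` method, or ``"eig"`` for the exact
    eigendecomposition propagator (fast path; identical results to within
    solver tolerance).  The grid is auto-refined near dose events so that
    early blood peaks (minutes post-dose) are resolved.
    """
    _check_routes(params, scenario)
    A = build_system_matrix(params)
    jumps, washoffs = _event_jumps(params, scenario)

    if t_grid is None:
        grid = _default_grid(scenario, jumps, washoffs)
    else:
        grid = np.unique(np.concatenate([
            np.asarray(t_grid, dtype=float),
            np.array([t for t, _ in jumps] + washoffs + [0.0, scenario.duration]),
        ]))
        grid = grid[(grid >= 0.0) & (grid <= scenario.duration)]

    dose_scale = max(scenario.total_dose, 1e-300)
    if atol is None:
        atol = 1e-12 * dose_scale

    breakpoints = np.unique(np.array(
        [0.0, scenario.duration] + [t for t, _ in jumps] + washoffs))
    breakpoints = breakpoints[(breakpoints >= 0) & (breakpoints <= scenario.duration)]

    prop = _EigPropagator(A) if method == "eig" else None

    y = np.zeros(N_STATE)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    washoff_amounts: list[float] = []
    depot_idx = [_OFF["cis"] + 1, _OFF["trans"] + 1]

    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        for te, dy in jumps:
            if te == t0:
                y = y + dy
        if t0 in washoffs:
            removed = float(y[depot_idx].sum())
            washoff_amounts.append(removed)
            y = y.copy()
            y[depot_idx] = 0.0
        seg_mask = (grid >= t0) & (grid <= t1)
        seg_t = np.unique(np.concatenate([[t0], grid[seg_mask], [t1]]))
        if prop is not None:
            seg_states = prop.states(y, seg_t - t0)
        else:
            sol = solve_ivp(lambda t, z: A @ z, (t0, t1), y, method=method,
                            t_eval=seg_t, rtol=rtol, atol=atol)
            if not sol.success:
                raise IntegrationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
            seg_states = sol.y.T
        y = seg_states[-1]
        times_out.append(seg_t[:-1] if t1 != breakpoints[-1] else seg_t)
        states_out.append(seg_states[:-1] if t1 != breakpoints[-1] else seg_states)

    # handle events exactly at the final time (degenerate but legal)
    for te, dy in jumps:
        if te == breakpoints[-1] and breakpoints.size == 1:
            y = y + dy

    times = np.concatenate(times_out) if times_out else np.array([0.0])
    states = np.vstack(states_out) if states_out else np.zeros((1, N_STATE))

    neg_tol = 1e3 * atol + 1e-9 * dose_scale
    if states.min() < -neg_tol:
        raise IntegrationError(
            f"negative state {states.min():.3e} mol beyond tolerance "
            f"{neg_tol:.3e}; tighten solver tolerances"
        )
    states = np.clip(states, 0.0, None)

    return SimulationResult(
        times=times, states=states, params=params, scenario=scenario,
        input_times=np.array([t for t, _ in jumps]),
        input_amounts=np.array([dy.sum() for _, dy in jumps]),
        washoff_times=np.array(washoffs, dtype=float),
        washoff_amounts=np.array(washoff_amounts, dtype=float),
    )


def mass_balance_residual(result: SimulationResult,
                          scenario: ExposureScenario | None = None) -> float:
    """Max relative mass-balance violation over the simulated span.

    At every time, the bioavailable dose delivered so far minus any material
    removed by wash-off must equal the sum of all compartments (including the
    cumulative urinary, fecal and non-observed sinks).  Returns 0 for a
    zero-dose scenario by convention.
    """
    if scenario is None:
        scenario = result.scenario
    if scenario.total_dose == 0:
        return 0.0
    t = result.times
    delivered = np.zeros_like(t)
    for te, amt in zip(result.input_times, result.input_amounts):
        delivered += np.where(t >= te, amt, 0.0)
    for te, amt in zip(result.washoff_times, result.washoff_amounts):
        delivered -= np.where(t >= te, amt, 0.0)
    total = result.total_state()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(delivered - total) / np.where(delivered > 0, delivered, np.inf)
    return float(np.max(rel)) if rel.size else 0.0
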