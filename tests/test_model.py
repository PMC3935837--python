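import numpy as np
import pytest
from dataclasses import replace

from pyretk import (ExposureScenario, ParameterSet,
                    build_system_matrix, derivative_field,
                    mass_balance_residual, simulate)
from pyretk.errors import UnsupportedRouteError
from pyretk.model import N_STATE, STATE_NAMES

from conftest import random_parameter_set


def oral_bolus(duration=120.0, amount=1.0, cis_fraction=0.5):
    return ExposureScenario.single_bolus("oral", amount,
                                         cis_fraction=cis_fraction,
                                         duration=duration)


class TestDerivativeField:
    def test_zero_state_gives_zero_derivative(self, table2):
        f = derivative_field(table2, oral_bolus())
        assert np.all(f(0.0, np.zeros(N_STATE)) == 0.0)

    def test_single_gi_term_flux(self, table2):
        f = derivative_field(table2, oral_bolus())
        y = np.zeros(N_STATE)
        y[STATE_NAMES.index("GI_cis")] = 1.0
        dy = f(0.0, y)
        assert dy[STATE_NAMES.index("B_cis")] == pytest.approx(
            table2.cis.k_abs_oral)
        assert dy[STATE_NAMES.index("GI_cis")] == pytest.approx(
            -table2.cis.k_abs_oral)

    def test_flux_conservation_column_sums(self):
        """Every transfer leaves one compartment and enters another (or a
        cumulative sink), so all columns of the system matrix sum to zero
        and the total state derivative vanishes for any state."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            A = build_system_matrix(random_parameter_set(rng))
            assert np.allclose(A.sum(axis=0), 0.0, atol=1e-12)

    def test_inhalation_requires_rate(self, table2):
        scen = ExposureScenario.single_bolus("inhalation", 1.0, duration=24.0)
        with pytest.raises(UnsupportedRouteError):
            derivative_field(table2, scen)


class TestSimulate:
    def test_zero_dose_all_zero(self, table2):
        scen = ExposureScenario([], duration=48.0)
        res = simulate(table2, scen)
        assert np.all(res.states == 0.0)
        assert mass_balance_residual(res) == 0.0

    def test_matches_matrix_exponential_oracle(self):
        """The adaptive Runge-Kutta path must agree with exact
        matrix-exponential propagation of the same linear system."""
        from scipy.linalg import expm

        from pyretk.model import build_system_matrix, _event_jumps

        rng = np.random.default_rng(7)
        tq = np.linspace(0.25, 120.0, 12)
        for _ in range(15):
            ps = random_parameter_set(rng)
            scen = oral_bolus()
            rk = simulate(ps, scen, t_grid=tq, rtol=1e-11, atol=1e-15)
            A = build_system_matrix(ps)
            (_, x0), = _event_jumps(ps, scen)[0]
            ref = np.array([expm(A * t) @ x0 for t in tq])
            rk_states = np.vstack([
                rk.states[np.isclose(rk.times, t)][0] for t in tq])
            scale = np.max(np.abs(ref), axis=0) + 1e-300
            rel = np.max(np.abs(rk_states - ref) / scale)
            assert rel < 1e-8

    def test_eigendecomposition_fast_path_consistent(self):
        """The eig-based propagator agrees with the RK solver well inside
        the acceptance tolerance for urinary observables."""
        rng = np.random.default_rng(17)
        tq = np.linspace(0.25, 120.0, 12)
        for _ in range(10):
            ps = random_parameter_set(rng)
            scen = oral_bolus()
            rk = simulate(ps, scen, t_grid=tq)
            ex = simulate(ps, scen, t_grid=tq, method="eig")
            scale = np.max(np.abs(ex.states), axis=0) + 1e-300
            assert np.max(np.abs(rk.states - ex.states) / scale) < 1e-6

    def test_mass_balance_oral(self, oral_result):
        assert mass_balance_residual(oral_result) < 1e-6

    def test_mass_balance_washoff_and_repeated(self, table2):
        washoff = ExposureScenario.single_bolus(
            "dermal", 2.0, cis_fraction=0.56, duration=240.0, washoff_time=8.0)
        res = simulate(table2, washoff)
        assert mass_balance_residual(res) < 1e-6
        assert res.washoff_amounts[0] > 0  # depot was actually removed
        repeated = ExposureScenario.repeated_oral(0.003, days=4)
        assert mass_balance_residual(simulate(table2, repeated)) < 1e-6

    def test_mass_balance_inhalation_route(self, table2):
        ps = ParameterSet(
            cis=replace(table2.cis, k_abs_inh=0.5),
            trans=replace(table2.trans, k_abs_inh=0.8),
            shared=table2.shared)
        scen = ExposureScenario.single_bolus("inhalation", 1.0, duration=300.0)
        res = simulate(ps, scen)
        assert mass_balance_residual(res) < 1e-6
        assert res.series("B_cis").max() > 0

    def test_corrupted_series_detected(self, table2):
        res = simulate(table2, oral_bolus())
        res.states[:, STATE_NAMES.index("U_transDCCA")] *= 1.5
        assert mass_balance_residual(res) > 1e-3

    def test_cumulative_series_monotone(self, oral_result):
        for name in ("U_cisDCCA", "U_transDCCA", "U_3PBA", "NO_cis",
                     "NO_trans"):
            s = oral_result.series(name)
            assert np.all(np.diff(s) >= -1e-8 * s[-1])

    def test_urinary_rate_consistent_with_cumulative(self, oral_result):
        """U must be the running integral of QU to solver accuracy."""
        t = oral_result.times
        qu = oral_result.urinary_rate("transDCCA")
        u = oral_result.cumulative_urinary("transDCCA")
        integral = np.concatenate(
            [[0.0], np.cumsum(0.5 * (qu[1:] + qu[:-1]) * np.diff(t))])
        assert np.max(np.abs(integral - u)) < 2e-4 * u[-1]

    def test_event_times_are_grid_points(self, table2):
        scen = ExposureScenario.repeated_oral(0.003, days=2)
        res = simulate(table2, scen)
        for e in scen.events:
            assert np.any(np.isclose(res.times, e.time))

    def test_states_nonnegative(self, dermal_result):
        assert dermal_result.states.min() >= 0.0


class TestKineticProperties:
    def test_slower_dermal_absorption_delays_blood_peak(self, table2):
        """Decreasing k_abs_dermal strictly delays the blood peak."""
        peaks = []
        for k in (0.2, 0.05, 0.02):
            ps = ParameterSet(cis=replace(table2.cis, k_abs_dermal=k),
                              trans=replace(table2.trans, k_abs_dermal=k),
                              shared=table2.shared)
            scen = ExposureScenario.single_bolus("dermal", 1.0, duration=400.0)
            res = simulate(ps, scen)
            b = res.series("B_trans")
            peaks.append(res.times[np.argmax(b)])
        assert peaks[0] < peaks[1] < peaks[2]

    def test_terminal_slope_reflects_storage_release(self):
        """When k_SB is much slower than everything else (and storage uptake
        is slow relative to metabolism), the terminal log-linear slope of
        the urinary rate equals k_SB within 2%."""
        from pyretk import IsomerParams, SharedParams

        iso = IsomerParams(k_abs_oral=2.0, k_abs_dermal=0.1, f_abs_oral=1.0,
                           f_abs_dermal=0.01, k_BS=0.08, k_SB=1e-3,
                           k_metabolism=10.0, k_elim=0.8, omega=2.0,
                           omega_3PBA=0.1)
        ps = ParameterSet(cis=iso, trans=iso, shared=SharedParams(k_elim_3PBA=0.5))
        scen = oral_bolus(duration=6000.0)
        res = simulate(ps, scen)
        t = res.times
        qu = res.urinary_rate("transDCCA")
        mask = (t > 2000) & (t < 5000) & (qu > 0)
        slope = -np.polyfit(t[mask], np.log(qu[mask]), 1)[0]
        assert slope == pytest.approx(1e-3, rel=0.02)

    def test_washoff_truncates_absorption(self, table2):
        base = ExposureScenario.single_bolus("dermal", 1.0, duration=600.0)
        cleaned = ExposureScenario.single_bolus("dermal", 1.0, duration=600.0,
                                                washoff_time=8.0)
        u_full = simulate(table2, base).cumulative_urinary("transDCCA")[-1]
        u_cut = simulate(table2, cleaned).cumulative_urinary("transDCCA")[-1]
        assert u_cut < 0.5 * u_full
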