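import numpy as np
import pytest

from pyretk.errors import (ConstraintError, InsufficientDataError,
                           ParameterError, UnidentifiableError, WindowError)
from pyretk.estimation import (FitMatrix, FitWindows,
                               ObservedTimeCourse, coordinate_descent_fit,
                               default_bounds, fit_dermal, grid_search_oral,
                               loglinear_rate_estimate, rank_select,
                               sensitivity_windows, windowed_sse)
from pyretk.synth import NoiseModel, fixture, generate_void_schedule, \
    synthesize_timecourse


@pytest.fixture(scope="module")
def oral_noiseless(table2):
    scen, sched = fixture("woollen_oral")
    return scen, synthesize_timecourse(table2, scen, sched,
                                       NoiseModel(cv=0.0, seed=1))


def exp_rate_timecourse(rate=0.157, duration=120.0, dt=4.0):
    """Voids whose interval-averaged rates lie exactly on e^{-rate*t_mid}."""
    starts = np.arange(0.0, duration, dt)
    mids = starts + dt / 2
    voids = np.column_stack([starts, starts + dt, np.exp(-rate * mids) * dt])
    return ObservedTimeCourse("s", "transDCCA", voids)


class TestObservedTimeCourse:
    def test_rejects_overlap_and_negative(self):
        with pytest.raises(ParameterError, match="overlap"):
            ObservedTimeCourse("s", "transDCCA",
                               [[0, 4, 1e-9], [3, 8, 1e-9]])
        with pytest.raises(ParameterError):
            ObservedTimeCourse("s", "transDCCA", [[0, 4, -1e-9]])
        with pytest.raises(ParameterError):
            ObservedTimeCourse("s", "transDCCA", [[4, 4, 1e-9]])
        with pytest.raises(ParameterError):
            ObservedTimeCourse("s", "badAnalyte", [[0, 4, 1e-9]])

    def test_sorts_voids(self):
        tc = ObservedTimeCourse("s", "transDCCA",
                                [[8, 12, 2e-9], [0, 4, 1e-9]])
        assert tc.t_start[0] == 0.0 and tc.amounts[0] == 1e-9


class TestLogLinear:
    def test_exact_exponential_recovered(self):
        tc = exp_rate_timecourse(rate=0.157)
        assert loglinear_rate_estimate(tc, (0.0, 120.0)) == pytest.approx(
            0.157, rel=1e-12)
        assert loglinear_rate_estimate(tc, (66.0, 114.0)) == pytest.approx(
            0.157, rel=1e-12)

    def test_too_few_points(self):
        tc = exp_rate_timecourse(dt=4.0)
        with pytest.raises(InsufficientDataError):
            loglinear_rate_estimate(tc, (0.0, 9.0))

    def test_terminal_slope_equals_slow_eigenvalue(self, table2,
                                                   oral_noiseless):
        """On generated data the 66-114 h slope is the slow eigenvalue of
        the blood-storage subsystem (the true terminal decay rate), which
        is k_SB scaled down by the storage branching."""
        _, tcs = oral_noiseless
        iso = table2.trans
        A2 = np.array([[-(iso.k_BS + iso.k_metabolism), iso.k_SB],
                       [iso.k_BS, -iso.k_SB]])
        slow = -np.max(np.linalg.eigvals(A2).real)
        est = loglinear_rate_estimate(tcs["transDCCA"], (66.0, 114.0))
        assert est == pytest.approx(slow, rel=0.05)

    def test_rising_profile_warns(self):
        starts = np.arange(0.0, 40.0, 4.0)
        voids = np.column_stack([starts, starts + 4,
                                 np.exp(0.05 * (starts + 2)) * 4])
        tc = ObservedTimeCourse("s", "transDCCA", voids)
        with pytest.warns(UserWarning):
            est = loglinear_rate_estimate(tc, (0.0, 40.0))
        assert est == pytest.approx(0.05, rel=1e-9)


class TestWindowedSSE:
    def test_identical_model_is_zero(self, oral_noiseless):
        _, tcs = oral_noiseless
        tc = tcs["transDCCA"]
        bounds_t = np.concatenate([tc.t_start, tc.t_end])
        cum = {}
        u_at = dict(zip(tc.t_end, tc.cumulative))
        u_at.update({tc.t_start[0]: 0.0})
        for s, e in zip(tc.t_start[1:], tc.t_end[:-1]):
            u_at.setdefault(s, u_at[e])
        u_model = lambda t: np.array([u_at[x] for x in np.atleast_1d(t)])
        assert windowed_sse(u_model, tc, None, "rate") == pytest.approx(0.0)
        assert windowed_sse(u_model, tc, None, "cumulative") == pytest.approx(0.0)

    def test_constant_rate_offset_gives_n_c_squared(self):
        tc = exp_rate_timecourse(dt=4.0, duration=40.0)
        c = 3.5e-9
        u_at = dict(zip(tc.t_end, tc.cumulative + c * 4.0 * np.arange(1, len(tc.voids) + 1)))
        u_at[tc.t_start[0]] = 0.0
        for s, e in zip(tc.t_start[1:], tc.t_end[:-1]):
            u_at.setdefault(s, u_at[e])
        u_model = lambda t: np.array([u_at[x] for x in np.atleast_1d(t)])
        n = len(tc.voids)
        assert windowed_sse(u_model, tc, None, "rate") == pytest.approx(
            n * c ** 2, rel=1e-9)

    def test_empty_window_raises(self, oral_noiseless):
        _, tcs = oral_noiseless
        with pytest.raises(WindowError, match="150"):
            windowed_sse(lambda t: np.zeros_like(np.atleast_1d(t)),
                         tcs["transDCCA"], (150.0, 200.0), "rate")

    def test_noise_sum_of_squares(self, table2):
        """Model at the generating parameters leaves exactly the injected
        noise as residual."""
        scen, sched = fixture("woollen_oral")
        clean = synthesize_timecourse(table2, scen, sched,
                                      NoiseModel(cv=0.0, seed=3))
        noisy = synthesize_timecourse(table2, scen, sched,
                                      NoiseModel(cv=0.10, seed=3))
        tc_c, tc_n = clean["transDCCA"], noisy["transDCCA"]
        u_at = dict(zip(tc_c.t_end, tc_c.cumulative))
        u_at[tc_c.t_start[0]] = 0.0
        for s, e in zip(tc_c.t_start[1:], tc_c.t_end[:-1]):
            u_at.setdefault(s, u_at[e])
        u_model = lambda t: np.array([u_at[x] for x in np.atleast_1d(t)])
        dt = tc_n.t_end - tc_n.t_start
        expected = float(((tc_n.amounts - tc_c.amounts) / dt) @
                         ((tc_n.amounts - tc_c.amounts) / dt))
        assert windowed_sse(u_model, tc_n, None, "rate") == pytest.approx(
            expected, rel=1e-9)


class TestSensitivityWindows:
    def test_published_window_structure(self, table2):
        scen, _ = fixture("woollen_oral")
        fw = sensitivity_windows(table2, scen, 0.5)
        # metabolite elimination acts on the 6-30 h rate window
        lo, hi = fw.window("k_elim")
        assert lo <= 6.0 and hi >= 30.0
        assert fw.kind("k_elim") == "rate"
        # storage release dominates the tail of the rate profile
        lo, hi = fw.window("k_SB")
        assert hi >= 114.0 and fw.kind("k_SB") == "rate"
        # storage uptake acts on the cumulative curve through 12-48 h
        lo, hi = fw.window("k_BS")
        assert lo <= 12.0 and hi >= 30.0
        assert fw.kind("k_BS") == "cumulative"
        # global parameters carry no window
        assert fw.window("k_abs_oral") is None
        assert fw.window("k_metabolism") is None

    def test_zero_perturbation_gives_no_windows(self, table2):
        scen, _ = fixture("woollen_oral")
        fw = sensitivity_windows(table2, scen, 0.0)
        assert all(w is None for w in fw.windows.values())


class TestCoordinateDescent:
    def test_noiseless_recovery_at_true_grid_point(self, table2,
                                                   oral_noiseless):
        _, tcs = oral_noiseless
        b = default_bounds(table2)
        fit = coordinate_descent_fit(
            tcs["transDCCA"], table2.trans.k_abs_oral,
            table2.trans.k_metabolism, bounds=b, f_abs=0.8)
        assert fit.k_BS == pytest.approx(table2.trans.k_BS, rel=0.01)
        assert fit.k_SB == pytest.approx(table2.trans.k_SB, rel=0.01)
        assert fit.k_elim == pytest.approx(table2.trans.k_elim, rel=0.01)
        assert fit.omega == pytest.approx(table2.trans.omega, rel=0.01)

    def test_objective_decreases_with_shared_objective(self, table2,
                                                       oral_noiseless):
        """With whole-profile (shared) objectives every coordinate step is a
        minimisation of the same function, so the combined SSE cannot
        increase across sweeps."""
        _, tcs = oral_noiseless
        b = default_bounds(table2)
        sses = []
        for sweeps in (1, 2, 3, 4):
            fit = coordinate_descent_fit(
                tcs["transDCCA"], table2.trans.k_abs_oral,
                table2.trans.k_metabolism, bounds=b, windows=None,
                f_abs=0.8, polish=False, max_sweeps=sweeps)
            sses.append(fit.sse_rate + fit.sse_cumulative)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(sses, sses[1:]))

    def test_bound_pinning_flagged(self, table2, oral_noiseless):
        """Data generated with k_BS above the allowed box pins the estimate
        at the bound and flags it."""
        from pyretk.estimation import ParameterBounds
        _, tcs = oral_noiseless
        b0 = default_bounds(table2)
        shrunk = dict(b0.bounds)
        shrunk["k_BS_trans"] = (0.1, 2.0)  # true value is 10.4
        fit = coordinate_descent_fit(
            tcs["transDCCA"], table2.trans.k_abs_oral,
            table2.trans.k_metabolism,
            bounds=ParameterBounds(bounds=shrunk), f_abs=0.8)
        assert fit.at_bound["k_BS"]
        assert fit.k_BS == pytest.approx(2.0, rel=0.01)

    def test_noisy_recovery_of_identifiable_combinations(self, table2):
        """With 5% multiplicative noise the urine-identifiable pair
        (omega, k_elim) stays well determined."""
        scen, _ = fixture("woollen_oral")
        b = default_bounds(table2)
        errs_omega, errs_kelim = [], []
        for seed in range(3):
            sched = generate_void_schedule(120.0, 4.0, 0.3, seed=100 + seed)
            tcs = synthesize_timecourse(table2, scen, sched,
                                        NoiseModel(cv=0.05, seed=seed))
            fit = coordinate_descent_fit(
                tcs["transDCCA"], table2.trans.k_abs_oral,
                table2.trans.k_metabolism, bounds=b, f_abs=0.8)
            errs_omega.append(abs(fit.omega / table2.trans.omega - 1))
            errs_kelim.append(abs(fit.k_elim / table2.trans.k_elim - 1))
        assert np.median(errs_omega) < 0.10
        assert np.median(errs_kelim) < 0.10

    def test_rate_only_and_cumulative_only_agree_noiseless(self, table2,
                                                           oral_noiseless):
        _, tcs = oral_noiseless
        b = default_bounds(table2)
        fits = {}
        for kind in ("rate", "cumulative"):
            w = FitWindows(windows={k: None for k in
                                    ("k_BS", "k_SB", "k_elim")},
                           kinds={k: kind for k in
                                  ("k_BS", "k_SB", "k_elim")})
            fits[kind] = coordinate_descent_fit(
                tcs["transDCCA"], table2.trans.k_abs_oral,
                table2.trans.k_metabolism, bounds=b, windows=w, f_abs=0.8)
        assert fits["rate"].omega == pytest.approx(
            fits["cumulative"].omega, rel=0.02)
        assert fits["rate"].k_elim == pytest.approx(
            fits["cumulative"].k_elim, rel=0.05)


class TestRankSelect:
    def _matrix(self, sse_rows, table2):
        import pandas as pd
        scen, _ = fixture("woollen_oral")
        cols = ["sse_rate_cisDCCA", "sse_cum_cisDCCA", "sse_rate_transDCCA",
                "sse_cum_transDCCA", "sse_rate_PBA3", "sse_cum_PBA3"]
        rows = []
        for i, sses in enumerate(sse_rows):
            row = {c: s for c, s in zip(cols, sses)}
            for which in ("cis", "trans"):
                iso = table2.isomer(which)
                row.update({
                    f"k_abs_oral_{which}": iso.k_abs_oral,
                    f"k_metabolism_{which}": iso.k_metabolism,
                    f"k_BS_{which}": iso.k_BS, f"k_SB_{which}": iso.k_SB,
                    f"k_elim_{which}": iso.k_elim, f"omega_{which}": iso.omega,
                    f"omega_3PBA_{which}": iso.omega_3PBA,
                })
            row["k_elim_3PBA"] = table2.shared.k_elim_3PBA
            row["row_id"] = i
            rows.append(row)
        return FitMatrix(table=pd.DataFrame(rows), template=table2,
                         scenario=scen).with_ranks()

    def test_single_row_returned(self, table2):
        fm = self._matrix([[1, 2, 3, 4, 5, 6]], table2)
        ps, row = rank_select(fm)
        assert row["row_id"] == 0

    def test_dominant_row_wins(self, table2):
        fm = self._matrix([[2, 2, 2, 2, 2, 2],
                           [1, 1, 1, 1, 1, 1],
                           [3, 3, 3, 3, 3, 3]], table2)
        _, row = rank_select(fm)
        assert row["row_id"] == 1

    def test_rank_sum_winner_beats_total_sse_winner(self, table2):
        """Row 0 wins 5 of 6 columns narrowly; row 1 wins one column by a
        landslide and has the smaller total SSE.  Rank aggregation must
        still pick row 0 (verified against scipy rankdata)."""
        from scipy.stats import rankdata
        sses = [[1.0, 1.0, 1.0, 1.0, 1.0, 100.0],
                [2.0, 2.0, 2.0, 2.0, 2.0, 1.0],
                [3.0, 3.0, 3.0, 3.0, 3.0, 50.0]]
        fm = self._matrix(sses, table2)
        arr = np.array(sses)
        rank_sums = rankdata(arr, axis=0).sum(axis=1)
        assert np.argmin(rank_sums) == 0
        assert np.argmin(arr.sum(axis=1)) == 1
        _, row = rank_select(fm)
        assert row["row_id"] == 0

    def test_rank_invariant_to_monotone_column_rescaling(self, table2):
        sses = [[1.0, 4.0, 2.0, 1.0, 5.0, 3.0],
                [2.0, 1.0, 1.0, 3.0, 2.0, 2.0],
                [3.0, 2.0, 4.0, 2.0, 1.0, 1.0]]
        fm1 = self._matrix(sses, table2)
        squared = [list(r) for r in sses]
        for r in squared:
            r[2] = r[2] ** 2  # monotone transform of one column
        fm2 = self._matrix(squared, table2)
        _, row1 = rank_select(fm1)
        _, row2 = rank_select(fm2)
        assert row1["row_id"] == row2["row_id"]
        assert (fm1.table["rank_sum"] == fm2.table["rank_sum"]).all()


class TestGridSearch:
    def test_single_point_grid_at_truth(self, table2, oral_noiseless):
        _, tcs = oral_noiseless
        b = default_bounds(table2)
        grids = {}
        for which in ("cis", "trans"):
            iso = table2.isomer(which)
            grids[f"k_abs_oral_{which}"] = [iso.k_abs_oral]
            grids[f"k_metabolism_{which}"] = [iso.k_metabolism]
        fm = grid_search_oral(tcs, bounds=b, grids=grids, template=table2)
        assert len(fm.table) == 1
        ps, row = rank_select(fm)
        # near-zero residuals and parameter recovery at the true grid point
        assert row["sse_cum_transDCCA"] < 1e-4 * (tcs["transDCCA"].amounts.sum()) ** 2
        assert ps.trans.omega == pytest.approx(table2.trans.omega, rel=0.02)
        assert ps.cis.omega == pytest.approx(table2.cis.omega, rel=0.02)
        assert ps.shared.k_elim_3PBA == pytest.approx(
            table2.shared.k_elim_3PBA, rel=0.05)

    def test_constraints_can_empty_the_grid(self, table2, oral_noiseless):
        _, tcs = oral_noiseless
        b = default_bounds(table2)
        grids = {
            "k_abs_oral_trans": [0.1], "k_metabolism_trans": [5.0],
            "k_abs_oral_cis": [0.4], "k_metabolism_cis": [10.0],
        }
        with pytest.raises(ConstraintError):
            grid_search_oral(tcs, bounds=b, grids=grids, template=table2)


class TestFitDermal:
    def test_noiseless_recovery(self, table2):
        scen, sched = fixture("woollen_dermal")
        tcs = synthesize_timecourse(table2, scen, sched,
                                    NoiseModel(cv=0.0, seed=2))
        res = fit_dermal(tcs, table2,
                         f_abs_grid=[0.005, 0.0082, 0.0125, 0.02])
        assert res["cis"]["f_abs_dermal"] == pytest.approx(0.0125)
        assert res["cis"]["k_abs_dermal"] == pytest.approx(0.033, rel=0.02)
        assert res["trans"]["f_abs_dermal"] == pytest.approx(0.0082)
        assert res["trans"]["k_abs_dermal"] == pytest.approx(0.047, rel=0.02)

    def test_scale_invariance(self, table2):
        scen, sched = fixture("woollen_dermal")
        tcs = synthesize_timecourse(table2, scen, sched,
                                    NoiseModel(cv=0.05, seed=5))
        doubled_scen = type(scen)(
            [type(e)(route=e.route, time=e.time, amount=2 * e.amount,
                     cis_fraction=e.cis_fraction,
                     washoff_time=e.washoff_time) for e in scen.events],
            scen.duration)
        doubled = {a: ObservedTimeCourse(
            tc.subject, tc.analyte,
            np.column_stack([tc.t_start, tc.t_end, 2 * tc.amounts]),
            doubled_scen, tc.incomplete)
            for a, tc in tcs.items()}
        grid = [0.005, 0.0082, 0.02]
        r1 = fit_dermal(tcs, table2, f_abs_grid=grid)
        r2 = fit_dermal(doubled, table2, f_abs_grid=grid)
        for w in ("cis", "trans"):
            assert r1[w]["f_abs_dermal"] == r2[w]["f_abs_dermal"]
            assert r1[w]["k_abs_dermal"] == pytest.approx(
                r2[w]["k_abs_dermal"], rel=1e-6)

    def test_all_zero_data_unidentifiable(self, table2):
        scen, sched = fixture("woollen_dermal")
        tcs = synthesize_timecourse(table2, scen, sched,
                                    NoiseModel(cv=0.0, seed=2))
        zeroed = {a: ObservedTimeCourse(
            tc.subject, tc.analyte,
            np.column_stack([tc.t_start, tc.t_end, 0 * tc.amounts]),
            scen, tc.incomplete) for a, tc in tcs.items()}
        with pytest.raises(UnidentifiableError):
            fit_dermal(zeroed, table2, f_abs_grid=[0.005, 0.01])
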