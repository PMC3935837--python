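"""Summary metrics of a simulation: peaks, early-excretion fractions, t50.

Peak times are refined below the grid spacing by a local quadratic fit
through the three points around the grid argmax; t50 is found by
root-finding on a monotone (PCHIP) interpolant of the cumulative curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import AsymptoteNotReachedError
from .model import SimulationResult, simulate

__all__ = ["PeakInfo", "UrinarySummary", "SummaryMetrics", "excretion_summary",
           "refine_peak", "summarize_to_plateau"]

#: relative plateau criterion over the final 10% of the grid
PLATEAU_RTOL = 1e-4


def refine_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(time, value) of the maximum, refined by a local quadratic fit."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    ts, ys = t[i - 1:i + 2], y[i - 1:i + 2]
    a, b, c = np.polyfit(ts, ys, 2)
    if a >= 0:  # flat/degenerate neighbourhood: keep the grid point
        return float(t[i]), float(y[i])
    t_star = -b / (2 * a)
    if not ts[0] <= t_star <= ts[2]:
        return float(t[i]), float(y[i])
    return float(t_star), float(a * t_star**2 + b * t_star + c)


@dataclass(frozen=True)
class PeakInfo:
    value_mol: float
    pct_of_dose: float
    time_h: float


@dataclass(frozen=True)
class UrinarySummary:
    asymptote_mol: float
    yield_pct_of_dose: float
    yield_pct_of_absorbed: float
    frac_12h: float      # fraction of total urinary recovery within 12 h
    frac_24h: float
    t50_h: float         # time to half the asymptotic recovery


@dataclass(frozen=True)
class SummaryMetrics:
    peaks: dict[str, PeakInfo] = field(default_factory=dict)
    urinary: dict[str, UrinarySummary] = field(default_factory=dict)


def _check_plateau(t: np.ndarray, u: np.ndarray, label: str) -> None:
    if u[-1] <= 0:
        return
    t_cut = t[-1] - 0.1 * (t[-1] - t[0])
    u_cut = np.interp(t_cut, t, u)
    if (u[-1] - u_cut) / u[-1] >= PLATEAU_RTOL:
        raise AsymptoteNotReachedError(
            f"cumulative {label} still rising by "
            f"{(u[-1] - u_cut) / u[-1]:.2e} (> {PLATEAU_RTOL:g}) over the final "
            "10% of the grid; simulate a longer duration"
        )


def _urinary_summary(t: np.ndarray, u: np.ndarray, dose: float,
                     absorbed: float, label: str) -> UrinarySummary:
    _check_plateau(t, u, label)
    u_inf = float(u[-1])
    if u_inf <= 0:
        nan = float("nan")
        return UrinarySummary(0.0, 0.0, 0.0, nan, nan, nan)
    interp = PchipInterpolator(t, np.maximum.accumulate(u))
    frac = lambda tq: float(interp(tq)) / u_inf if tq <= t[-1] else 1.0
    t50 = brentq(lambda x: float(interp(x)) - 0.5 * u_inf, t[0], t[-1],
                 xtol=1e-8)
    return UrinarySummary(
        asymptote_mol=u_inf,
        yield_pct_of_dose=100.0 * u_inf / dose if dose > 0 else float("nan"),
        yield_pct_of_absorbed=(100.0 * u_inf / absorbed
                               if absorbed > 0 else float("nan")),
        frac_12h=frac(12.0),
        frac_24h=frac(24.0),
        t50_h=float(t50),
    )


def excretion_summary(result: SimulationResult) -> SummaryMetrics:
    """Peaks and urinary-recovery metrics for a (plateaued) simulation.

    Raises :class:`AsymptoteNotReachedError` when any cumulative urinary
    series is still rising by more than ``PLATEAU_RTOL`` relative over the
    final 10% of the grid.
    """
    t = result.times
    dose = result.scenario.total_dose
    absorbed = result.scenario.absorbed_dose(result.params)

    peaks: dict[str, PeakInfo] = {}
    for name in ("B_cis", "B_trans", "S_cis", "S_trans",
                 "M_cisDCCA", "M_transDCCA", "M_3PBA"):
        pt, pv = refine_peak(t, result.series(name))
        peaks[name] = PeakInfo(
            value_mol=pv,
            pct_of_dose=100.0 * pv / dose if dose > 0 else float("nan"),
            time_h=pt,
        )

    urinary: dict[str, UrinarySummary] = {}
    total = np.zeros_like(t)
    for analyte in ("cisDCCA", "transDCCA", "PBA3"):
        u = result.cumulative_urinary(analyte)
        total = total + u
        urinary[analyte] = _urinary_summary(t, u, dose, absorbed, analyte)
    urinary["total"] = _urinary_summary(t, total, dose, absorbed,
                                        "total urinary metabolites")
    return SummaryMetrics(peaks=peaks, urinary=urinary)


def summarize_to_plateau(params, scenario, *, max_duration: float = 4096.0,
                         **simulate_kw) -> tuple[SummaryMetrics, SimulationResult]:
    """Summary metrics with the horizon extended until the urinary curves
    plateau (doubling the duration up to ``max_duration``)."""
    horizon = max(scenario.duration, 240.0)
    while True:
        res = simulate(params, scenario.extended(horizon), **simulate_kw)
        try:
            return excretion_summary(res), res
        except AsymptoteNotReachedError:
            if horizon >= max_duration:
                raise
            horizon = min(2.0 * horizon, max_duration)
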