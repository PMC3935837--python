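"""Synthetic urine-void time courses for testing the estimation pipeline.

Real calibration data for this model are per-void urine collections from
controlled volunteer studies: a single 3.3 mg oral cypermethrin bolus
(50:50 cis:trans) with urine collected void-by-void over 120 h, a 31 mg
dermal application (56:44) with the skin cleaned at 8 h, and dermal
permethrin designs (whole-body cream with 3 g active, 215 mg scalp
solution).  Those individual-level data are not redistributable, so this
module generates voids with the same statistical structure from the model
itself: a jittered void schedule with an optional nocturnal gap,
per-void amounts equal to the model's cumulative-excretion increments,
multiplicative lognormal noise, and occasional flagged incomplete voids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .estimation import ObservedTimeCourse
from .model import simulate
from .params import ParameterSet
from .scenario import ExposureScenario, mg_to_mol

__all__ = ["VoidSchedule", "NoiseModel", "generate_void_schedule",
           "synthesize_timecourse", "fixture", "FIXTURES"]


@dataclass(frozen=True)
class VoidSchedule:
    """Ordered, non-overlapping void intervals covering [0, duration]."""

    intervals: np.ndarray  # (n, 2) t_start, t_end in h
    duration: float

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if np.any(iv[:, 1] <= iv[:, 0]) or np.any(iv[1:, 0] < iv[:-1, 1] - 1e-9):
            raise ParameterError("void intervals must be ordered and disjoint")
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise on void amounts.

    Multiplicative lognormal noise with coefficient of variation ``cv``
    (mean-one, so totals are unbiased), plus incomplete voids: with
    probability ``incomplete_prob`` a void retains only
    ``incomplete_fraction`` of its amount and is flagged.
    """

    cv: float = 0.15
    incomplete_prob: float = 0.0
    incomplete_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ParameterError("cv must be >= 0")
        if not (0.0 <= self.incomplete_prob <= 1.0):
            raise ParameterError("incomplete_prob must lie in [0, 1]")
        if not (0.0 < self.incomplete_fraction <= 1.0):
            raise ParameterError("incomplete_fraction must lie in (0, 1]")


def generate_void_schedule(duration: float, mean_interval: float = 4.0,
                           jitter: float = 0.0, seed: int | None = None, *,
                           nocturnal_gap: bool = True,
                           night: tuple[float, float] = (23.0, 7.0),
                           start_clock: float = 8.0) -> VoidSchedule:
    """A reproducible void schedule.

    Void boundaries advance by ``mean_interval * (1 + jitter * u)`` with
    ``u ~ Uniform(-1, 1)``; with ``nocturnal_gap`` any boundary falling in
    the night span (clock hours ``night[0]``..``night[1]``) is pushed to the
    morning, producing one long overnight void per night.  ``start_clock``
    is the clock time of t = 0 (default 08:00 — controlled dosing happens in
    the morning, so the first study day is fully sampled).  ``jitter = 0``
    and ``nocturnal_gap=False`` give equal back-to-back intervals.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if mean_interval >= duration:
        raise ParameterError("mean_interval must be smaller than duration")
    if not (0.0 <= jitter < 1.0):
        raise ParameterError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    bounds = [0.0]
    t = 0.0
    while t < duration:
        step = mean_interval * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        t = t + step
        if nocturnal_gap:
            start, end = night
            abs_clock = t + start_clock
            clock = abs_clock % 24.0
            in_night = (clock >= start or clock < end) if start > end \
                else start <= clock < end
            if in_night and t < duration:
                # push the boundary to the next morning wake-up
                day = np.floor(abs_clock / 24.0)
                morning = (day + (1 if clock >= start else 0)) * 24.0 + end
                t = morning - start_clock
        bounds.append(min(t, duration))
    iv = np.column_stack([bounds[:-1], bounds[1:]])
    iv = iv[iv[:, 1] - iv[:, 0] > 1e-9]
    return VoidSchedule(intervals=iv, duration=float(duration))


def synthesize_timecourse(params: ParameterSet, scenario: ExposureScenario,
                          schedule: VoidSchedule, noise: NoiseModel,
                          subject: str = "synthetic") -> dict[str, ObservedTimeCourse]:
    """Per-void urinary amounts for all three analytes.

    Each void's amount is the model's cumulative-excretion increment
    U(t_end) - U(t_start) times a mean-one lognormal factor; incomplete
    voids retain ``noise.incomplete_fraction`` of the amount and are
    flagged.  Returns ``{analyte: ObservedTimeCourse}``.
    """
    rng = np.random.default_rng(noise.seed)
    horizon = max(scenario.duration, schedule.intervals[-1, 1])
    scen = scenario.extended(horizon) if horizon > scenario.duration else scenario
    bounds = np.unique(schedule.intervals.ravel())
    res = simulate(params, scen, t_grid=bounds, method="eig")

    if noise.cv > 0:
        sigma = float(np.sqrt(np.log1p(noise.cv ** 2)))
    else:
        sigma = 0.0

    out = {}
    for analyte in ("cisDCCA", "transDCCA", "PBA3"):
        u = np.interp(bounds, res.times, res.cumulative_urinary(analyte))
        lut = dict(zip(bounds, u))
        incr = np.array([lut[b] - lut[a] for a, b in schedule.intervals])
        n = len(incr)
        factors = (np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=n))
                   if sigma > 0 else np.ones(n))
        flags = rng.uniform(size=n) < noise.incomplete_prob
        amounts = incr * factors
        amounts[flags] *= noise.incomplete_fraction
        voids = np.column_stack([schedule.intervals, amounts])
        out[analyte] = ObservedTimeCourse(subject=subject, analyte=analyte,
                                          voids=voids, scenario=scenario,
                                          incomplete=flags)
    return out


def synthesize_cohort_average(params: ParameterSet, scenario: ExposureScenario,
                              schedule: VoidSchedule, noise: NoiseModel,
                              n_subjects: int = 6,
                              subject: str = "cohort-average",
                              ) -> dict[str, ObservedTimeCourse]:
    """Average per-void time course over a cohort of ``n_subjects``.

    The calibration data behind the bundled parameters were *average*
    urinary time courses of six volunteers; this reproduces that design:
    every subject shares the collection schedule, gets an independent noise
    realisation (seeds derived from ``noise.seed``), and the per-void
    amounts are averaged.  Incomplete-void corruption is disabled here —
    subjects with incomplete voids were excluded from the source averages.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    master = np.random.default_rng(noise.seed)
    per_subject = []
    for _ in range(n_subjects):
        sub_noise = NoiseModel(cv=noise.cv, incomplete_prob=0.0,
                               seed=int(master.integers(2 ** 31)))
        per_subject.append(synthesize_timecourse(params, scenario, schedule,
                                                 sub_noise))
    out = {}
    for analyte in ("cisDCCA", "transDCCA", "PBA3"):
        amounts = np.mean([tcs[analyte].amounts for tcs in per_subject], axis=0)
        voids = np.column_stack([schedule.intervals, amounts])
        out[analyte] = ObservedTimeCourse(subject=subject, analyte=analyte,
                                          voids=voids, scenario=scenario)
    return out


# ---------------------------------------------------------------------------
# study-design fixtures
# ---------------------------------------------------------------------------

def _woollen_oral():
    scen = ExposureScenario.single_bolus(
        "oral", mg_to_mol(3.3, "cypermethrin"), cis_fraction=0.50,
        duration=120.0)
    return scen, dict(duration=120.0, mean_interval=4.0, jitter=0.3)

def _woollen_dermal():
    scen = ExposureScenario.single_bolus(
        "dermal", mg_to_mol(31.0, "cypermethrin"), cis_fraction=0.56,
        duration=120.0, washoff_time=8.0)
    return scen, dict(duration=120.0, mean_interval=4.0, jitter=0.3)

def _tomalik_wholebody():
    scen = ExposureScenario.single_bolus(
        "dermal", mg_to_mol(3000.0, "permethrin"), cis_fraction=0.25,
        duration=168.0)
    return scen, dict(duration=168.0, mean_interval=4.0, jitter=0.3)

def _tomalik_scalp():
    scen = ExposureScenario.single_bolus(
        "dermal", mg_to_mol(215.0, "permethrin"), cis_fraction=0.25,
        duration=168.0)
    return scen, dict(duration=168.0, mean_interval=4.0, jitter=0.3)


FIXTURES = {
    "woollen_oral": _woollen_oral,
    "woollen_dermal": _woollen_dermal,
    "tomalik_wholebody": _tomalik_wholebody,
    "tomalik_scalp": _tomalik_scalp,
}


def fixture(kind: str) -> tuple[ExposureScenario, VoidSchedule]:
    """A named study-design scenario plus a default void schedule.

    ``woollen_oral``: 3.3 mg oral cypermethrin bolus, 50:50, 120 h.
    ``woollen_dermal``: 31 mg dermal, 56:44, skin cleaned at 8 h.
    ``tomalik_wholebody``: 3 g permethrin in a whole-body cream (25:75).
    ``tomalik_scalp``: 215 mg permethrin solution on the scalp (25:75).
    """
    try:
        scen, sched_kw = FIXTURES[kind]()
    except KeyError:
        raise ParameterError(
            f"unknown fixture {kind!r}; valid: {sorted(FIXTURES)}") from None
    schedule = generate_void_schedule(sched_kw["duration"],
                                      sched_kw["mean_interval"],
                                      sched_kw["jitter"], seed=0)
    return scen, schedule
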