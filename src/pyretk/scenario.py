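"""Exposure scenarios: timed dose events with isomer split and dermal wash-off.

A dose event is a bolus: at ``time`` the bioavailable part of ``amount``
(moles of total parent compound, split ``cis_fraction`` : 1-cis_fraction)
is placed in the route's input compartment as a discrete state jump.  A
dermal event may carry a ``washoff_time`` at which any parent compound still
sitting on the skin is removed (skin cleaned).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ParameterError

__all__ = [
    "ExposureEvent",
    "ExposureScenario",
    "MOLAR_MASS_G_PER_MOL",
    "mg_to_mol",
    "load_scenario",
]

ROUTES = ("oral", "dermal", "inhalation")

#: Molar masses (g/mol) for dose and analyte unit conversion.
MOLAR_MASS_G_PER_MOL = {
    "permethrin": 391.3,
    "cypermethrin": 416.3,
    "cisDCCA": 209.1,
    "transDCCA": 209.1,
    "PBA3": 214.2,
}


def mg_to_mol(amount_mg: float, compound: str) -> float:
    try:
        mm = MOLAR_MASS_G_PER_MOL[compound]
    except KeyError:
        raise ParameterError(
            f"unknown compound {compound!r}; known: {sorted(MOLAR_MASS_G_PER_MOL)}"
        ) from None
    return amount_mg * 1e-3 / mm


@dataclass(frozen=True)
class ExposureEvent:
    """One bolus dose.

    Parameters
    ----------
    route : {"oral", "dermal", "inhalation"}
    time : float
        Event time, h.
    amount : float
        Total parent compound, mol (both isomers combined).
    cis_fraction : float
        Molar fraction of the cis isomer in the dose.
    washoff_time : float or None
        Dermal only: time (h) at which the remaining skin depot is removed.
    """

    route: str
    time: float
    amount: float
    cis_fraction: float = 0.5
    washoff_time: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ParameterError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.amount < 0:
            raise ParameterError(f"amount must be >= 0, got {self.amount!r}")
        if not (0.0 <= self.cis_fraction <= 1.0):
            raise ParameterError("cis_fraction must lie in [0, 1]")
        if self.time < 0:
            raise ParameterError("event time must be >= 0")
        if self.washoff_time is not None:
            if self.route != "dermal":
                raise ParameterError("washoff_time only applies to dermal events")
            if not self.washoff_time > self.time:
                raise ParameterError("washoff_time must be later than the event time")


@dataclass(frozen=True)
class ExposureScenario:
    """An ordered list of dose events plus the total simulated duration (h)."""

    events: tuple[ExposureEvent, ...]
    duration: float

    def __init__(self, events: Iterable[ExposureEvent], duration: float):
        events = tuple(sorted(events, key=lambda e: e.time))
        if duration <= 0:
            raise ParameterError("duration must be positive")
        if events and events[-1].time > duration:
            raise ParameterError("duration must cover the last event time")
        for e in events:
            if e.washoff_time is not None and e.washoff_time > duration:
                raise ParameterError("duration must cover all wash-off times")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "duration", float(duration))

    @property
    def total_dose(self) -> float:
        """Total administered parent compound, mol."""
        return sum(e.amount for e in self.events)

    def isomer_dose(self, which: str) -> float:
        frac = {"cis": lambda e: e.cis_fraction,
                "trans": lambda e: 1.0 - e.cis_fraction}[which]
        return sum(e.amount * frac(e) for e in self.events)

    def routes(self) -> set[str]:
        return {e.route for e in self.events}

    def absorbed_dose(self, params) -> float:
        """Total bioavailable dose (mol) under ``params``.

        For dermal events this is the f_abs_dermal-scaled depot, i.e. it
        assumes the depot is fully absorbed (no wash-off truncation).
        """
        total = 0.0
        for e in self.events:
            for which, frac in (("cis", e.cis_fraction),
                                ("trans", 1.0 - e.cis_fraction)):
                iso = params.isomer(which)
                f = {"oral": iso.f_abs_oral, "dermal": iso.f_abs_dermal,
                     "inhalation": 1.0}[e.route]
                total += e.amount * frac * f
        return total

    def extended(self, duration: float) -> "ExposureScenario":
        """Same events, longer horizon."""
        return ExposureScenario(self.events, duration)

    @staticmethod
    def single_bolus(route: str, amount: float, *, cis_fraction: float = 0.5,
                     duration: float = 120.0, time: float = 0.0,
                     washoff_time: float | None = None) -> "ExposureScenario":
        return ExposureScenario(
            [ExposureEvent(route=route, time=time, amount=amount,
                           cis_fraction=cis_fraction, washoff_time=washoff_time)],
            duration=duration,
        )

    @staticmethod
    def repeated_oral(daily_amount: float, *, times_of_day: Sequence[float] = (7.5, 12.5, 18.5),
                      days: int = 10, cis_fraction: float = 0.5,
                      extra_duration: float = 0.0) -> "ExposureScenario":
        """Repeated oral dosing: ``daily_amount`` split equally over the
        listed clock times (h) for ``days`` consecutive days."""
        per_dose = daily_amount / len(times_of_day)
        events = [
            ExposureEvent(route="oral", time=24.0 * d + tod, amount=per_dose,
                          cis_fraction=cis_fraction)
            for d in range(days) for tod in times_of_day
        ]
        return ExposureScenario(events, duration=24.0 * days + extra_duration)


def _event_from_mapping(m: Mapping, index: int) -> ExposureEvent:
    if "amount_mol" in m:
        amount = float(m["amount_mol"])
    elif "amount_mg" in m:
        compound = m.get("compound")
        if compound is None:
            raise ParameterError(
                f"event {index}: amount_mg requires a 'compound' key "
                f"(one of {sorted(MOLAR_MASS_G_PER_MOL)})"
            )
        amount = mg_to_mol(float(m["amount_mg"]), compound)
    else:
        raise ParameterError(f"event {index}: needs amount_mol or amount_mg")
    return ExposureEvent(
        route=m.get("route", "oral"),
        time=float(m.get("time_h", 0.0)),
        amount=amount,
        cis_fraction=float(m.get("cis_fraction", 0.5)),
        washoff_time=(float(m["washoff_h"]) if m.get("washoff_h") is not None else None),
    )


def load_scenario(source: str | Path | Mapping) -> ExposureScenario:
    """Read a scenario from a YAML/JSON file or an already-parsed mapping.

    Format: ``{duration_h: float, events: [{route, time_h, amount_mol |
    (amount_mg + compound), cis_fraction, washoff_h}, ...]}``.
    """
    if not isinstance(source, Mapping):
        path = Path(source)
        text = path.read_text()
        source = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(source, Mapping):
            raise ParameterError(f"scenario file {path} did not parse to a mapping")
    events = [_event_from_mapping(m, i) for i, m in enumerate(source.get("events", []))]
    if "duration_h" not in source:
        raise ParameterError("scenario needs a duration_h key")
    return ExposureScenario(events, duration=float(source["duration_h"]))
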