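"""File formats: observed time-course CSV and tidy simulation output.

Time-course dialect (comma-separated, header required, UTF-8):

    subject,analyte,t_start_h,t_end_h,amount_nmol,incomplete_flag

Analytes are ``cisDCCA``, ``transDCCA``, ``PBA3``; amounts are nanomoles
(helpers convert from micrograms via the bundled molar masses); the flag is
0/1.  An optional ``unit`` column is accepted only with the value ``nmol``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import TimecourseParseError
from .estimation import ANALYTES, ObservedTimeCourse
from .model import SimulationResult
from .scenario import MOLAR_MASS_G_PER_MOL, ExposureScenario

__all__ = ["read_timecourse_csv", "write_timecourse_csv",
           "write_simulation_csv", "ug_to_nmol", "nmol_to_ug"]

_REQUIRED = ("subject", "analyte", "t_start_h", "t_end_h", "amount_nmol")


def ug_to_nmol(amount_ug: float, analyte: str) -> float:
    return amount_ug / MOLAR_MASS_G_PER_MOL[analyte] * 1e3


def nmol_to_ug(amount_nmol: float, analyte: str) -> float:
    return amount_nmol * MOLAR_MASS_G_PER_MOL[analyte] * 1e-3


def read_timecourse_csv(path: str | Path,
                        scenario: ExposureScenario | None = None,
                        ) -> dict[tuple[str, str], ObservedTimeCourse]:
    """Parse a void table into ``{(subject, analyte): ObservedTimeCourse}``.

    ``scenario`` (exposure metadata) is attached to every time course; it is
    required later for fitting but not for parsing.  Errors name the
    offending data rows (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TimecourseParseError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TimecourseParseError(f"{path}: missing columns {missing}")
    if "unit" in df.columns:
        bad = df.index[df["unit"].astype(str) != "nmol"]
        if len(bad):
            raise TimecourseParseError(
                f"{path}: unrecognised unit in rows "
                f"{[int(i) + 1 for i in bad[:5]]}; only 'nmol' is accepted")

    bad = df.index[~df["analyte"].isin(ANALYTES)]
    if len(bad):
        raise TimecourseParseError(
            f"{path}: unknown analyte in rows {[int(i) + 1 for i in bad[:5]]} "
            f"(valid: {ANALYTES})")
    bad = df.index[df["amount_nmol"] < 0]
    if len(bad):
        raise TimecourseParseError(
            f"{path}: negative amount in rows {[int(i) + 1 for i in bad[:5]]}")
    bad = df.index[df["t_end_h"] <= df["t_start_h"]]
    if len(bad):
        raise TimecourseParseError(
            f"{path}: t_end_h <= t_start_h in rows "
            f"{[int(i) + 1 for i in bad[:5]]}")

    if "incomplete_flag" not in df.columns:
        df["incomplete_flag"] = 0

    out: dict[tuple[str, str], ObservedTimeCourse] = {}
    for (subject, analyte), grp in df.groupby(["subject", "analyte"], sort=True):
        grp = grp.sort_values("t_start_h")
        overlap = grp.index[1:][
            grp["t_start_h"].to_numpy()[1:] < grp["t_end_h"].to_numpy()[:-1] - 1e-9]
        if len(overlap):
            raise TimecourseParseError(
                f"{path}: overlapping voids for subject {subject!r} / "
                f"{analyte} at rows {[int(i) + 1 for i in overlap[:5]]}")
        voids = np.column_stack([
            grp["t_start_h"].to_numpy(float), grp["t_end_h"].to_numpy(float),
            grp["amount_nmol"].to_numpy(float) * 1e-9,
        ])
        out[(str(subject), str(analyte))] = ObservedTimeCourse(
            subject=str(subject), analyte=str(analyte), voids=voids,
            scenario=scenario,
            incomplete=grp["incomplete_flag"].to_numpy().astype(bool),
        )
    return out


def write_timecourse_csv(tcs: Iterable[ObservedTimeCourse] | Mapping,
                         path: str | Path) -> None:
    """Write time courses in the documented dialect (amounts in nmol)."""
    if isinstance(tcs, Mapping):
        tcs = list(tcs.values())
    rows = []
    for tc in tcs:
        for (t0, t1, amt), flag in zip(tc.voids, tc.incomplete):
            rows.append({
                "subject": tc.subject, "analyte": tc.analyte,
                "t_start_h": float(t0), "t_end_h": float(t1),
                "amount_nmol": float(amt) * 1e9,
                "incomplete_flag": int(flag),
            })
    pd.DataFrame(rows, columns=list(_REQUIRED) + ["incomplete_flag"]
                 ).to_csv(path, index=False)


def write_simulation_csv(result: SimulationResult, path: str | Path) -> None:
    """Tidy long-format simulation output (time_h, compartment, amount_mol,
    pct_of_dose)."""
    result.to_frame().to_csv(path, index=False)
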