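"""Closed-bottle seawater respirometry arithmetic (OECD 306 style).

The degradation degree of a substance dosed at concentration ``conc``
is the measured biochemical oxygen demand relative to the theoretical
oxygen demand of complete oxidation:

    Dt(t) = 100 * BOD(t) / (ThOD * conc)

ThOD (mg O2 per mg substance) follows the ammonia-rule stoichiometry
for a CcHhOoNn compound: mol O2 = c + h/4 - o/2 - 3n/4.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ThODSpec",
    "BODSeries",
    "BiodegradationResult",
    "thod_from_formula",
    "blank_correct",
    "degradation_degree",
    "summarize_batch",
]

O2_MASS = 31.998
_ATOMIC_AVG = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}
REPORT_DAYS = (5, 10, 21)


@dataclass(frozen=True)
class ThODSpec:
    """Theoretical oxygen demand, mg O2 per mg substance.

    Zero is legal only for fully oxidised species (no demand); computing
    a degradation degree requires a strictly positive value.
    """

    value: float
    source: str = "user"  # formula | user

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("ThOD cannot be negative")


def parse_formula(formula: str) -> dict[str, int]:
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    counts: dict[str, int] = {}
    for el, num in tokens:
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def thod_from_formula(formula: str) -> ThODSpec:
    """ThOD of a CHON compound by complete-oxidation stoichiometry.

    Nitrogen is assumed to end as ammonia (no nitrification):
    mol O2 = c + h/4 - o/2 - 3n/4, clamped at zero for fully oxidised
    species such as CO2.
    """
    counts = parse_formula(formula)
    unknown = set(counts) - set(_ATOMIC_AVG)
    if unknown:
        raise ValueError(f"ThOD formula supports C/H/O/N only, got {sorted(unknown)}")
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    o = counts.get("O", 0)
    n = counts.get("N", 0)
    mol_o2 = max(c + h / 4.0 - o / 2.0 - 3.0 * n / 4.0, 0.0)
    mw = sum(_ATOMIC_AVG[el] * k for el, k in counts.items())
    return ThODSpec(value=O2_MASS * mol_o2 / mw, source="formula")


@dataclass(frozen=True)
class BODSeries:
    """A respirometric oxygen-demand time series for one bottle."""

    sample_id: str
    times: tuple[float, ...]  # days, strictly increasing
    bod: tuple[float, ...]  # mg/L
    conc: float = 100.0  # test-substance concentration, mg/L
    blank_bod: tuple[float, ...] | None = None
    inoculum: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "bod", tuple(float(b) for b in self.bod))
        if self.blank_bod is not None:
            object.__setattr__(
                self, "blank_bod", tuple(float(b) for b in self.blank_bod)
            )
        if len(self.times) != len(self.bod):
            raise ValueError("times and bod must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.conc <= 0:
            raise ValueError("concentration must be positive")
        if self.blank_bod is not None and len(self.blank_bod) != len(self.times):
            raise ValueError("blank series must share the sample time grid")


def blank_correct(series: BODSeries) -> BODSeries:
    """Subtract the blank (inoculum-only) series, clamping at zero."""
    if series.blank_bod is None:
        raise ValueError(f"{series.sample_id}: no blank series recorded")
    corrected = tuple(
        max(b - bl, 0.0) for b, bl in zip(series.bod, series.blank_bod)
    )
    return replace(series, bod=corrected, blank_bod=None)


@dataclass(frozen=True)
class BiodegradationResult:
    sample_id: str
    times: tuple[float, ...]
    dt_curve: tuple[float, ...]  # percent
    dt5: float | None
    dt10: float | None
    dt21: float | None
    inoculum: str = ""
    missing_days: tuple[int, ...] = ()


def degradation_degree(
    series: BODSeries,
    thod: ThODSpec | float,
    *,
    day_tolerance: float = 0.5,
) -> BiodegradationResult:
    """Dt(t) = 100 * BOD(t) / (ThOD * conc), with Dt5/Dt10/Dt21 read-outs.

    The day-5/10/21 values are taken from the nearest recorded time
    within ``day_tolerance`` days; missing days are reported, not
    fabricated.
    """
    if not isinstance(thod, ThODSpec):
        thod = ThODSpec(float(thod))
    if thod.value <= 0:
        raise ValueError("degradation degree needs a positive ThOD")
    denom = thod.value * series.conc
    curve = tuple(100.0 * b / denom for b in series.bod)

    times = np.asarray(series.times)
    readouts: dict[int, float | None] = {}
    missing: list[int] = []
    for day in REPORT_DAYS:
        i = int(np.argmin(np.abs(times - day)))
        if abs(times[i] - day) <= day_tolerance:
            readouts[day] = curve[i]
        else:
            readouts[day] = None
            missing.append(day)
    return BiodegradationResult(
        sample_id=series.sample_id,
        times=series.times,
        dt_curve=curve,
        dt5=readouts[5],
        dt10=readouts[10],
        dt21=readouts[21],
        inoculum=series.inoculum,
        missing_days=tuple(missing),
    )


def summarize_batch(results: Iterable[BiodegradationResult]) -> pd.DataFrame:
    """Long-form Dt table: one row per (sample, inoculum)."""
    rows = [
        {
            "sample": r.sample_id,
            "inoculum": r.inoculum,
            "Dt5": r.dt5,
            "Dt10": r.dt10,
            "Dt21": r.dt21,
        }
        for r in results
    ]
    if not rows:
        raise ValueError("no biodegradation results to summarise")
    return pd.DataFrame(rows)
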