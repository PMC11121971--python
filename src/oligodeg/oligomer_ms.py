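"""ESI-MS oligomer arithmetic: Mn/Mw/dispersity and adduct series.

For a peak list with abundances N_i at neutral masses M_i (m/z minus
the adduct mass), the number- and weight-average molecular weights and
the dispersity are

    Mn = sum(N_i M_i) / sum(N_i)
    Mw = sum(N_i M_i^2) / sum(N_i M_i)
    D  = Mw / Mn >= 1.

Sodium-adduct series of linear condensation oligomers are predicted
arithmetically: an n-mer of an alternating acyl/hydroxy composition has
neutral mass  sum(monomer masses) - (n-1) * 18.015, plus 14.027 per
methyl-ester end, plus the adduct mass for the observed m/z.  Average
masses are the default convention (unit-resolution ion trap);
monoisotopic is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from oligodeg.chemlib import (
    METHYL_END_AVG,
    METHYL_END_MONO,
    MONOMERS,
    WATER_AVG,
    WATER_MONO,
    Monomer,
)

__all__ = [
    "PeakList",
    "MassSummary",
    "AdductSeries",
    "ADDUCT_MASSES",
    "mass_summary",
    "predict_adduct_series",
    "assign_peaks",
    "floor_2dp",
]

ADDUCT_MASSES = {"Na": 22.990, "H": 1.008, "K": 39.098, "none": 0.0}


@dataclass(frozen=True)
class PeakList:
    """ESI-MS peaks as (m/z, abundance) pairs."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        peaks = tuple((float(mz), float(ab)) for mz, ab in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        if any(mz <= 0 for mz, _ in peaks):
            raise ValueError("m/z values must be positive")
        if any(ab < 0 for _, ab in peaks):
            raise ValueError("abundances must be non-negative")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @classmethod
    def from_arrays(cls, mz, abundance) -> "PeakList":
        return cls(tuple(zip(map(float, mz), map(float, abundance))))


@dataclass(frozen=True)
class MassSummary:
    Mn: float
    Mw: float
    dispersity: float


def floor_2dp(x: float) -> float:
    """Truncate (floor) to two decimals, the printing convention of the
    dispersity fixture tables."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


def mass_summary(peaks: PeakList, adduct_mass: float = 0.0) -> MassSummary:
    """Mn, Mw and dispersity of a peak list.

    ``adduct_mass`` is subtracted from every m/z so that averages are
    over neutral oligomer masses.  Zero-abundance peaks are ignored.
    """
    mz = peaks.mz
    ab = peaks.abundance
    keep = ab > 0
    if not keep.any():
        raise ValueError("no peaks with positive abundance")
    m = mz[keep] - adduct_mass
    if (m <= 0).any():
        raise ValueError("negative neutral mass after adduct subtraction")
    n = ab[keep]
    mn = float((n * m).sum() / n.sum())
    mw = float((n * m * m).sum() / (n * m).sum())
    return MassSummary(Mn=mn, Mw=mw, dispersity=mw / mn)


_END_DELTAS = {"acid_ol": 0, "methyl_ester": 1, "dimethyl_ester": 2}


@dataclass(frozen=True)
class AdductSeries:
    """Predicted m/z ladder of one oligomer family."""

    acyl_id: str
    hydroxy_id: str
    end_group: str  # acid_ol | methyl_ester | dimethyl_ester
    adduct: str  # Na | H | K | none
    mass_convention: str  # average | monoisotopic
    members: tuple[tuple[int, float], ...]  # (n_monomers, predicted m/z)

    @property
    def label(self) -> str:
        return f"{self.acyl_id}/{self.hydroxy_id} {self.end_group} [{self.adduct}]"


def _monomer_mass(m: Monomer, convention: str) -> float:
    if convention == "average":
        return m.avg_mass
    if convention == "monoisotopic":
        return m.mono_mass
    raise ValueError(f"unknown mass convention {convention!r}")


def predict_adduct_series(
    monomers: Sequence[str | Monomer],
    end_group: str = "acid_ol",
    adduct: str = "Na",
    n_max: int = 10,
    mass_convention: str = "average",
) -> AdductSeries:
    """Predict the m/z ladder of a two-monomer alternating oligomer family.

    ``monomers`` names one acyl and one hydroxy/amino monomer.  For each
    chain length n (2..n_max) the acyl/hydroxy counts split as evenly as
    possible (they can differ by at most one in a linear alternating
    chain); for odd n the acyl-rich split is used, matching series that
    carry a free or methylated acid end.
    """
    if not monomers:
        raise ValueError("empty composition")
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    if end_group not in _END_DELTAS:
        raise ValueError(f"unknown end group {end_group!r}")
    if adduct not in ADDUCT_MASSES:
        raise ValueError(f"unknown adduct {adduct!r}")

    resolved = [m if isinstance(m, Monomer) else MONOMERS[m] for m in monomers]
    acyl = [m for m in resolved if m.is_acyl]
    hydroxy = [m for m in resolved if not m.is_acyl]
    if len(acyl) != 1 or len(hydroxy) != 1:
        raise ValueError("series prediction needs exactly one acyl and one hydroxy monomer")

    water = WATER_AVG if mass_convention == "average" else WATER_MONO
    methyl = METHYL_END_AVG if mass_convention == "average" else METHYL_END_MONO
    ma = _monomer_mass(acyl[0], mass_convention)
    mh = _monomer_mass(hydroxy[0], mass_convention)
    end_delta = _END_DELTAS[end_group] * methyl
    adduct_mass = ADDUCT_MASSES[adduct]

    members = []
    for n in range(2, n_max + 1):
        n_acyl = (n + 1) // 2
        mass = n_acyl * ma + (n - n_acyl) * mh - (n - 1) * water
        members.append((n, mass + end_delta + adduct_mass))
    return AdductSeries(
        acyl_id=acyl[0].id,
        hydroxy_id=hydroxy[0].id,
        end_group=end_group,
        adduct=adduct,
        mass_convention=mass_convention,
        members=tuple(members),
    )


def assign_peaks(
    peaks: PeakList,
    candidates: Iterable[AdductSeries],
    tol_mz: float = 1.0,
) -> pd.DataFrame:
    """Match each peak to the nearest predicted series member within tolerance.

    Returns one row per peak with the best match (or none) and an
    ``ambiguous`` flag when members of two different series fall within
    the tolerance of the same peak.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be positive")
    candidates = list(candidates)
    rows = []
    for mz, ab in peaks.peaks:
        hits = []
        for series in candidates:
            for n, pred in series.members:
                err = pred - mz
                if abs(err) <= tol_mz:
                    hits.append((abs(err), series.label, n, pred))
        hits.sort()
        best = hits[0] if hits else None
        ambiguous = len({label for _, label, _, _ in hits}) > 1
        rows.append(
            {
                "mz": mz,
                "abundance": ab,
                "assigned": best is not None,
                "series": best[1] if best else None,
                "n_monomers": best[2] if best else None,
                "predicted_mz": best[3] if best else None,
                "error_mz": (best[3] - mz) if best else None,
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mz", "abundance", "assigned", "series",
            "n_monomers", "predicted_mz", "error_mz", "ambiguous",
        ],
    )
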