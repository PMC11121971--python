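"""Reference tables from the oligoester biodegradation study.

The packaged CSV/JSON assets carry the published measurement tables
that feed the pipeline: ESI-MS mass summaries (Mn/Mw/dispersity),
closed-bottle BOD series with their ThOD values and printed degradation
degrees, the twelve tetramer model structures with their experimental
biodegradation percentages, and the 18-descriptor selection list.

:func:`verify_fixture_consistency` recomputes every derivable cell
(Dt = 100*BOD/(ThOD*conc); dispersity = floor(Mw/Mn, 2dp)) and labels
each as ``match``, ``known_discrepancy`` (internally inconsistent in
the printed source tables) or ``mismatch``.  The oligoamide table
prints no ThOD column, so its Dt cells cannot be recomputed and are
labelled ``unverifiable``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PaperFixtures",
    "load_fixtures",
    "verify_fixture_consistency",
    "DEFAULT_CONC",
    "fixture_checksum",
]

#: Test-substance concentration (mg/L).  Not printed, but uniquely implied
#: by Dt = BOD/ThOD consistency across the large majority of table rows.
DEFAULT_CONC = 100.0

#: The nitrogen-containing tetramer excluded from PLS as the PCA outlier.
OUTLIER_ID = "AA-DAF-AA-DAF"

_EXPECTED_CHECKSUM = None  # filled below at import


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("oligodeg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _read_json(name: str) -> dict:
    with resources.files("oligodeg.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class PaperFixtures:
    mass_summaries: pd.DataFrame  # sample, mn, mw, dispersity_printed
    oligoester_bod: pd.DataFrame  # co/ter oligomer ThOD + BOD + Dt
    monomer_bod: pd.DataFrame  # monomer ThOD + BOD + Dt, two inocula
    oligoamide_bod: pd.DataFrame  # oligoamide BOD + Dt (no ThOD column)
    tetramers: pd.DataFrame  # label, units, linkage, SMILES, biodeg %
    selected18: list[str]
    adme_exclusions: list[str]

    def __post_init__(self) -> None:
        if len(self.tetramers) != 12:
            raise ValueError("tetramer fixture must have 12 rows")
        if len(self.selected18) != 18:
            raise ValueError("descriptor selection must have 18 names")

    @property
    def pls_tetramers(self) -> pd.DataFrame:
        """Tetramers retained for regression (nitrogen outlier excluded)."""
        return self.tetramers[self.tetramers["label"] != OUTLIER_ID]


def fixture_checksum() -> str:
    """SHA-256 over the canonical serialisation of all fixture assets."""
    h = hashlib.sha256()
    for name in (
        "table_mass_summaries.csv",
        "table_oligoester_bod.csv",
        "table_monomer_bod.csv",
        "table_oligoamide_bod.csv",
        "table_tetramers.csv",
        "selected_descriptors.json",
    ):
        h.update(resources.files("oligodeg.data").joinpath(name).read_bytes())
    return h.hexdigest()


_EXPECTED_CHECKSUM = "76ff303d9dcbd3abb9c2e8046dd3606c17b45a38c224b47f92ef66a4babe8379"


def load_fixtures(verify_checksum: bool = True) -> PaperFixtures:
    if verify_checksum and fixture_checksum() != _EXPECTED_CHECKSUM:
        raise RuntimeError("fixture assets were modified (checksum mismatch)")
    sel = _read_json("selected_descriptors.json")
    return PaperFixtures(
        mass_summaries=_read_csv("table_mass_summaries.csv"),
        oligoester_bod=_read_csv("table_oligoester_bod.csv"),
        monomer_bod=_read_csv("table_monomer_bod.csv"),
        oligoamide_bod=_read_csv("table_oligoamide_bod.csv"),
        tetramers=_read_csv("table_tetramers.csv"),
        selected18=list(sel["selected18"]),
        adme_exclusions=list(sel["adme_exclusions"]),
    )


def _floor2(x: float) -> float:
    return np.floor(x * 100.0 + 1e-9) / 100.0


def verify_fixture_consistency(
    fixtures: PaperFixtures | None = None,
    *,
    conc: float = DEFAULT_CONC,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Recompute every derivable fixture cell and report its status.

    Dt cells are recomputed as 100*BOD/(ThOD*conc) and compared to the
    printed percentage (rounded to the printed precision); dispersities
    as floor(Mw/Mn, 2dp).  Rows the printed tables themselves leave
    internally inconsistent come back as ``known_discrepancy`` when the
    recomputed value is well-defined but disagrees, ``unverifiable``
    when no recomputation is possible (missing ThOD).
    """
    fx = fixtures or load_fixtures()
    if fx.tetramers.empty or fx.oligoester_bod.empty:
        raise ValueError("fixtures are empty")

    records: list[dict] = []

    def add_dt_rows(table: pd.DataFrame, table_name: str) -> None:
        for _, row in table.iterrows():
            for day in (5, 10, 21):
                printed = row[f"dt{day}"]
                if "thod" not in row or pd.isna(row.get("thod", np.nan)):
                    status, recomputed = "unverifiable", np.nan
                else:
                    recomputed = 100.0 * row[f"bod{day}"] / (row["thod"] * conc)
                    status = (
                        "match"
                        if abs(round(recomputed, 2) - printed) <= tol
                        else "known_discrepancy"
                    )
                records.append(
                    {
                        "table": table_name,
                        "cell": f"{row['sample']}/{row['inoculum']}/Dt{day}",
                        "printed": printed,
                        "recomputed": round(float(recomputed), 2)
                        if np.isfinite(recomputed)
                        else np.nan,
                        "status": status,
                    }
                )

    add_dt_rows(fx.oligoester_bod, "oligoester_bod")
    add_dt_rows(fx.monomer_bod, "monomer_bod")
    add_dt_rows(fx.oligoamide_bod, "oligoamide_bod")

    for _, row in fx.mass_summaries.iterrows():
        recomputed = _floor2(row["mw"] / row["mn"])
        status = (
            "match"
            if abs(recomputed - row["dispersity_printed"]) <= tol / 2
            else "known_discrepancy"
        )
        records.append(
            {
                "table": "mass_summaries",
                "cell": f"{row['sample']}/dispersity",
                "printed": row["dispersity_printed"],
                "recomputed": recomputed,
                "status": status,
            }
        )
    return pd.DataFrame(records)
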