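"""Plate maps: which well received what.

A plate map assigns each well a role (vehicle / positive_control / compound /
empty), a compound identity, concentration (uM), radiation dose (Gy) and a
read-out time point (h).  It drives control matching during normalization:
every (plate, dose, time point) stratum must contain at least one vehicle
well by the time wells are normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

VALID_ROLES = ("vehicle", "positive_control", "compound", "empty")
_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")

COLUMNS = ["plate_id", "well_id", "role", "compound_id", "concentration_um", "dose_gy", "timepoint_h"]


class PlateMapError(ValueError):
    """Raised for malformed or inconsistent plate maps."""


@dataclass
class PlateMap:
    """Validated well-to-treatment table (one row per well)."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise PlateMapError(f"plate map missing column(s): {missing}")
        df = df[COLUMNS].copy()
        df["role"] = df["role"].astype(str)
        for i, row in enumerate(df.itertuples(index=False), start=1):
            if not _WELL_RE.match(str(row.well_id)):
                raise PlateMapError(f"row {i}: well id {row.well_id!r} is not in A01-H12 form")
            if row.role not in VALID_ROLES:
                raise PlateMapError(f"row {i}: unknown role {row.role!r} (valid: {VALID_ROLES})")
            if row.role != "empty":
                if pd.isna(row.dose_gy) or float(row.dose_gy) < 0:
                    raise PlateMapError(f"row {i}: dose_gy must be a number >= 0")
                if pd.isna(row.timepoint_h) or float(row.timepoint_h) < 0:
                    raise PlateMapError(f"row {i}: timepoint_h must be a number >= 0")
                conc = row.concentration_um
                if not pd.isna(conc) and float(conc) < 0:
                    raise PlateMapError(f"row {i}: concentration_um must be >= 0")
        dup = df.duplicated(subset=["plate_id", "well_id"])
        if dup.any():
            bad = df.loc[dup, ["plate_id", "well_id"]].iloc[0]
            raise PlateMapError(f"duplicate well id {bad.well_id!r} on plate {bad.plate_id!r}")
        self.wells = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def treated(self) -> pd.DataFrame:
        """Rows for wells that actually contain cells (role != empty)."""
        return self.wells[self.wells["role"] != "empty"]

    def strata(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.treated.groupby(["plate_id", "dose_gy", "timepoint_h"], sort=True)

    def require_vehicle_per_stratum(self) -> None:
        """Raise unless every (plate, dose, time) stratum has a vehicle well."""
        for key, grp in self.strata():
            if not (grp["role"] == "vehicle").any():
                raise PlateMapError(
                    f"stratum plate={key[0]!r} dose={key[1]} Gy t={key[2]} h has no vehicle well"
                )

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)


def read_platemap(path) -> PlateMap:
    """Read and validate a plate-map CSV (header required)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface the cause with context
        raise PlateMapError(f"could not read plate map {path}: {exc}") from exc
    return PlateMap(df)


def _well_name(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def zprime_platemap(
    timepoint_h: float,
    positive_compound: str,
    plate_id: str = "ZP1",
    dose_gy: float = 6.0,
    concentration_um: float = 50.0,
) -> PlateMap:
    """Z'-validation layout: columns 1-6 vehicle, columns 7-12 positive control.

    Mirrors the validation experiment of the assay: 48 vehicle wells against
    48 wells of a single positive control on one 96-well plate, all at the
    same dose and time point.
    """
    rows = []
    for r in range(8):
        for c in range(12):
            vehicle = c < 6
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": _well_name(r, c),
                    "role": "vehicle" if vehicle else "positive_control",
                    "compound_id": "DMSO" if vehicle else positive_compound,
                    "concentration_um": 0.0 if vehicle else concentration_um,
                    "dose_gy": dose_gy,
                    "timepoint_h": timepoint_h,
                }
            )
    return PlateMap(pd.DataFrame(rows))


def screen_platemap(
    compounds: list[str],
    timepoint_h: float,
    plate_id: str = "P1",
    dose_gy: float = 6.0,
    concentration_um: float = 6.25,
) -> PlateMap:
    """Screening layout: column 1 holds eight vehicle wells, the rest compounds.

    ``compounds`` fills wells column-major from column 2; remaining wells are
    marked empty.
    """
    rows = []
    it = iter(compounds)
    for c in range(12):
        for r in range(8):
            if c == 0:
                role, comp, conc = "vehicle", "DMSO", 0.0
            else:
                comp = next(it, None)
                if comp is None:
                    role, comp, conc = "empty", "", 0.0
                else:
                    role, conc = "compound", concentration_um
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": _well_name(r, c),
                    "role": role,
                    "compound_id": comp,
                    "concentration_um": conc,
                    "dose_gy": dose_gy,
                    "timepoint_h": timepoint_h,
                }
            )
    return PlateMap(pd.DataFrame(rows))
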