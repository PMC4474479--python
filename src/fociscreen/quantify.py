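"""Per-well aggregation and vehicle-control normalization.

Nuclei are pooled across the fields of a well (the analysis unit is the
~240-320 nuclei a compound contributes, not the field), and each well's mean
foci/nucleus and nuclei/field are divided by the unweighted mean over the
vehicle wells of the same (plate, dose, time point) stratum, so vehicle
wells average to a fold change of exactly 1.00 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .platemap import PlateMap

GT20_THRESHOLD = 20  # strict: a nucleus counts when foci_count > 20


class NormalizationError(ValueError):
    """Raised when a stratum lacks a usable vehicle reference."""


@dataclass(frozen=True)
class WellQuant:
    """Per-well aggregate over all analyzed nuclei."""

    well_id: str
    plate_id: str
    n_fields: int
    n_nuclei: int
    mean_foci_per_nucleus: float  # NaN when degenerate
    nuclei_per_field: float
    fraction_gt20: float  # NaN when degenerate
    mean_sub_threshold: float  # NaN when degenerate
    degenerate: bool  # zero analyzable nuclei in the well

    @property
    def usable(self) -> bool:
        return not self.degenerate


@dataclass(frozen=True)
class NormalizedScore:
    """Fold changes of one well against its matched vehicle reference."""

    well_id: str
    plate_id: str
    fold_foci: float
    fold_nuclei: float
    control_stratum: tuple  # (plate_id, dose_gy, timepoint_h)


def quantify_well(
    well_id: str,
    nucleus_counts: pd.DataFrame,
    n_fields: int,
    plate_id: str = "",
) -> WellQuant:
    """Aggregate per-nucleus counts (all fields of one well) into a WellQuant.

    ``nucleus_counts`` holds one row per analyzed nucleus with columns
    ``foci_count`` and ``sub_threshold_count``.  The mean pools nuclei
    across fields rather than averaging field means.  A well with zero
    nuclei is returned flagged as degenerate, never silently zero.
    """
    if n_fields < 1:
        raise ValueError("a well must contribute at least one field")
    n_nuclei = int(len(nucleus_counts))
    if n_nuclei == 0:
        return WellQuant(
            well_id=well_id,
            plate_id=plate_id,
            n_fields=n_fields,
            n_nuclei=0,
            mean_foci_per_nucleus=float("nan"),
            nuclei_per_field=0.0,
            fraction_gt20=float("nan"),
            mean_sub_threshold=float("nan"),
            degenerate=True,
        )
    counts = nucleus_counts["foci_count"].to_numpy(dtype=float)
    subs = nucleus_counts["sub_threshold_count"].to_numpy(dtype=float)
    return WellQuant(
        well_id=well_id,
        plate_id=plate_id,
        n_fields=n_fields,
        n_nuclei=n_nuclei,
        mean_foci_per_nucleus=float(counts.mean()),
        nuclei_per_field=n_nuclei / n_fields,
        fraction_gt20=float((counts > GT20_THRESHOLD).mean()),
        mean_sub_threshold=float(subs.mean()),
        degenerate=False,
    )


def _stratum_key(row) -> tuple:
    return (row.plate_id, float(row.dose_gy), float(row.timepoint_h))


def normalize_to_controls(
    quants: list[WellQuant],
    platemap: PlateMap,
) -> list[NormalizedScore]:
    """Normalize every usable well to the vehicle mean of its stratum.

    The vehicle reference of a (plate, dose, time point) stratum is the
    unweighted mean of ``mean_foci_per_nucleus`` over that stratum's
    non-degenerate vehicle wells (and likewise for nuclei/field).
    Degenerate (zero-nucleus) wells receive no score here; hit calling
    treats them as toxic candidates.
    """
    wells = platemap.treated.set_index(["plate_id", "well_id"])
    by_key: dict[tuple, WellQuant] = {(q.plate_id, q.well_id): q for q in quants}

    refs: dict[tuple, tuple[float, float]] = {}
    strata: dict[tuple, list[tuple]] = {}
    for (plate, well), row in wells.iterrows():
        key = (plate, float(row["dose_gy"]), float(row["timepoint_h"]))
        strata.setdefault(key, []).append((plate, well))
    for key, members in strata.items():
        vehicle_q = [
            by_key[m]
            for m in members
            if m in by_key and by_key[m].usable and wells.loc[m, "role"] == "vehicle"
        ]
        if not vehicle_q:
            raise NormalizationError(
                f"no usable vehicle well in stratum plate={key[0]!r} "
                f"dose={key[1]} Gy t={key[2]} h"
            )
        ref_foci = float(np.mean([q.mean_foci_per_nucleus for q in vehicle_q]))
        ref_nuclei = float(np.mean([q.nuclei_per_field for q in vehicle_q]))
        if ref_foci <= 0 or ref_nuclei <= 0:
            raise NormalizationError(
                f"vehicle reference is zero in stratum plate={key[0]!r} "
                f"dose={key[1]} Gy t={key[2]} h"
            )
        refs[key] = (ref_foci, ref_nuclei)

    scores: list[NormalizedScore] = []
    for q in quants:
        if not q.usable:
            continue
        row = wells.loc[(q.plate_id, q.well_id)]
        key = (q.plate_id, float(row["dose_gy"]), float(row["timepoint_h"]))
        ref_foci, ref_nuclei = refs[key]
        scores.append(
            NormalizedScore(
                well_id=q.well_id,
                plate_id=q.plate_id,
                fold_foci=q.mean_foci_per_nucleus / ref_foci,
                fold_nuclei=q.nuclei_per_field / ref_nuclei,
                control_stratum=key,
            )
        )
    return scores


def quants_to_frame(quants: list[WellQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": q.plate_id,
                "well_id": q.well_id,
                "n_fields": q.n_fields,
                "n_nuclei": q.n_nuclei,
                "mean_foci_per_nucleus": q.mean_foci_per_nucleus,
                "nuclei_per_field": q.nuclei_per_field,
                "fraction_gt20": q.fraction_gt20,
                "mean_sub_threshold": q.mean_sub_threshold,
                "degenerate": q.degenerate,
            }
            for q in quants
        ]
    )


def scores_to_frame(scores: list[NormalizedScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": s.plate_id,
                "well_id": s.well_id,
                "fold_foci": s.fold_foci,
                "fold_nuclei": s.fold_nuclei,
                "dose_gy": s.control_stratum[1],
                "timepoint_h": s.control_stratum[2],
            }
            for s in scores
        ]
    )
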