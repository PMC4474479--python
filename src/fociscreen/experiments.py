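"""Canned validation experiments of the assay.

These reproduce, in silico, the studies that established the screen:

* the Z'-factor validation plates (48 vehicle vs 48 positive-control wells,
  CGK733-like formation suppression at 2 h, etoposide-like persistence at
  24 h, 4 fields/well),
* the operating-point characterization (detected foci/nucleus and the >20-
  foci tail in vehicle wells at 6 Gy),
* planted-effect parameter recovery and the four exemplar phenotype calls
  (formation suppressor, persistence enhancer, sub-threshold small-foci
  artifact, toxicity).

Each function runs the *full* pipeline — simulation, segmentation, focus
detection, per-well aggregation, control normalization — under the default
calibration, so their numbers are end-to-end measurements, not shortcuts
through the ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import CALL_PERSISTENCE, CALL_SUPPRESSOR, CALL_TOXIC
from .params import CONTROL_EFFECTS, DrugEffect, KineticsParams, RenderParams
from .pipeline import ScreenResult, analyze_simulated_screen
from .platemap import PlateMap, zprime_platemap
from .qc import ZPrimeResult, compute_zprime
from .simulate import expected_foci

ZPRIME_POSITIVES = {2.0: "CGK733", 24.0: "etoposide_25uM"}
RECOVERY_SCALES = (0.25, 0.5, 1.0, 1.5, 2.0)


def zprime_experiment(
    timepoint_h: float,
    seed: int,
    render: RenderParams | None = None,
    kinetics: KineticsParams | None = None,
) -> tuple[ZPrimeResult, ScreenResult]:
    """Simulate and score one Z'-validation plate (48/48 wells, 4 fields)."""
    positive = ZPRIME_POSITIVES[float(timepoint_h)]
    pm = zprime_platemap(timepoint_h, positive, plate_id=f"ZP{timepoint_h:g}h")
    result = analyze_simulated_screen(
        pm, kinetics=kinetics, effects_by_compound=CONTROL_EFFECTS, render=render, seed=seed
    )
    neg = result.folds_by_role("vehicle")
    pos = result.folds_by_role("positive_control")
    return compute_zprime(neg, pos), result


def vehicle_operating_point(result: ScreenResult) -> dict:
    """Pooled vehicle-well read-out: mean foci/nucleus and the >20-foci tail."""
    wells = result.platemap.treated
    keys = set(
        map(tuple, wells.loc[wells["role"] == "vehicle", ["plate_id", "well_id"]].to_numpy())
    )
    nc = result.nucleus_counts
    sel = nc[[(p, w) in keys for p, w in zip(nc["plate_id"], nc["well_id"])]]
    counts = sel["foci_count"].to_numpy(dtype=float)
    return {
        "mean_foci_per_nucleus": float(counts.mean()),
        "n_nuclei": int(len(counts)),
        "pct_gt20": float(100.0 * (counts > 20).mean()),
    }


def _recovery_platemap(plate_id: str) -> PlateMap:
    """One replicate plate: planted fold effects at 24 h plus the four
    exemplar phenotypes in their native strata (2 h and 24 h)."""
    wells = [f"{r}{c:02d}" for c in range(1, 13) for r in "ABCDEFGH"]
    rows, i = [], 0

    def add(role, comp, tp, n=1):
        nonlocal i
        for _ in range(n):
            rows.append(
                dict(
                    plate_id=plate_id,
                    well_id=wells[i],
                    role=role,
                    compound_id=comp,
                    concentration_um=0.0 if role == "vehicle" else 50.0,
                    dose_gy=6.0,
                    timepoint_h=tp,
                )
            )
            i += 1

    add("vehicle", "DMSO", 24.0, n=4)
    for s in RECOVERY_SCALES:
        add("compound", f"scale_{s:g}", 24.0)
    add("compound", "etoposide_6.25uM", 24.0)
    add("compound", "toxic_reference", 24.0)
    add("vehicle", "DMSO", 2.0, n=4)
    add("compound", "CGK733", 2.0)
    add("compound", "topotecan", 2.0)
    return PlateMap(pd.DataFrame(rows))


#: expected call for each exemplar phenotype
PHENOTYPE_EXPECTED = {
    "CGK733": CALL_SUPPRESSOR,
    "etoposide_6.25uM": CALL_PERSISTENCE,
    "topotecan": CALL_SUPPRESSOR,
    "toxic_reference": CALL_TOXIC,
}


def recovery_experiment(
    n_replicates: int,
    seed: int,
    kinetics: KineticsParams | None = None,
    render: RenderParams | None = None,
) -> dict:
    """Planted-effect recovery and phenotype calling over seeded replicates.

    Returns ``{"recovery": DataFrame, "phenotypes": DataFrame}``: per-scale
    recovered folds with their analytic expectations, and the per-replicate
    call for each exemplar phenotype.
    """
    kinetics = kinetics or KineticsParams()
    effects = dict(CONTROL_EFFECTS)
    for s in RECOVERY_SCALES:
        effects[f"scale_{s:g}"] = DrugEffect(formation_scale=s)
    lam = expected_foci(6.0, 24.0, kinetics)
    expected_fold = {
        s: (s * (lam - kinetics.baseline_mean) + kinetics.baseline_mean) / lam
        for s in RECOVERY_SCALES
    }
    rec_rows, phen_rows = [], []
    for rep in range(n_replicates):
        pm = _recovery_platemap(f"REC{rep}")
        result = analyze_simulated_screen(
            pm, kinetics=kinetics, effects_by_compound=effects, render=render,
            seed=seed * 1000 + rep,
        )
        info = pm.treated.set_index("well_id")
        fold_by_comp = {
            info.loc[s.well_id, "compound_id"]: s.fold_foci for s in result.scores
        }
        for s in RECOVERY_SCALES:
            rec_rows.append(
                {
                    "replicate": rep,
                    "formation_scale": s,
                    "expected_fold": expected_fold[s],
                    "recovered_fold": fold_by_comp[f"scale_{s:g}"],
                }
            )
        for c in result.calls:
            comp = c.compound_id
            if comp in PHENOTYPE_EXPECTED:
                phen_rows.append(
                    {
                        "replicate": rep,
                        "phenotype": comp,
                        "expected_call": PHENOTYPE_EXPECTED[comp],
                        "call": c.call,
                        "fold_foci": c.fold_foci,
                        "fold_nuclei": c.fold_nuclei,
                        "flags": ";".join(sorted(c.flags)),
                    }
                )
    return {"recovery": pd.DataFrame(rec_rows), "phenotypes": pd.DataFrame(phen_rows)}


def recovery_bias_table(recovery: pd.DataFrame) -> pd.DataFrame:
    """Mean recovered fold and relative bias per planted scale."""
    out = (
        recovery.groupby("formation_scale")
        .agg(
            expected_fold=("expected_fold", "first"),
            mean_recovered=("recovered_fold", "mean"),
            sd_recovered=("recovered_fold", "std"),
            n=("recovered_fold", "size"),
        )
        .reset_index()
    )
    out["rel_bias_pct"] = 100.0 * (out["mean_recovered"] - out["expected_fold"]) / out["expected_fold"]
    return out


def operating_point_experiment(
    timepoint_h: float,
    seed: int,
    n_wells: int = 3,
    kinetics: KineticsParams | None = None,
    render: RenderParams | None = None,
) -> dict:
    """Triplicate vehicle wells at 6 Gy pushed through the full pipeline."""
    wells = [f"A{c:02d}" for c in range(1, n_wells + 1)]
    pm = PlateMap(
        pd.DataFrame(
            [
                dict(
                    plate_id=f"OP{timepoint_h:g}h",
                    well_id=w,
                    role="vehicle",
                    compound_id="DMSO",
                    concentration_um=0.0,
                    dose_gy=6.0,
                    timepoint_h=timepoint_h,
                )
                for w in wells
            ]
        )
    )
    result = analyze_simulated_screen(
        pm, kinetics=kinetics, effects_by_compound=CONTROL_EFFECTS, render=render, seed=seed
    )
    return vehicle_operating_point(result)
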