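"""End-to-end drivers: segment -> detect -> quantify -> normalize -> call.

Two entry points: :func:`analyze_simulated_screen` streams simulator output
through the analysis chain fully in memory (used for validation studies and
the QC experiments), while :func:`run_pipeline` is the file-based driver the
CLI wraps (TIFF images + plate-map CSV in, CSV tables + manifest out).
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calls import ScreenScore, call_hit, scores_to_frame as calls_to_frame, summarize_screen
from .detect import FocusRecord, detect_foci, foci_per_nucleus, foci_to_frame
from .params import (
    DetectionParams,
    DrugEffect,
    HitCriteria,
    KineticsParams,
    RenderParams,
    SegmentationParams,
)
from .platemap import PlateMap
from .quantify import (
    NormalizedScore,
    WellQuant,
    normalize_to_controls,
    quantify_well,
    quants_to_frame,
    scores_to_frame,
)
from .segment import NucleusRecord, records_to_frame, segment_nuclei
from .simulate import FieldImage, NUCLEAR_CHANNEL, REPORTER_CHANNEL, iter_simulated_fields

log = logging.getLogger("fociscreen")

_FILE_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-H]\d{2})_s(?P<field>\d+)_(?P<channel>\w+)\.tif$")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and well context."""


@dataclass
class FieldAnalysis:
    """Everything measured in one field."""

    labels: np.ndarray
    nuclei: list[NucleusRecord]
    foci: list[FocusRecord]
    sub_threshold: dict[int, int]
    table: pd.DataFrame  # nucleus_label, foci_count, sub_threshold_count, touches_border


def analyze_field(
    image: FieldImage,
    seg_params: SegmentationParams | None = None,
    det_params: DetectionParams | None = None,
) -> FieldAnalysis:
    """Segment one field's nuclei and detect foci within them."""
    seg_params = seg_params or SegmentationParams()
    det_params = det_params or DetectionParams()
    labels, nuclei = segment_nuclei(image.nuclear, image.pixel_size, seg_params)
    foci, subs = detect_foci(image.reporter, labels, det_params)
    table = foci_per_nucleus(foci, nuclei)
    table["sub_threshold_count"] = table["nucleus_label"].map(subs).fillna(0).astype(int)
    border = {n.label: n.touches_border for n in nuclei}
    table["touches_border"] = table["nucleus_label"].map(border)
    return FieldAnalysis(labels=labels, nuclei=nuclei, foci=foci, sub_threshold=subs, table=table)


@dataclass
class ScreenResult:
    """Aggregated outcome of a whole plate set."""

    platemap: PlateMap
    quants: list[WellQuant]
    scores: list[NormalizedScore]
    calls: list[ScreenScore]
    nucleus_counts: pd.DataFrame  # per-nucleus rows across all wells

    def folds_by_role(self, role: str, timepoint_h: float | None = None) -> np.ndarray:
        """Per-well fold_foci values of all wells with the given plate-map role."""
        wells = self.platemap.treated
        sel = wells["role"] == role
        if timepoint_h is not None:
            sel &= wells["timepoint_h"] == timepoint_h
        keys = set(map(tuple, wells.loc[sel, ["plate_id", "well_id"]].to_numpy()))
        return np.array(
            [s.fold_foci for s in self.scores if (s.plate_id, s.well_id) in keys], dtype=float
        )


def _finalize_screen(
    platemap: PlateMap,
    well_tables: dict[tuple[str, str], list[pd.DataFrame]],
    fields_per_well: int,
    seg_params: SegmentationParams,
    criteria: HitCriteria,
) -> ScreenResult:
    quants, all_rows = [], []
    for row in platemap.treated.itertuples(index=False):
        key = (row.plate_id, row.well_id)
        tables = well_tables.get(key, [])
        tbl = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
            columns=["nucleus_label", "foci_count", "sub_threshold_count", "touches_border", "field"]
        )
        if seg_params.exclude_border and len(tbl):
            tbl = tbl[~tbl["touches_border"].astype(bool)]
        quants.append(quantify_well(row.well_id, tbl, fields_per_well, plate_id=row.plate_id))
        if len(tbl):
            out = tbl.copy()
            out.insert(0, "well_id", row.well_id)
            out.insert(0, "plate_id", row.plate_id)
            all_rows.append(out)
    scores = normalize_to_controls(quants, platemap)
    score_by_well = {(s.plate_id, s.well_id): s for s in scores}
    wellinfo = platemap.treated.set_index(["plate_id", "well_id"])
    calls = []
    for q in quants:
        info = wellinfo.loc[(q.plate_id, q.well_id)]
        calls.append(
            call_hit(
                score_by_well.get((q.plate_id, q.well_id)),
                q,
                criteria,
                compound_id=str(info["compound_id"]),
                concentration_um=float(info["concentration_um"]),
                timepoint_h=float(info["timepoint_h"]),
            )
        )
    nucleus_counts = (
        pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    )
    return ScreenResult(
        platemap=platemap, quants=quants, scores=scores, calls=calls, nucleus_counts=nucleus_counts
    )


def analyze_simulated_screen(
    platemap: PlateMap,
    kinetics: KineticsParams | None = None,
    effects_by_compound: dict[str, DrugEffect] | None = None,
    render: RenderParams | None = None,
    seg_params: SegmentationParams | None = None,
    det_params: DetectionParams | None = None,
    criteria: HitCriteria | None = None,
    fields_per_well: int = 4,
    seed: int | None = None,
) -> ScreenResult:
    """Simulate every well of ``platemap`` and push it through the pipeline."""
    kinetics = kinetics or KineticsParams()
    render = render or RenderParams()
    seg_params = seg_params or SegmentationParams()
    det_params = det_params or DetectionParams()
    criteria = criteria or HitCriteria()
    effects_by_compound = effects_by_compound or {}
    well_tables: dict[tuple[str, str], list[pd.DataFrame]] = {}
    for row, f_idx, image, _gt in iter_simulated_fields(
        platemap, kinetics, effects_by_compound, render, fields_per_well, seed
    ):
        fa = analyze_field(image, seg_params, det_params)
        tbl = fa.table
        tbl["field"] = f_idx
        well_tables.setdefault((row.plate_id, row.well_id), []).append(tbl)
    return _finalize_screen(platemap, well_tables, fields_per_well, seg_params, criteria)


def iter_image_fields(images_dir, platemap: PlateMap):
    """Yield (well_row, field_index, FieldImage) from a directory of TIFFs."""
    images_dir = Path(images_dir)
    by_key: dict[tuple[str, str, int], dict[str, Path]] = {}
    for p in sorted(images_dir.glob("*.tif")):
        m = _FILE_RE.match(p.name)
        if not m:
            continue
        key = (m["plate"], m["well"], int(m["field"]))
        by_key.setdefault(key, {})[m["channel"]] = p
    for row in platemap.treated.itertuples(index=False):
        fields = sorted(f for (p, w, f) in by_key if p == row.plate_id and w == row.well_id)
        for f_idx in fields:
            chans = by_key[(row.plate_id, row.well_id, f_idx)]
            if NUCLEAR_CHANNEL not in chans or REPORTER_CHANNEL not in chans:
                raise PipelineError(
                    f"stage=read well={row.well_id}: field {f_idx} is missing a channel "
                    f"(found {sorted(chans)})"
                )
            yield row, f_idx, FieldImage(
                nuclear=tifffile.imread(chans[NUCLEAR_CHANNEL]),
                reporter=tifffile.imread(chans[REPORTER_CHANNEL]),
                pixel_size=float("nan"),  # overwritten by caller's config
            )


def analyze_image_screen(
    images_dir,
    platemap: PlateMap,
    pixel_size: float,
    seg_params: SegmentationParams | None = None,
    det_params: DetectionParams | None = None,
    criteria: HitCriteria | None = None,
) -> ScreenResult:
    """Run the analysis chain on images already on disk."""
    seg_params = seg_params or SegmentationParams()
    det_params = det_params or DetectionParams()
    criteria = criteria or HitCriteria()
    well_tables: dict[tuple[str, str], list[pd.DataFrame]] = {}
    n_fields_seen: dict[tuple[str, str], int] = {}
    for row, f_idx, image in iter_image_fields(images_dir, platemap):
        image.pixel_size = pixel_size
        try:
            fa = analyze_field(image, seg_params, det_params)
        except Exception as exc:
            raise PipelineError(
                f"stage=analyze well={row.well_id} field={f_idx}: {exc}"
            ) from exc
        tbl = fa.table
        tbl["field"] = f_idx
        key = (row.plate_id, row.well_id)
        well_tables.setdefault(key, []).append(tbl)
        n_fields_seen[key] = n_fields_seen.get(key, 0) + 1
    counts = set(n_fields_seen.values())
    fields_per_well = max(counts) if counts else 0
    if fields_per_well == 0:
        raise PipelineError("stage=read: no images matched the plate map")
    return _finalize_screen(platemap, well_tables, fields_per_well, seg_params, criteria)


def write_screen_outputs(result: ScreenResult, out_dir, manifest_extra: dict | None = None) -> dict:
    """Write all CSV outputs plus a reproducibility manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "well_quant": out / "well_quant.csv",
        "normalized_scores": out / "normalized_scores.csv",
        "screen_scores": out / "screen_scores.csv",
        "screen_summary": out / "screen_summary.csv",
        "nucleus_counts": out / "nucleus_counts.csv",
        "manifest": out / "manifest.json",
    }
    quants_to_frame(result.quants).to_csv(paths["well_quant"], index=False)
    scores_to_frame(result.scores).to_csv(paths["normalized_scores"], index=False)
    calls_to_frame(result.calls).to_csv(paths["screen_scores"], index=False)
    summary = summarize_screen(result.calls)
    pd.DataFrame(
        [
            {
                "n_scored": summary.n_scored,
                "n_persistence": summary.n_persistence,
                "n_suppressor": summary.n_suppressor,
                "n_toxic": summary.n_toxic,
                "n_none": summary.n_none,
                "hit_rate_pct": summary.hit_rate_pct,
            }
        ]
    ).to_csv(paths["screen_summary"], index=False)
    result.nucleus_counts.to_csv(paths["nucleus_counts"], index=False)
    manifest = {"fociscreen_version": __version__, "n_wells": len(result.quants)}
    manifest.update(manifest_extra or {})
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config, out_dir=None) -> dict:
    """All-in-one driver from a :class:`~fociscreen.config.RunConfig`.

    Simulates the plate set when ``config.simulate`` is set (writing images
    only if ``config.write_images``), analyzes every field, and writes the
    full CSV/manifest artifact directory.  Any stage error aborts with the
    stage name and well context in the message.
    """
    from .config import RunConfig  # local import to avoid a cycle

    assert isinstance(config, RunConfig)
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    platemap = config.load_platemap()
    if config.simulate:
        if config.write_images:
            from .simulate import simulate_plate

            simulate_plate(
                platemap, config.kinetics, config.effects, config.render,
                out / "images", config.fields_per_well, config.seed,
            )
            result = analyze_image_screen(
                out / "images", platemap, config.render.pixel_size,
                config.segmentation, config.detection, config.criteria,
            )
        else:
            result = analyze_simulated_screen(
                platemap, config.kinetics, config.effects, config.render,
                config.segmentation, config.detection, config.criteria,
                config.fields_per_well, config.seed,
            )
    else:
        if config.images_dir is None:
            raise PipelineError("stage=config: images_dir required when simulate is false")
        result = analyze_image_screen(
            config.images_dir, platemap, config.detection.pixel_size,
            config.segmentation, config.detection, config.criteria,
        )
    paths = write_screen_outputs(
        result, out, manifest_extra={"seed": config.seed, "config": config.echo()}
    )
    log.info("pipeline finished in %.1f s: %d wells", time.time() - t0, len(result.quants))
    return paths
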