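"""Synthetic two-channel plate simulator with known ground truth.

Emulates the screening assay: Hoechst-stained nuclei in one channel and a
GFP reporter that relocalizes into radiation-induced foci in the other.  The
per-nucleus mean focus count follows a saturating-induction, biexponential-
resolution kinetic model (:func:`expected_foci`); per-cell heterogeneity is a
gamma-mixed Poisson; drug action enters as multiplicative scales on
formation, slow-phase resolution rate, rendered focus width, and nucleus
survival.

Foci are placed inside each nucleus with a hard-core minimum separation tied
to their rendered size: IRIF are discrete chromatin domains, and modelling
them as mutually exclusive keeps detected counts close to true counts, which
is what makes the screen's fold-change read-out approximately linear.

Reproducibility contract: one root seed; the stream for each field is derived
by stable hashing of (plate, well, field), so wells are independent and the
output does not depend on simulation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd
import tifffile

from .params import DrugEffect, IDENTITY_EFFECT, KineticsParams, RenderParams
from .platemap import PlateMap

_PLACEMENT_TRIES = 300
_FOCUS_TRIES = 80
#: gray-level reference used when sizing the repulsion radius of a focus
_NOMINAL_DETECT_LEVEL = 50.0

NUCLEAR_CHANNEL = "hoechst"
REPORTER_CHANNEL = "gfp"


class SimulationError(RuntimeError):
    """Raised when a field cannot be realized under its constraints."""


def expected_foci(
    dose: float,
    time_h: float,
    kinetics: KineticsParams,
    effect: DrugEffect = IDENTITY_EFFECT,
) -> float:
    """Mean true foci per nucleus at ``dose`` Gy and ``time_h`` hours post-IR.

    lambda(D, t) = s_form * A * D / (1 + D / D_sat)
                   * [f * exp(-t / tau_f) + (1 - f) * exp(-t * s_slow / tau_s)]
                   + baseline

    where ``s_form`` is the drug's formation scale and ``s_slow`` multiplies
    the slow resolution *rate* 1 / tau_s.  At ``dose == 0`` this is exactly
    the unirradiated baseline.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if time_h < 0:
        raise ValueError(f"time must be >= 0, got {time_h}")
    induced = kinetics.amplitude_per_gy * dose / (1.0 + dose / kinetics.saturation_dose)
    f = kinetics.fast_fraction
    decay = f * math.exp(-time_h / kinetics.tau_fast) + (1.0 - f) * math.exp(
        -time_h * effect.slow_resolution_scale / kinetics.tau_slow
    )
    return effect.formation_scale * induced * decay + kinetics.baseline_mean


@dataclass
class FieldImage:
    """One imaged field: co-registered nuclear and reporter rasters (uint16)."""

    nuclear: np.ndarray
    reporter: np.ndarray
    pixel_size: float  # um / px


@dataclass
class FieldGroundTruth:
    """True nucleus footprints and focus placements for one field."""

    nuclei: pd.DataFrame  # nucleus_id, y, x, semi_major_px, semi_minor_px, angle_rad, area_px
    foci: pd.DataFrame  # nucleus_id, y, x, width_fwhm_um, amplitude, subthreshold

    @property
    def foci_per_nucleus(self) -> pd.Series:
        counts = self.foci.groupby("nucleus_id").size()
        return counts.reindex(self.nuclei["nucleus_id"], fill_value=0)


def field_rng(seed: int, plate_id: str, well_id: str, field_index: int) -> np.random.Generator:
    """Independent, order-insensitive random stream for one (plate, well, field)."""
    entropy = [
        int(seed) & 0x7FFFFFFF,
        crc32(str(plate_id).encode()) & 0x7FFFFFFF,
        crc32(str(well_id).encode()) & 0x7FFFFFFF,
        int(field_index) & 0x7FFFFFFF,
    ]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


def _ellipse_patch(cy, cx, a, b, theta, shape):
    """Boolean patch and its slice for an ellipse; None if out of bounds."""
    r = int(math.ceil(max(a, b))) + 1
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
        return None, None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    return inside, (slice(y0, y1), slice(x0, x1))


def _place_nuclei(n: int, render: RenderParams, rng: np.random.Generator):
    """Dart-throw non-overlapping ellipses (touching allowed), fully interior."""
    shape = render.image_shape
    occupancy = np.zeros(shape, dtype=bool)
    area_px_mean = render.nucleus_area_mean / render.pixel_size**2
    sigma_ln = math.sqrt(math.log(1.0 + render.nucleus_area_cv**2))
    mu_ln = math.log(area_px_mean) - 0.5 * sigma_ln**2
    nuclei = []
    for nucleus_id in range(1, n + 1):
        placed = False
        for _ in range(_PLACEMENT_TRIES):
            area = rng.lognormal(mu_ln, sigma_ln)
            aspect = rng.uniform(0.70, 0.95)
            a = math.sqrt(area / (math.pi * aspect))
            b = aspect * a
            theta = rng.uniform(0.0, math.pi)
            r = a + 2.0
            if 2 * r >= min(shape):
                continue
            cy = rng.uniform(r, shape[0] - 1 - r)
            cx = rng.uniform(r, shape[1] - 1 - r)
            patch, sl = _ellipse_patch(cy, cx, a, b, theta, shape)
            if patch is None or not patch.any():
                continue
            if occupancy[sl][patch].any():
                continue
            occupancy[sl][patch] = True
            nuclei.append(
                {
                    "nucleus_id": nucleus_id,
                    "y": cy,
                    "x": cx,
                    "semi_major_px": a,
                    "semi_minor_px": b,
                    "angle_rad": theta,
                    "area_px": int(patch.sum()),
                    "_patch": patch,
                    "_slice": sl,
                }
            )
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"could not place nucleus {nucleus_id}/{n} without overlap after "
                f"{_PLACEMENT_TRIES} tries: field too crowded for "
                f"nucleus_area_mean={render.nucleus_area_mean} um^2 on a "
                f"{shape[0]}x{shape[1]} px field"
            )
    return nuclei, occupancy


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.log(mean) - 0.5 * sigma * sigma, sigma


def _draw_counts(lam: float, n: int, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-mixed Poisson counts: Var = lam * (1 + dispersion)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if lam <= 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion > 0:
        rates = rng.gamma(shape=lam / dispersion, scale=dispersion, size=n)
    else:
        rates = np.full(n, lam)
    return rng.poisson(rates)


def _footprint_diameter(amplitude: float, sigma_eff_px: float) -> float:
    """Expected at-threshold component diameter of a rendered Gaussian spot."""
    ratio = max(amplitude / _NOMINAL_DETECT_LEVEL, 1.3)
    return 2.0 * sigma_eff_px * math.sqrt(2.0 * math.log(ratio))


def _place_foci_in_nucleus(nucleus, n_foci, widths_um, amplitudes, render, rng):
    """Sample focus centers uniformly in the ellipse with hard-core repulsion."""
    if n_foci == 0:
        return np.zeros((0, 2))
    pad = 1.5
    a = max(nucleus["semi_major_px"] - pad, 1.0)
    b = max(nucleus["semi_minor_px"] - pad, 1.0)
    ct, st = math.cos(nucleus["angle_rad"]), math.sin(nucleus["angle_rad"])
    psf_px = render.psf_sigma / render.pixel_size
    diams = np.empty(n_foci)
    for i in range(n_foci):
        sig = widths_um[i] / 2.355 / render.pixel_size
        diams[i] = _footprint_diameter(amplitudes[i], math.hypot(sig, psf_px))
    centers = np.empty((n_foci, 2))
    for i in range(n_foci):
        best = None
        best_clearance = -np.inf
        for _ in range(_FOCUS_TRIES):
            rad = math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            u, v = rad * math.cos(phi) * a, rad * math.sin(phi) * b
            y = nucleus["y"] + u * st + v * ct
            x = nucleus["x"] + u * ct - v * st
            if i == 0:
                best = (y, x)
                break
            d = np.hypot(centers[:i, 0] - y, centers[:i, 1] - x)
            required = (diams[:i] + diams[i]) / 2.0 + 1.5
            clearance = float(np.min(d - required))
            if clearance >= 0.0:
                best = (y, x)
                break
            if clearance > best_clearance:
                best_clearance = clearance
                best = (y, x)
        centers[i] = best
    return centers


def _add_gaussian_spot(img, y, x, amplitude, sigma):
    r = int(math.ceil(4.0 * sigma))
    y0 = max(int(round(y)) - r, 0)
    y1 = min(int(round(y)) + r + 1, img.shape[0])
    x0 = max(int(round(x)) - r, 0)
    x1 = min(int(round(x)) + r + 1, img.shape[1])
    if y1 <= y0 or x1 <= x0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma * sigma)
    )


def _quantize(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def simulate_field(
    dose: float,
    time_h: float,
    kinetics: KineticsParams,
    effect: DrugEffect,
    render: RenderParams,
    rng: np.random.Generator,
) -> tuple[FieldImage, FieldGroundTruth]:
    """Render one two-channel field and return it with its ground truth."""
    from scipy.ndimage import gaussian_filter

    lo, hi = render.nucleus_count_range
    n_seeded = int(rng.integers(lo, hi + 1))
    n = int(rng.binomial(n_seeded, effect.survival_fraction)) if effect.survival_fraction < 1.0 else n_seeded
    nuclei, _ = _place_nuclei(n, render, rng)

    shape = render.image_shape
    psf_px = render.psf_sigma / render.pixel_size
    nuclear = np.full(shape, float(render.background_level))
    diffuse = np.full(shape, float(render.background_level))
    for nuc in nuclei:
        patch, sl = nuc["_patch"], nuc["_slice"]
        nuclear[sl][patch] += render.nucleus_stain_level * rng.normal(1.0, 0.08)
        diffuse[sl][patch] += render.reporter_nuclear_level * rng.normal(1.0, 0.10)
    if psf_px > 0:
        nuclear = gaussian_filter(nuclear, psf_px)
        diffuse = gaussian_filter(diffuse, psf_px)

    lam = expected_foci(dose, time_h, kinetics, effect)
    counts = _draw_counts(lam, n, render.dispersion, rng)
    p_small = render.subthreshold_fraction(time_h)
    width_mean = render.focus_width_mean(time_h) * effect.width_scale
    mu_w, sig_w = _lognormal_params(max(width_mean, 1e-3), render.focus_width_cv)
    mu_ws, sig_ws = _lognormal_params(render.subthreshold_width, render.focus_width_cv)
    mu_a, sig_a = _lognormal_params(render.focus_amplitude_mean, render.focus_amplitude_cv)

    reporter = diffuse
    foci_rows = []
    for nuc, n_foci in zip(nuclei, counts):
        if n_foci == 0:
            continue
        small = rng.random(n_foci) < p_small
        widths = np.where(
            small,
            rng.lognormal(mu_ws, sig_ws, n_foci),
            rng.lognormal(mu_w, sig_w, n_foci),
        )
        amplitudes = rng.lognormal(mu_a, sig_a, n_foci)
        centers = _place_foci_in_nucleus(nuc, int(n_foci), widths, amplitudes, render, rng)
        for i in range(int(n_foci)):
            sigma_eff = math.hypot(widths[i] / 2.355 / render.pixel_size, psf_px)
            _add_gaussian_spot(reporter, centers[i, 0], centers[i, 1], amplitudes[i], sigma_eff)
            foci_rows.append(
                {
                    "nucleus_id": nuc["nucleus_id"],
                    "y": centers[i, 0],
                    "x": centers[i, 1],
                    "width_fwhm_um": widths[i],
                    "amplitude": amplitudes[i],
                    "subthreshold": bool(small[i]),
                }
            )

    image = FieldImage(
        nuclear=_quantize(nuclear, render.noise_sd, rng),
        reporter=_quantize(reporter, render.noise_sd, rng),
        pixel_size=render.pixel_size,
    )
    nuclei_df = pd.DataFrame(
        nuclei,
        columns=["nucleus_id", "y", "x", "semi_major_px", "semi_minor_px", "angle_rad", "area_px"],
    )
    foci_df = pd.DataFrame(
        foci_rows,
        columns=["nucleus_id", "y", "x", "width_fwhm_um", "amplitude", "subthreshold"],
    )
    return image, FieldGroundTruth(nuclei=nuclei_df, foci=foci_df)


def iter_simulated_fields(
    platemap: PlateMap,
    kinetics: KineticsParams,
    effects_by_compound: dict[str, DrugEffect],
    render: RenderParams,
    fields_per_well: int = 4,
    seed: int | None = None,
):
    """Yield (well_row, field_index, FieldImage, FieldGroundTruth) per field.

    Streams fields one at a time so a whole plate never has to sit in memory.
    """
    platemap.require_vehicle_per_stratum()
    root = render.seed if seed is None else seed
    for row in platemap.treated.itertuples(index=False):
        effect = IDENTITY_EFFECT if row.role == "vehicle" else effects_by_compound.get(
            row.compound_id, IDENTITY_EFFECT
        )
        for f_idx in range(1, fields_per_well + 1):
            rng = field_rng(root, row.plate_id, row.well_id, f_idx)
            image, gt = simulate_field(
                float(row.dose_gy), float(row.timepoint_h), kinetics, effect, render, rng
            )
            yield row, f_idx, image, gt


def simulate_plate(
    platemap: PlateMap,
    kinetics: KineticsParams,
    effects_by_compound: dict[str, DrugEffect],
    render: RenderParams,
    out_dir,
    fields_per_well: int = 4,
    seed: int | None = None,
) -> dict:
    """Simulate every treated well of ``platemap`` and write images + truth.

    Writes one 16-bit single-channel TIFF per (well, field, channel) named
    ``{plate}_{well}_s{field}_{channel}.tif`` plus ``{plate}_true_foci.csv``
    and ``{plate}_true_nuclei.csv``.  Returns a manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_nuclei, all_foci, n_images = [], [], 0
    for row, f_idx, image, gt in iter_simulated_fields(
        platemap, kinetics, effects_by_compound, render, fields_per_well, seed
    ):
        stem = f"{row.plate_id}_{row.well_id}_s{f_idx}"
        tifffile.imwrite(out / f"{stem}_{NUCLEAR_CHANNEL}.tif", image.nuclear)
        tifffile.imwrite(out / f"{stem}_{REPORTER_CHANNEL}.tif", image.reporter)
        n_images += 2
        for df, sink in ((gt.nuclei, all_nuclei), (gt.foci, all_foci)):
            d = df.copy()
            d.insert(0, "field", f_idx)
            d.insert(0, "well_id", row.well_id)
            d.insert(0, "plate_id", row.plate_id)
            sink.append(d)
    plates = sorted(platemap.treated["plate_id"].unique())
    nuclei_df = pd.concat(all_nuclei, ignore_index=True) if all_nuclei else pd.DataFrame()
    foci_df = pd.concat(all_foci, ignore_index=True) if all_foci else pd.DataFrame()
    for plate in plates:
        nuclei_df[nuclei_df["plate_id"] == plate].to_csv(out / f"{plate}_true_nuclei.csv", index=False)
        foci_df[foci_df["plate_id"] == plate].to_csv(out / f"{plate}_true_foci.csv", index=False)
    platemap.to_csv(out / "platemap.csv")
    return {
        "out_dir": str(out),
        "plates": [str(p) for p in plates],
        "n_wells": int(len(platemap.treated)),
        "fields_per_well": fields_per_well,
        "n_images": n_images,
        "seed": int(render.seed if seed is None else seed),
    }
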