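"""Parameter sets for the IRIF screening pipeline.

Every stage of the pipeline is driven by a small frozen dataclass that
validates itself on construction.  Defaults reproduce the assay's standard
operating point: a 6 Gy screening dose read out at 2 h (formation) and 24 h
(persistence), with the granularity gates of the screen (50 gray levels above
local background, 3–19 px equivalent width at 0.3667 um/px).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields


class ParameterError(ValueError):
    """A parameter set violates one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class KineticsParams:
    """Mean IRIF count model: saturating induction times biexponential decay.

    lambda(D, t) = A * D / (1 + D / D_sat) * [f * exp(-t/tau_f)
                   + (1 - f) * exp(-t/tau_s)] + baseline

    The fast phase stands for rapid end-joining repair, the slow phase for the
    long tail of unrepaired/slowly-repaired breaks; induction saturates above
    ``saturation_dose`` giving the observed plateau in countable foci.

    Units: ``amplitude_per_gy`` foci/Gy, ``saturation_dose`` Gy, time
    constants in hours, ``baseline_mean`` foci per unirradiated nucleus.
    """

    amplitude_per_gy: float = 23.7
    saturation_dose: float = 6.0
    fast_fraction: float = 0.75
    tau_fast: float = 0.6
    tau_slow: float = 21.1
    baseline_mean: float = 0.2

    def __post_init__(self) -> None:
        _require(self.amplitude_per_gy > 0, "amplitude_per_gy must be positive")
        _require(self.saturation_dose > 0, "saturation_dose must be positive")
        _require(0.0 <= self.fast_fraction <= 1.0, "fast_fraction must be in [0, 1]")
        _require(self.tau_fast > 0 and self.tau_slow > 0, "time constants must be positive")
        _require(self.tau_fast < self.tau_slow, "tau_fast must be smaller than tau_slow")
        _require(self.baseline_mean >= 0, "baseline_mean must be >= 0")


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative perturbation of the simulated assay.

    ``formation_scale`` scales the induced (non-baseline) focus count,
    ``slow_resolution_scale`` scales the slow resolution *rate* 1/tau_slow
    (values < 1 therefore slow resolution down, i.e. foci persist),
    ``width_scale`` scales the rendered focus width, and
    ``survival_fraction`` thins the number of nuclei per field (toxicity).
    The identity effect is (1, 1, 1, 1).
    """

    formation_scale: float = 1.0
    slow_resolution_scale: float = 1.0
    width_scale: float = 1.0
    survival_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("formation_scale", "slow_resolution_scale", "width_scale", "survival_fraction"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.survival_fraction <= 1.0, "survival_fraction must be <= 1")

    @property
    def is_identity(self) -> bool:
        return (
            self.formation_scale == 1.0
            and self.slow_resolution_scale == 1.0
            and self.width_scale == 1.0
            and self.survival_fraction == 1.0
        )


IDENTITY_EFFECT = DrugEffect()

#: Control / exemplar effects used throughout validation.  The two etoposide
#: presets reflect the two concentrations of the screen: 6.25 uM (printed fold
#: 1.95) and the stronger 25 uM condition used on the Z'-validation plates
#: (etoposide nucleates foci even without IR, hence the formation boost).
CONTROL_EFFECTS: dict[str, DrugEffect] = {
    "CGK733": DrugEffect(formation_scale=0.48),
    "etoposide_6.25uM": DrugEffect(slow_resolution_scale=0.36),
    "etoposide_25uM": DrugEffect(formation_scale=1.10, slow_resolution_scale=0.33),
    "topotecan": DrugEffect(width_scale=0.3),
    "toxic_reference": DrugEffect(survival_fraction=0.4),
}


@dataclass(frozen=True)
class RenderParams:
    """Rendering geometry and photometry of a simulated field.

    ``image_shape`` is (rows, cols); intensities are in 16-bit gray levels.
    ``focus_width_mean_2h``/``_24h`` are the intrinsic FWHM (um) of a rendered
    focus at the two canonical time points (foci grow between them; widths at
    other times are interpolated linearly and clamped).  ``dispersion`` is the
    excess-Fano factor of the per-cell focus-count distribution (gamma-mixed
    Poisson, Var = mean * (1 + dispersion)).
    """

    pixel_size: float = 0.3667
    image_shape: tuple[int, int] = (672, 672)
    psf_sigma: float = 0.15
    nucleus_area_mean: float = 180.0
    nucleus_count_range: tuple[int, int] = (60, 80)
    focus_width_mean_2h: float = 0.62
    focus_width_mean_24h: float = 0.75
    focus_amplitude_mean: float = 350.0
    background_level: float = 150.0
    noise_sd: float = 12.0
    dispersion: float = 0.3
    seed: int = 0
    # secondary rendering knobs
    nucleus_stain_level: float = 2500.0
    reporter_nuclear_level: float = 60.0
    nucleus_area_cv: float = 0.16
    focus_width_cv: float = 0.20
    focus_amplitude_cv: float = 0.30
    subthreshold_fraction_2h: float = 0.15
    subthreshold_fraction_24h: float = 0.0
    subthreshold_width: float = 0.3

    def __post_init__(self) -> None:
        _require(self.pixel_size > 0, "pixel_size must be positive")
        _require(len(self.image_shape) == 2 and min(self.image_shape) > 0, "image_shape must be 2-D")
        _require(self.psf_sigma >= 0, "psf_sigma must be >= 0")
        _require(self.nucleus_area_mean > 0, "nucleus_area_mean must be positive")
        lo, hi = self.nucleus_count_range
        _require(0 <= lo <= hi, "nucleus_count_range must be a nonempty integer interval")
        _require(
            self.focus_width_mean_24h >= self.focus_width_mean_2h,
            "foci grow over time: focus_width_mean_24h must be >= focus_width_mean_2h",
        )
        _require(self.focus_amplitude_mean > 0, "focus_amplitude_mean must be positive")
        _require(self.background_level >= 0, "background_level must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.dispersion >= 0, "dispersion must be >= 0")
        _require(0 <= self.subthreshold_fraction_2h <= 1, "subthreshold_fraction_2h in [0,1]")
        _require(0 <= self.subthreshold_fraction_24h <= 1, "subthreshold_fraction_24h in [0,1]")

    def focus_width_mean(self, time_h: float) -> float:
        """Intrinsic focus FWHM (um) at ``time_h``, interpolated 2 h -> 24 h."""
        if time_h <= 2.0:
            return self.focus_width_mean_2h
        if time_h >= 24.0:
            return self.focus_width_mean_24h
        frac = (time_h - 2.0) / 22.0
        return self.focus_width_mean_2h + frac * (self.focus_width_mean_24h - self.focus_width_mean_2h)

    def subthreshold_fraction(self, time_h: float) -> float:
        """Fraction of foci rendered deliberately below the 3-px width gate."""
        if time_h <= 2.0:
            return self.subthreshold_fraction_2h
        if time_h >= 24.0:
            return self.subthreshold_fraction_24h
        frac = (time_h - 2.0) / 22.0
        return self.subthreshold_fraction_2h + frac * (
            self.subthreshold_fraction_24h - self.subthreshold_fraction_2h
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Nuclear-channel segmentation: smooth -> Otsu -> fill -> watershed -> gate."""

    smoothing_sigma: float = 1.0  # um
    min_nucleus_area: float = 40.0  # um^2
    max_nucleus_area: float = 400.0  # um^2
    split_touching: bool = True
    exclude_border: bool = True
    min_peak_distance_px: int = 10

    def __post_init__(self) -> None:
        _require(self.smoothing_sigma > 0, "smoothing_sigma must be positive")
        _require(0 < self.min_nucleus_area < self.max_nucleus_area, "need 0 < min_nucleus_area < max_nucleus_area")
        _require(self.min_peak_distance_px >= 1, "min_peak_distance_px must be >= 1")


@dataclass(frozen=True)
class DetectionParams:
    """Granularity gates: intensity above local background plus width limits."""

    intensity_threshold: float = 50.0  # gray levels above local background
    min_width: float = 3.0  # px, equivalent-circular diameter
    max_width: float = 19.0  # px
    pixel_size: float = 0.3667  # um/px; 3 px == 1.1 um at the default
    background_radius: int = 10  # px, radius of the opening disk
    smoothing_sigma: float = 0.6  # px; denoise before background + threshold

    def __post_init__(self) -> None:
        _require(self.intensity_threshold > 0, "intensity_threshold must be positive")
        _require(self.smoothing_sigma >= 0, "smoothing_sigma must be >= 0")
        _require(0 < self.min_width <= self.max_width, "need 0 < min_width <= max_width")
        _require(self.pixel_size > 0, "pixel_size must be positive")
        _require(self.background_radius >= 1, "background_radius must be >= 1")
        if self.background_radius < self.max_width / 2.0:
            warnings.warn(
                "background_radius smaller than max_width/2: the largest foci would "
                "leak into the local-background estimate",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class HitCriteria:
    """Fold-change cutoffs of the screen (inclusive) plus the toxicity gate."""

    suppression_cutoff: float = 0.5
    persistence_cutoff: float = 1.5
    toxicity_cutoff: float = 0.5
    sub_threshold_flag_level: float = 2.0

    def __post_init__(self) -> None:
        _require(
            self.suppression_cutoff < 1.0 < self.persistence_cutoff,
            "need suppression_cutoff < 1 < persistence_cutoff",
        )
        _require(0.0 < self.toxicity_cutoff < 1.0, "toxicity_cutoff must be in (0, 1)")
        _require(self.sub_threshold_flag_level >= 0, "sub_threshold_flag_level must be >= 0")


def params_from_dict(cls, data: dict, context: str = ""):
    """Build a parameter dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        where = f" in {context}" if context else ""
        raise ParameterError(f"unknown parameter key(s){where}: {sorted(unknown)}")
    coerced = dict(data)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)
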