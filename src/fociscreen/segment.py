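"""Nuclei segmentation from the nuclear-stain channel.

Standard high-content recipe: Gaussian smoothing, global Otsu threshold,
hole filling, then a distance-transform watershed to split touching nuclei,
followed by area gating and border flagging.  The Otsu threshold is relative
to the image histogram, so segmentation is invariant to adding a constant
offset to the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .params import SegmentationParams


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus."""

    label: int
    area: float  # um^2
    centroid: tuple[float, float]  # (x, y) pixels, 0-based pixel centers
    touches_border: bool
    mean_stain_intensity: float


def segment_nuclei(
    image: np.ndarray,
    pixel_size: float,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Segment nuclei; returns (label mask, records).

    An empty, constant, or nucleus-free image yields zero nuclei (not an
    error).  Regions outside the area gates are removed from the mask;
    border-touching nuclei are kept in the mask but flagged, so callers can
    apply the exclusion policy downstream.
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {img.shape}")
    if img.size == 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32), []

    sigma_px = params.smoothing_sigma / pixel_size
    smoothed = gaussian(img.astype(np.float64), sigma=sigma_px, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(img.shape, dtype=np.int32), []
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), []

    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        dist_s = gaussian(distance, sigma=2.0, preserve_range=True)
        peaks = peak_local_max(
            dist_s,
            min_distance=params.min_peak_distance_px,
            labels=mask,
            exclude_border=False,
        )
        if len(peaks) == 0:
            labels, _ = ndi.label(mask)
        else:
            # deterministic marker order: peak_local_max sorts by peak height;
            # re-sort by (row, col) so marker labels do not depend on intensity ties
            order = np.lexsort((peaks[:, 1], peaks[:, 0]))
            peaks = peaks[order]
            markers = np.zeros(mask.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = watershed(-dist_s, markers=markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)

    # area gating + relabeling to consecutive ids
    px_area = pixel_size * pixel_size
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[
        (counts * px_area >= params.min_nucleus_area) & (counts * px_area <= params.max_nucleus_area)
    ]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    labels = lut[labels]
    if len(keep) == 0:
        return labels, []

    n = len(keep)
    index = np.arange(1, n + 1)
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    labs = flat[nz]
    areas_px = np.bincount(labs, minlength=n + 1)[1:].astype(float)
    ys, xs = np.unravel_index(nz, labels.shape)
    cy = np.bincount(labs, weights=ys, minlength=n + 1)[1:] / areas_px
    cx = np.bincount(labs, weights=xs, minlength=n + 1)[1:] / areas_px
    means = (
        np.bincount(labs, weights=img.ravel()[nz].astype(np.float64), minlength=n + 1)[1:]
        / areas_px
    )
    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge[edge > 0])] = True

    records = [
        NucleusRecord(
            label=int(lab),
            area=float(areas_px[i] * px_area),
            centroid=(float(cx[i]), float(cy[i])),
            touches_border=bool(border[lab]),
            mean_stain_intensity=float(means[i]),
        )
        for i, lab in enumerate(index)
    ]
    return labels, records


def nuclei_per_field(records: list[NucleusRecord], exclude_border: bool = True) -> int:
    """Count nuclei in one field under the border-exclusion policy."""
    if exclude_border:
        return sum(1 for r in records if not r.touches_border)
    return len(records)


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area_um2": r.area,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "touches_border": r.touches_border,
                "mean_stain_intensity": r.mean_stain_intensity,
            }
            for r in records
        ],
        columns=[
            "label",
            "area_um2",
            "centroid_x",
            "centroid_y",
            "touches_border",
            "mean_stain_intensity",
        ],
    )
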