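"""Independent brute-force reference for the granularity analysis.

Deliberately naive: shift-based disk erosion/dilation for the background
opening, an explicit stack-based flood fill for 8-connected components, and
per-component measurements by direct iteration.  Shares nothing with the
package implementation beyond numpy and the parameter definitions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi

from fociscreen.params import DetectionParams


def naive_disk_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a disk via explicit shifts (reflect edges)."""
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]

    def erode(a):
        p = np.pad(a, radius, mode="symmetric")
        out = None
        for dy, dx in offsets:
            v = p[radius + dy : radius + dy + a.shape[0], radius + dx : radius + dx + a.shape[1]]
            out = v.copy() if out is None else np.minimum(out, v)
        return out

    def dilate(a):
        p = np.pad(a, radius, mode="symmetric")
        out = None
        for dy, dx in offsets:
            v = p[radius + dy : radius + dy + a.shape[0], radius + dx : radius + dx + a.shape[1]]
            out = v.copy() if out is None else np.maximum(out, v)
        return out

    return dilate(erode(img))


def brute_force_detect(reporter: np.ndarray, label_mask: np.ndarray, params: DetectionParams):
    """Reference granularity detection: returns (records, sub_threshold).

    Records are dicts with keys nucleus_label / width / peak_height / area /
    centroid, sorted by centroid for comparison.
    """
    work = reporter.astype(np.float64)
    if params.smoothing_sigma > 0:
        work = ndi.gaussian_filter(work, params.smoothing_sigma)
    work = work.astype(np.float32)
    background = naive_disk_opening(work, params.background_radius)
    height = work - background
    candidates = (height >= params.intensity_threshold) & (label_mask > 0)

    h, w = candidates.shape
    seen = np.zeros_like(candidates, dtype=bool)
    sub_threshold = {int(lab): 0 for lab in np.unique(label_mask[label_mask > 0])}
    records = []
    for y0 in range(h):
        for x0 in range(w):
            if not candidates[y0, x0] or seen[y0, x0]:
                continue
            stack, pixels = [(y0, x0)], []
            seen[y0, x0] = True
            while stack:
                y, x = stack.pop()
                pixels.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and candidates[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            area = len(pixels)
            width = math.sqrt(4.0 * area / math.pi)
            votes: dict[int, int] = {}
            for y, x in pixels:
                lab = int(label_mask[y, x])
                votes[lab] = votes.get(lab, 0) + 1
            owner, best = 0, 0
            for lab in sorted(votes):
                if lab > 0 and votes[lab] > best:
                    owner, best = lab, votes[lab]
            if owner == 0:
                continue
            if width < params.min_width:
                sub_threshold[owner] += 1
            elif width <= params.max_width:
                records.append(
                    {
                        "nucleus_label": owner,
                        "width": width,
                        "peak_height": float(max(height[y, x] for y, x in pixels)),
                        "area": area,
                        "centroid": (
                            float(sum(x for _, x in pixels)) / area,
                            float(sum(y for y, _ in pixels)) / area,
                        ),
                    }
                )
    records.sort(key=lambda r: r["centroid"])
    return records, sub_threshold


def random_patch(rng: np.random.Generator, size: int = 128):
    """Random synthetic patch: nuclei-like label disks, spots, ramp, noise."""
    h = w = size
    img = np.full((h, w), 150.0)
    if rng.random() < 0.5:  # illumination gradient
        img += np.linspace(0, rng.uniform(0, 60), w)[None, :]
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[:h, :w]
    n_nuc = rng.integers(1, 4)
    for lab in range(1, n_nuc + 1):
        cy, cx = rng.uniform(20, h - 20, 2)
        r = rng.uniform(12, 22)
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        labels[inside] = lab
        img[inside] += rng.uniform(30, 80)
        for _ in range(rng.integers(0, 8)):
            rad = math.sqrt(rng.uniform()) * r * 0.8
            phi = rng.uniform(0, 2 * math.pi)
            sy, sx = cy + rad * math.sin(phi), cx + rad * math.cos(phi)
            sigma = rng.uniform(0.4, 2.5)
            amp = rng.uniform(40, 500)
            img += amp * np.exp(-((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sigma * sigma))
    img += rng.normal(0, rng.uniform(0, 15), (h, w))
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16), labels
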