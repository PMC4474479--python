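"""Shared fixtures: small render presets and canned plate maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fociscreen.params import KineticsParams, RenderParams
from fociscreen.platemap import PlateMap


@pytest.fixture
def kinetics() -> KineticsParams:
    return KineticsParams()


@pytest.fixture
def small_render() -> RenderParams:
    """Fast render preset: ~10 nuclei on a 300 px field (unit-test scale)."""
    return RenderParams(image_shape=(300, 300), nucleus_count_range=(8, 12))


@pytest.fixture
def default_render() -> RenderParams:
    return RenderParams()


def make_platemap(plate_id: str, timepoint_h: float, entries, dose_gy: float = 6.0) -> PlateMap:
    """Build a plate map from (role, compound, n_wells) triples, column-major."""
    wells = [f"{r}{c:02d}" for c in range(1, 13) for r in "ABCDEFGH"]
    rows, i = [], 0
    for role, comp, n in entries:
        for _ in range(n):
            rows.append(
                dict(
                    plate_id=plate_id,
                    well_id=wells[i],
                    role=role,
                    compound_id=comp,
                    concentration_um=0.0 if role == "vehicle" else 50.0,
                    dose_gy=dose_gy,
                    timepoint_h=timepoint_h,
                )
            )
            i += 1
    return PlateMap(pd.DataFrame(rows))


def draw_disk(img: np.ndarray, cy: float, cx: float, radius: float, value: float) -> None:
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] += value
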