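"""Kinetic model and field simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fociscreen.params import DrugEffect, IDENTITY_EFFECT, KineticsParams, RenderParams
from fociscreen.simulate import (
    SimulationError,
    expected_foci,
    field_rng,
    simulate_field,
)

ORACLE_KINETICS = KineticsParams(
    amplitude_per_gy=4.0, saturation_dose=6.0, fast_fraction=0.6,
    tau_fast=0.5, tau_slow=40.0, baseline_mean=1.0,
)
# hand evaluation of the closed form at D=6 Gy, t=2 h:
#   induced = 4*6/(1+1) = 12;  decay = 0.6*e^-4 + 0.4*e^-0.05
#   = 0.010989383... + 0.380491770... = 0.391481153...
#   lambda = 12*0.391481153 + 1 = 5.697773837...
ORACLE_VALUE = 5.697773837


class TestExpectedFoci:
    def test_matches_hand_computed_value(self):
        assert expected_foci(6.0, 2.0, ORACLE_KINETICS) == pytest.approx(ORACLE_VALUE, abs=1e-8)

    def test_zero_dose_returns_baseline(self, kinetics):
        for t in (0.0, 2.0, 24.0, 100.0):
            assert expected_foci(0.0, t, kinetics) == kinetics.baseline_mean

    def test_time_zero_identity_is_saturating_induction(self, kinetics):
        d = 6.0
        expect = kinetics.amplitude_per_gy * d / (1 + d / kinetics.saturation_dose) + kinetics.baseline_mean
        assert expected_foci(d, 0.0, kinetics) == pytest.approx(expect)

    @pytest.mark.parametrize("dose,time", [(-1.0, 2.0), (6.0, -0.5)])
    def test_negative_arguments_rejected(self, kinetics, dose, time):
        with pytest.raises(ValueError):
            expected_foci(dose, time, kinetics)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d1=st.floats(0, 20), d2=st.floats(0, 20),
        t1=st.floats(0, 48), t2=st.floats(0, 48),
    )
    def test_monotone_in_dose_and_time(self, d1, d2, t1, t2):
        k = KineticsParams()
        lo_d, hi_d = sorted((d1, d2))
        lo_t, hi_t = sorted((t1, t2))
        assert expected_foci(lo_d, lo_t, k) <= expected_foci(hi_d, lo_t, k) + 1e-12
        assert expected_foci(lo_d, lo_t, k) >= expected_foci(lo_d, hi_t, k) - 1e-12

    def test_saturation_per_gray_yield_decreases(self, kinetics):
        per_gy = [expected_foci(d, 2.0, kinetics) / d for d in (2, 4, 6, 8, 10, 14)]
        assert all(a > b for a, b in zip(per_gy, per_gy[1:]))

    def test_formation_scale_multiplies_induced_term_exactly(self, kinetics):
        base = expected_foci(6.0, 2.0, kinetics)
        for s in (0.0, 0.25, 0.48, 1.5, 2.0):
            scaled = expected_foci(6.0, 2.0, kinetics, DrugEffect(formation_scale=s))
            assert scaled - kinetics.baseline_mean == pytest.approx(
                s * (base - kinetics.baseline_mean), rel=1e-12
            )

    def test_slow_resolution_scale_slows_late_decay(self, kinetics):
        persistent = expected_foci(6.0, 24.0, kinetics, DrugEffect(slow_resolution_scale=0.3))
        assert persistent > expected_foci(6.0, 24.0, kinetics)


class TestSimulateField:
    def test_zero_survival_gives_empty_field(self, kinetics, small_render):
        rng = field_rng(0, "P", "A01", 1)
        image, gt = simulate_field(6, 2, kinetics, DrugEffect(survival_fraction=0.0), small_render, rng)
        assert len(gt.nuclei) == 0 and len(gt.foci) == 0
        assert image.nuclear.shape == small_render.image_shape

    def test_no_dose_no_baseline_gives_focus_free_reporter(self, small_render):
        quiet = KineticsParams(baseline_mean=0.0)
        render = RenderParams(
            image_shape=small_render.image_shape,
            nucleus_count_range=small_render.nucleus_count_range,
            noise_sd=0.0,
        )
        image, gt = simulate_field(0.0, 2.0, quiet, IDENTITY_EFFECT, render, field_rng(0, "P", "A01", 1))
        assert len(gt.foci) == 0
        assert len(gt.nuclei) > 0

    def test_ground_truth_mean_tracks_kinetic_model(self, kinetics, default_render):
        lam = expected_foci(6.0, 2.0, kinetics)
        counts = []
        for f in (1, 2):
            _, gt = simulate_field(6, 2, kinetics, IDENTITY_EFFECT, default_render,
                                   field_rng(3, "P", "B02", f))
            counts.extend(gt.foci_per_nucleus.tolist())
        counts = np.asarray(counts, dtype=float)
        se = math.sqrt(lam * (1 + default_render.dispersion) / len(counts))
        assert abs(counts.mean() - lam) < 3 * se

    def test_nuclei_do_not_overlap(self, kinetics, small_render):
        _, gt = simulate_field(6, 2, kinetics, IDENTITY_EFFECT, small_render, field_rng(5, "P", "C03", 1))
        assert len(gt.nuclei) >= 8
        occupancy = np.zeros(small_render.image_shape, dtype=bool)
        yy, xx = np.mgrid[: small_render.image_shape[0], : small_render.image_shape[1]]
        for nuc in gt.nuclei.itertuples(index=False):
            ct, st = math.cos(nuc.angle_rad), math.sin(nuc.angle_rad)
            dx, dy = xx - nuc.x, yy - nuc.y
            u = (dx * ct + dy * st) / nuc.semi_major_px
            v = (-dx * st + dy * ct) / nuc.semi_minor_px
            inside = u * u + v * v <= 1.0
            assert not (occupancy & inside).any()  # footprints are disjoint
            occupancy |= inside

    def test_same_stream_reproduces_identical_output(self, kinetics, small_render):
        a_img, a_gt = simulate_field(6, 24, kinetics, IDENTITY_EFFECT, small_render,
                                     field_rng(9, "P", "D04", 2))
        b_img, b_gt = simulate_field(6, 24, kinetics, IDENTITY_EFFECT, small_render,
                                     field_rng(9, "P", "D04", 2))
        assert np.array_equal(a_img.nuclear, b_img.nuclear)
        assert np.array_equal(a_img.reporter, b_img.reporter)
        assert a_gt.foci.equals(b_gt.foci) and a_gt.nuclei.equals(b_gt.nuclei)

    def test_different_fields_differ(self, kinetics, small_render):
        a_img, _ = simulate_field(6, 24, kinetics, IDENTITY_EFFECT, small_render,
                                  field_rng(9, "P", "D04", 1))
        b_img, _ = simulate_field(6, 24, kinetics, IDENTITY_EFFECT, small_render,
                                  field_rng(9, "P", "D04", 2))
        assert not np.array_equal(a_img.reporter, b_img.reporter)

    def test_overcrowded_field_raises_named_error(self, kinetics):
        render = RenderParams(image_shape=(150, 150), nucleus_count_range=(60, 60))
        with pytest.raises(SimulationError, match="crowded"):
            simulate_field(6, 2, kinetics, IDENTITY_EFFECT, render, field_rng(0, "P", "A01", 1))

    def test_width_scale_shrinks_rendered_foci(self, kinetics, small_render):
        _, gt = simulate_field(6, 2, kinetics, DrugEffect(width_scale=0.3), small_render,
                               field_rng(4, "P", "E05", 1))
        big = gt.foci[~gt.foci["subthreshold"]]
        assert big["width_fwhm_um"].mean() < 0.5 * small_render.focus_width_mean_2h
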