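"""Per-well aggregation and vehicle normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_platemap
from fociscreen.quantify import (
    NormalizationError,
    WellQuant,
    normalize_to_controls,
    quantify_well,
)


def _counts(foci, subs=None, fields=None):
    n = len(foci)
    return pd.DataFrame(
        {
            "nucleus_label": np.arange(1, n + 1),
            "foci_count": foci,
            "sub_threshold_count": subs if subs is not None else np.zeros(n, dtype=int),
            "field": fields if fields is not None else np.ones(n, dtype=int),
        }
    )


def _quant(well, plate, mean_foci, npf=70.0, n=280, sub=0.0, fr20=0.0):
    return WellQuant(
        well_id=well, plate_id=plate, n_fields=4, n_nuclei=n,
        mean_foci_per_nucleus=mean_foci, nuclei_per_field=npf,
        fraction_gt20=fr20, mean_sub_threshold=sub, degenerate=False,
    )


class TestQuantifyWell:
    def test_uniform_counts_pool_exactly(self):
        df = _counts([5] * 280, fields=np.repeat([1, 2, 3, 4], 70))
        q = quantify_well("A01", df, n_fields=4)
        assert q.mean_foci_per_nucleus == 5.0
        assert q.nuclei_per_field == 70.0
        assert q.fraction_gt20 == 0.0
        assert q.n_nuclei == 280 and not q.degenerate

    def test_fraction_gt20_is_strict_count(self):
        foci = [0] * 98 + [25, 30]
        q = quantify_well("A01", _counts(foci), n_fields=4)
        assert q.fraction_gt20 == pytest.approx(0.02)
        # a nucleus at exactly 20 does not count
        q20 = quantify_well("A01", _counts([20] * 50), n_fields=2)
        assert q20.fraction_gt20 == 0.0

    def test_zero_nucleus_well_is_flagged_not_zero(self):
        q = quantify_well("H12", _counts([]), n_fields=4)
        assert q.degenerate and q.n_nuclei == 0
        assert math.isnan(q.mean_foci_per_nucleus)

    def test_pooling_is_partition_invariant(self):
        rng = np.random.default_rng(1)
        foci = rng.poisson(6, 200)
        a = quantify_well("A01", _counts(foci, fields=np.repeat([1, 2, 3, 4], 50)), n_fields=4)
        b = quantify_well("A01", _counts(foci, fields=np.r_[np.ones(199), [4]]), n_fields=4)
        assert a.mean_foci_per_nucleus == b.mean_foci_per_nucleus
        assert a.fraction_gt20 == b.fraction_gt20

    def test_requires_a_field(self):
        with pytest.raises(ValueError):
            quantify_well("A01", _counts([1]), n_fields=0)


class TestNormalizeToControls:
    def test_single_vehicle_normalizes_to_exactly_one(self):
        pm = make_platemap("P", 24.0, [("vehicle", "DMSO", 1)])
        scores = normalize_to_controls([_quant("A01", "P", 5.83)], pm)
        assert scores[0].fold_foci == 1.0
        assert scores[0].fold_nuclei == 1.0

    def test_vehicle_wells_average_to_one_exactly(self):
        pm = make_platemap("P", 24.0, [("vehicle", "DMSO", 8), ("compound", "x", 1)])
        quants = [
            _quant(w, "P", m)
            for w, m in zip(
                [f"{r}01" for r in "ABCDEFGH"], [4.8, 5.1, 5.6, 6.0, 5.2, 5.9, 5.5, 5.3]
            )
        ] + [_quant("A02", "P", 9.75)]
        scores = normalize_to_controls(quants, pm)
        vehicle_folds = [s.fold_foci for s in scores if s.well_id != "A02"]
        assert np.mean(vehicle_folds) == pytest.approx(1.0, abs=1e-12)

    def test_fold_is_plain_ratio(self):
        pm = make_platemap("P", 24.0, [("vehicle", "DMSO", 1), ("compound", "etop", 1)])
        scores = normalize_to_controls(
            [_quant("A01", "P", 5.0), _quant("B01", "P", 9.75)], pm
        )
        by_well = {s.well_id: s for s in scores}
        assert by_well["B01"].fold_foci == pytest.approx(1.95)

    def test_missing_vehicle_stratum_names_the_stratum(self):
        pm = make_platemap("P7", 24.0, [("compound", "x", 2)])
        with pytest.raises(NormalizationError, match="P7"):
            normalize_to_controls([_quant("A01", "P7", 5.0), _quant("B01", "P7", 6.0)], pm)

    def test_zero_vehicle_reference_rejected(self):
        pm = make_platemap("P", 24.0, [("vehicle", "DMSO", 1), ("compound", "x", 1)])
        with pytest.raises(NormalizationError, match="zero"):
            normalize_to_controls(
                [_quant("A01", "P", 0.0), _quant("B01", "P", 6.0)], pm
            )

    def test_degenerate_wells_are_skipped_not_scored(self):
        pm = make_platemap("P", 24.0, [("vehicle", "DMSO", 1), ("compound", "x", 1)])
        dead = WellQuant(
            well_id="B01", plate_id="P", n_fields=4, n_nuclei=0,
            mean_foci_per_nucleus=float("nan"), nuclei_per_field=0.0,
            fraction_gt20=float("nan"), mean_sub_threshold=float("nan"), degenerate=True,
        )
        scores = normalize_to_controls([_quant("A01", "P", 5.0), dead], pm)
        assert [s.well_id for s in scores] == ["A01"]

    def test_strata_are_matched_by_dose_time_and_plate(self):
        # two time points on one plate: each normalizes against its own vehicles
        import pandas as pd

        rows = []
        for i, (tp, role, comp, well) in enumerate(
            [
                (2.0, "vehicle", "DMSO", "A01"),
                (2.0, "compound", "x", "B01"),
                (24.0, "vehicle", "DMSO", "A02"),
                (24.0, "compound", "x", "B02"),
            ]
        ):
            rows.append(
                dict(plate_id="P", well_id=well, role=role, compound_id=comp,
                     concentration_um=0.0, dose_gy=6.0, timepoint_h=tp)
            )
        from fociscreen.platemap import PlateMap

        pm = PlateMap(pd.DataFrame(rows))
        quants = [
            _quant("A01", "P", 14.0), _quant("B01", "P", 7.0),
            _quant("A02", "P", 5.0), _quant("B02", "P", 10.0),
        ]
        by_well = {s.well_id: s for s in normalize_to_controls(quants, pm)}
        assert by_well["B01"].fold_foci == pytest.approx(0.5)
        assert by_well["B02"].fold_foci == pytest.approx(2.0)
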