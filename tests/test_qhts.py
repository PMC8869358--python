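"""Plate normalization, Hill fitting, activity calls and the filter cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hergscreen import qhts, synthetic
from hergscreen.config import SynthConfig
from hergscreen.errors import FitError, NormalizationError

from conftest import toy_plate


class TestNormalize:
    def test_control_anchors_and_hand_example(self):
        # VDMSO=100, Vpos=50: well at 100 -> 0%, at 50 -> -100%, at 75 -> -50%
        wells = toy_plate(100.0, 50.0, compound_values=(100.0, 50.0, 75.0))
        (curve,) = qhts.normalize(wells)
        assert curve.pct == pytest.approx([0.0, -100.0, -50.0], abs=1e-12)

    def test_poscon_median_maps_to_exactly_minus_100(self):
        wells = toy_plate(10000.0, 5000.0, compound_values=(5000.0,))
        (curve,) = qhts.normalize(wells)
        assert curve.pct[0] == -100.0

    @given(scale=st.floats(0.1, 100.0), offset=st.floats(-5000.0, 5000.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_of_anchors(self, scale, offset):
        # rescaling/offsetting the whole plate leaves normalized values unchanged
        base = toy_plate(10000.0, 5000.0, compound_values=(5000.0, 10000.0, 7500.0))
        moved = base.copy()
        moved["raw_value"] = moved["raw_value"] * scale + offset
        (c0,), (c1,) = qhts.normalize(base), qhts.normalize(moved)
        np.testing.assert_allclose(c1.pct, c0.pct, atol=1e-8)

    def test_missing_or_degenerate_controls_raise(self):
        wells = toy_plate()
        with pytest.raises(NormalizationError):
            qhts.normalize(wells[wells.well_type != "dmso"])
        degenerate = wells.copy()
        degenerate.loc[degenerate.well_type.isin(["dmso", "poscon"]), "raw_value"] = 7.0
        with pytest.raises(NormalizationError):
            qhts.normalize(degenerate)


class TestFitHill:
    def test_noiseless_recovery_within_0p1_percent(self, noiseless_plate):
        wells, truth = noiseless_plate
        for curve in qhts.normalize(wells):
            t = truth.loc[curve.compound_id]
            h = qhts.fit_hill(curve)
            if not t.is_active:
                continue
            assert abs(h.ic50 - t.ic50_M) / t.ic50_M < 1e-3
            assert abs(h.hill_slope - t.hill_slope) / t.hill_slope < 1e-3
            assert h.curve_rank <= -5
            assert h.curve_class == 1

    def test_flat_curve_is_rank_zero_inactive(self):
        curve = qhts.CRCurve("flat", np.geomspace(1e-8, 1e-4, 15),
                             np.zeros(15), np.zeros((15, 1)))
        h = qhts.fit_hill(curve)
        assert (h.curve_class, h.curve_rank) == (4, 0)
        assert qhts.call_activity(h).call == "inactive"

    def test_pic50_unit_conversion(self):
        # pIC50 of 4.8 corresponds to 15.85 uM
        assert qhts.pic50_to_molar(4.8) * 1e6 == pytest.approx(15.85, abs=5e-3)

    def test_too_few_points_raise(self):
        curve = qhts.CRCurve("short", np.array([1e-6, 1e-5, 1e-4]),
                             np.zeros(3), np.zeros((3, 1)))
        with pytest.raises(FitError):
            qhts.fit_hill(curve)

    def test_noisy_recovery_median_error_below_15_percent(self):
        cfg = SynthConfig(n_compounds=210, frac_active=0.96, noise_sd=0.05, seed=7)
        wells, truth = synthetic.generate_plate(cfg)
        truth = truth.set_index("compound_id")
        errs = []
        for curve in qhts.normalize(wells):
            t = truth.loc[curve.compound_id]
            if not t.is_active:
                continue
            h = qhts.fit_hill(curve)
            errs.append(abs(h.ic50 - t.ic50_M) / t.ic50_M)
        assert len(errs) >= 200
        assert np.median(errs) < 0.15


class TestCallActivity:
    @pytest.mark.parametrize("rank,call", [
        (0, "inactive"), (-5, "active_antagonist"), (-9, "active_antagonist"),
        (-4, "inconclusive"), (-1, "inconclusive"), (4, "inconclusive"),
        (5, "agonist"), (9, "agonist"),
    ])
    def test_rank_bins(self, rank, call):
        h = _result(rank=rank, efficacy=60.0, inspection=True)
        assert qhts.call_activity(h).call == call

    def test_reliable_requires_efficacy_and_inspection(self):
        assert qhts.call_activity(_result(-7, 45.0, True)).reliable_active
        assert not qhts.call_activity(_result(-6, 20.0, True)).reliable_active
        assert not qhts.call_activity(_result(-6, 45.0, False)).reliable_active
        # reliable_active implies the antagonist call
        for rank in (-9, -5, -4, 0, 5):
            c = qhts.call_activity(_result(rank, 90.0, True))
            assert not c.reliable_active or c.call == "active_antagonist"

    def test_out_of_range_rank_raises(self):
        with pytest.raises(FitError):
            qhts.call_activity(_result(-10, 50.0, True))


def _result(rank, efficacy, inspection):
    return qhts.HillResult("x", 1e-6, 1.0, 0.0, -efficacy, efficacy,
                           -1 if rank < 0 else (1 if rank > 0 else 0),
                           1, rank, 6.0, 0.01, 1.0, 0, inspection)


class TestFilterCascade:
    def test_planted_failures_counted_per_step(self):
        results = [
            _result(-9, 90.0, True),     # survives everything
            _result(-7, 90.0, True),     # survives everything
            _result(-2, 90.0, True),     # falls at the rank bin
            _result(-6, 20.0, True),     # falls at efficacy
            _result(-5, 60.0, False),    # falls at inspection
            _result(-8, 60.0, True),     # falls at standardization
            _result(0, 0.0, True),       # never an antagonist
            _result(6, 90.0, True),      # agonist, never an antagonist
        ]
        for i, r in enumerate(results):
            r.compound_id = f"c{i}"
        ok = {f"c{i}": True for i in range(8)}
        ok["c5"] = False
        counts = qhts.filter_cascade(results, standardization_ok=ok)
        assert counts.tolist() == [6, 5, 4, 3, 2]
        assert (counts.diff().dropna() <= 0).all()

    def test_empty_and_all_pass_edges(self):
        assert qhts.filter_cascade([], standardization_ok={}).tolist() == [0] * 5
        rs = [_result(-9, 90.0, True)]
        rs[0].compound_id = "a"
        assert qhts.filter_cascade(rs, standardization_ok={"a": True}).tolist() == [1] * 5
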