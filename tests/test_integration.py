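"""Bioactivity record integration and the potency-shift regression."""

import numpy as np
import pandas as pd
import pytest

from hergscreen import integration, synthetic
from hergscreen.config import SynthConfig
from hergscreen.errors import IntegrationError


def _records(rows):
    return pd.DataFrame(rows, columns=["chemical_id", "endpoint", "value_M",
                                       "exact", "assay"])


class TestIntegrateRecords:
    def test_patch_clamp_priority(self):
        rec = _records([("c1", "IC50", 1e-7, True, "patch_clamp"),
                        ("c1", "IC50", 5e-5, True, "other")])
        out = integration.integrate_records(rec)
        assert out.loc["c1", "pAffinity"] == pytest.approx(7.0)
        assert out.loc["c1", "label"] == True  # noqa: E712

    def test_conflicting_patch_clamp_values_drop_chemical(self):
        # 0.1 and 2 uM: log10 gap 1.30 > 1
        rec = _records([("c1", "IC50", 1e-7, True, "patch_clamp"),
                        ("c1", "IC50", 2e-6, True, "patch_clamp")])
        out = integration.integrate_records(rec)
        assert out.loc["c1", "drop_reason"] == "conflicting_values"
        assert pd.isna(out.loc["c1", "label"])

    def test_single_half_micromolar_record_is_active(self):
        rec = _records([("c1", "Ki", 5e-7, True, "other")])
        out = integration.integrate_records(rec)
        assert out.loc["c1", "pAffinity"] == pytest.approx(6.301, abs=1e-3)
        assert out.loc["c1", "label"] == True  # noqa: E712

    def test_censored_records_excluded(self):
        rec = _records([("c1", "IC50", 1e-7, False, "patch_clamp")])
        out = integration.integrate_records(rec)
        assert out.loc["c1", "drop_reason"] == "no_exact_records"

    def test_concordant_values_averaged_on_log_scale(self):
        # 1 and 10 uM, gap exactly 1 log10: retained, geometric mean ~3.16 uM
        rec = _records([("c1", "IC50", 1e-6, True, "other"),
                        ("c1", "EC50", 1e-5, True, "other")])
        out = integration.integrate_records(rec)
        assert out.loc["c1", "pAffinity"] == pytest.approx(5.5)
        assert out.loc["c1", "label"] == False  # noqa: E712

    def test_assay_set_label_wins_on_overlap(self):
        rec = _records([("c1", "IC50", 1e-8, True, "patch_clamp")])
        assay = pd.Series({"c1": False})
        out = integration.integrate_records(rec, assay_labels=assay)
        assert out.loc["c1", "provenance"] == "assay_set"
        assert out.loc["c1", "label"] == False  # noqa: E712

    def test_no_retained_external_below_paffinity_six(self):
        rec = synthetic.generate_bioactivity_records(SynthConfig(n_compounds=300, seed=2))
        out = integration.integrate_records(rec)
        kept = integration.retained_actives(out)
        assert (kept["pAffinity"] >= 6.0).all()
        # retained chemicals with duplicates satisfied the <= 1 log10 spread rule
        pc = rec[rec["exact"] & (rec["assay"] == "patch_clamp")]
        pc_spread = pc.groupby("chemical_id")["value_M"].agg(
            lambda v: np.log10(v.max() / v.min()))
        # chemicals conflicted on their prioritized records are never retained
        pc_conflicted = set(pc_spread[pc_spread > 1.0].index)
        assert pc_conflicted.isdisjoint(kept.index)

    def test_idempotent_on_own_output(self):
        rec = synthetic.generate_bioactivity_records(SynthConfig(n_compounds=200, seed=3))
        first = integration.integrate_records(rec)
        kept = first[first["drop_reason"] == ""]
        back = _records([(cid, "IC50", 10 ** (-row.pAffinity), True, "patch_clamp")
                         for cid, row in kept.iterrows()])
        second = integration.integrate_records(back)
        pd.testing.assert_series_equal(second["pAffinity"], kept["pAffinity"],
                                       check_exact=False, rtol=1e-12)
        assert (second["label"] == kept["label"]).all()

    def test_bad_inputs_raise(self):
        with pytest.raises(IntegrationError):
            integration.integrate_records(_records([("c1", "AC50", 1e-6, True, "other")]))
        with pytest.raises(IntegrationError):
            integration.integrate_records(_records([("c1", "IC50", -1e-6, True, "other")]))


class TestPotencyShift:
    def test_noiseless_identity_line(self):
        x = np.linspace(4, 8, 10)
        m = integration.fit_potency_shift(x, x)
        assert m.slope == pytest.approx(1.0, abs=1e-10)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.r2 == pytest.approx(1.0)

    def test_printed_coefficients_reproduce_dofetilide(self):
        # patch = -0.1953 + 1.17 * flux applied to a 0.139 uM flux IC50
        model = integration.PotencyShiftModel(-0.1953, 1.17, np.nan, np.nan, np.nan, 28)
        pred_m = model.predict_ic50_molar(-np.log10(0.139e-6))
        uM = float(pred_m) * 1e6
        assert f"{uM:.2g}" == "0.015"

    def test_slope_recovery_inside_ci(self):
        # y = -0.2 + 1.2 x + N(0, 0.3): 95% CI covers truth in >= 90% of runs
        rng = np.random.default_rng(11)
        hits_slope = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.uniform(4, 8, 28)
            y = -0.2 + 1.2 * x + rng.normal(0, 0.3, 28)
            import statsmodels.api as sm
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            lo, hi = fit.conf_int()[1]
            hits_slope += lo <= 1.2 <= hi
        assert hits_slope / n_rep >= 0.90

    def test_too_few_pairs_raise(self):
        with pytest.raises(IntegrationError):
            integration.fit_potency_shift([5.0, 6.0], [5.0, 6.0])
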