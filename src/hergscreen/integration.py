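"""External bioactivity integration and the assay potency-shift model.

ChEMBL-style potency records (IC50 / Ki / EC50) are merged into the
training labels under strict rules: only exact (non-censored) values are
admitted; patch-clamp measurements, the electrophysiology gold standard,
take priority over other formats; chemicals whose surviving records
disagree by more than one log10 are removed; the rest are averaged on
the pAffinity (-log10 molar) scale, and a chemical is labeled active
when its pAffinity is >= 6 (potency <= 1 uM). Chemicals already labeled
by the screening assay keep their assay-set label.

A paired thallium-flux vs patch-clamp pIC50 set additionally supports an
ordinary-least-squares potency-shift model mapping flux potencies onto
the electrophysiology scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import IntegrationError

VALID_ENDPOINTS = {"IC50", "Ki", "EC50"}


def paffinity(value_molar) -> np.ndarray:
    return -np.log10(np.asarray(value_molar, dtype=float))


def integrate_records(records: pd.DataFrame,
                      assay_labels: pd.Series | None = None,
                      paffinity_min: float = 6.0,
                      max_log10_gap: float = 1.0) -> pd.DataFrame:
    """Collapse external potency records to one label per chemical.

    Returns a table indexed by chemical id with columns pAffinity, label,
    provenance ('assay_set' or 'external') and drop_reason (empty string
    for retained chemicals; dropped chemicals have label <NA>).
    """
    req = {"chemical_id", "endpoint", "value_M", "exact", "assay"}
    missing = req - set(records.columns)
    if missing:
        raise IntegrationError(f"missing record columns: {sorted(missing)}")
    bad = ~records["endpoint"].isin(VALID_ENDPOINTS)
    if bad.any():
        raise IntegrationError(f"unknown endpoint(s): {sorted(records.loc[bad, 'endpoint'].unique())}")
    if (records["value_M"] <= 0).any():
        raise IntegrationError("potency values must be positive molar concentrations")

    rows = []
    for cid, grp in records.groupby("chemical_id", sort=True):
        cid = str(cid)
        if assay_labels is not None and cid in assay_labels.index:
            # the screening assay outcome wins over external records
            rows.append((cid, np.nan, bool(assay_labels[cid]), "assay_set", ""))
            continue
        exact = grp[grp["exact"].astype(bool)]
        if exact.empty:
            rows.append((cid, np.nan, pd.NA, "external", "no_exact_records"))
            continue
        pc = exact[exact["assay"] == "patch_clamp"]
        use = pc if not pc.empty else exact
        paff = paffinity(use["value_M"])
        if len(paff) > 1 and (paff.max() - paff.min()) > max_log10_gap:
            rows.append((cid, np.nan, pd.NA, "external", "conflicting_values"))
            continue
        mean_paff = float(paff.mean())   # arithmetic mean of pAffinity = geometric mean potency
        rows.append((cid, mean_paff, mean_paff >= paffinity_min, "external", ""))

    out = pd.DataFrame(rows, columns=["chemical_id", "pAffinity", "label",
                                      "provenance", "drop_reason"]).set_index("chemical_id")
    return out


def retained_actives(integrated: pd.DataFrame) -> pd.DataFrame:
    """External chemicals that enrich the training set (active, retained)."""
    ext = integrated[(integrated["provenance"] == "external")
                     & (integrated["drop_reason"] == "")]
    return ext[ext["label"] == True]  # noqa: E712 (label is nullable boolean)


@dataclass
class PotencyShiftModel:
    """OLS map from thallium-flux pIC50 to patch-clamp pIC50."""

    intercept: float
    slope: float
    r2: float
    r2_adj: float
    pvalue: float
    n_pairs: int

    def predict(self, thallium_pic50) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(thallium_pic50, dtype=float)

    def predict_ic50_molar(self, thallium_pic50) -> np.ndarray:
        return 10.0 ** (-self.predict(thallium_pic50))

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "slope": self.slope, "r2": self.r2,
                "r2_adj": self.r2_adj, "pvalue": self.pvalue, "n_pairs": self.n_pairs}


def fit_potency_shift(thallium_pic50, patch_pic50) -> PotencyShiftModel:
    """Plain OLS on paired pIC50 values (flux on x, patch clamp on y)."""
    x = np.asarray(thallium_pic50, dtype=float)
    y = np.asarray(patch_pic50, dtype=float)
    if x.shape != y.shape:
        raise IntegrationError("paired pIC50 vectors must have equal length")
    if x.size < 3:
        raise IntegrationError("potency-shift regression needs >= 3 pairs")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope_p = float(model.pvalues[1]) if x.std() > 0 else float("nan")
    return PotencyShiftModel(float(model.params[0]), float(model.params[1]),
                             float(model.rsquared), float(model.rsquared_adj),
                             slope_p, int(x.size))
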