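"""qHTS concentration-response analysis for the thallium-flux hERG assay.

Raw well fluorescence is normalized to percent activity anchored on the
plate controls (DMSO-only wells define 0%, the positive-control median
defines -100%), each compound's concentration series is fit to a
four-parameter Hill model, and the fit is summarized as a curve class
(1-4, by fit significance and asymptote completeness), a signed curve
rank in [-9, 9] (negative = inhibition), and an activity call.

Active-antagonist calls are then pushed through the sequential filter
cascade used to nominate reliable channel inhibitors: antagonist outcome
-> rank in [-9, -5] -> efficacy > 30% -> automated curve inspection ->
structure-standardization pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, NormalizationError

RANK_BASE = {1: 7, 2: 5, 3: 2, 4: 0}
ANTAGONIST_BIN = (-9, -5)
AGONIST_BIN = (5, 9)


@dataclass
class CRCurve:
    """Replicate-averaged, control-normalized concentration-response series."""

    compound_id: str
    conc: np.ndarray            # molar, ascending
    pct: np.ndarray             # % activity, replicate mean per concentration
    pct_replicates: np.ndarray  # shape (n_conc, n_replicates), NaN-padded

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.pct = np.asarray(self.pct, dtype=float)
        if self.conc.shape != self.pct.shape:
            raise FitError("conc and pct series must have equal length")


@dataclass
class HillResult:
    """Four-parameter Hill fit plus qHTS curve categorization."""

    compound_id: str
    ic50: float                 # molar; AC50 of the fit
    hill_slope: float
    top: float                  # % activity asymptote at low concentration
    bottom: float               # % activity asymptote at high concentration
    efficacy: float             # |top - bottom| (class 3: largest observed response)
    direction: int              # -1 inhibition, +1 activation, 0 flat
    curve_class: int            # 1..4
    curve_rank: int             # signed, in [-9, 9]
    pic50: float                # -log10(ic50 in M)
    fit_pvalue: float           # F-test of Hill vs constant model
    residual_sd: float
    monotonicity_violations: int
    inspection_pass: bool
    converged: bool = True

    @property
    def ic50_uM(self) -> float:
        return self.ic50 * 1e6


@dataclass
class ActivityCall:
    compound_id: str
    call: str                   # active_antagonist | agonist | inconclusive | inactive
    reliable_active: bool
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)


def hill(conc, ic50, slope, top, bottom):
    """Four-parameter Hill model: response at concentration ``conc`` (molar).

    ``top`` is the zero-dose asymptote, ``bottom`` the high-concentration
    plateau (so a full inhibitor runs from 0 down to -100), and ``ic50``
    the concentration of half-maximal response.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** slope)


def pic50_to_molar(pic50: float) -> float:
    """pIC50 -> IC50 in molar units (e.g. 4.8 -> 1.585e-5 M = 15.85 uM)."""
    return 10.0 ** (-pic50)


def normalize(wells: pd.DataFrame) -> list[CRCurve]:
    """Normalize raw well values to percent activity using plate controls.

    % Activity = (Vcompound - VDMSO) / (VDMSO - Vpos) * 100, with VDMSO and
    Vpos the plate medians of the DMSO-only and positive-control wells. A
    well at the DMSO median maps to 0%, one at the positive-control median
    to exactly -100%.

    Parameters
    ----------
    wells : DataFrame with columns compound_id, conc_M, replicate,
        raw_value, well_type (compound | dmso | poscon). An optional
        ``plate`` column scopes the control medians per plate.
    """
    required = {"compound_id", "conc_M", "replicate", "raw_value", "well_type"}
    missing = required - set(wells.columns)
    if missing:
        raise NormalizationError(f"missing well columns: {sorted(missing)}")

    curves: list[CRCurve] = []
    groups = wells.groupby("plate", sort=False) if "plate" in wells.columns else [(None, wells)]
    for _, plate in groups:
        dmso = plate.loc[plate["well_type"] == "dmso", "raw_value"]
        pos = plate.loc[plate["well_type"] == "poscon", "raw_value"]
        if dmso.empty or pos.empty:
            raise NormalizationError("plate lacks DMSO and/or positive-control wells")
        v_dmso = float(dmso.median())
        v_pos = float(pos.median())
        if v_dmso == v_pos:
            raise NormalizationError("degenerate controls: DMSO and positive medians are equal")

        cpd = plate[plate["well_type"] == "compound"].copy()
        if not np.isfinite(cpd["raw_value"]).all():
            raise NormalizationError("non-finite raw values in compound wells")
        cpd["pct"] = (cpd["raw_value"] - v_dmso) / (v_dmso - v_pos) * 100.0

        for cid, grp in cpd.groupby("compound_id", sort=False):
            pivot = grp.pivot_table(index="conc_M", columns="replicate",
                                    values="pct", aggfunc="mean").sort_index()
            conc = pivot.index.to_numpy(dtype=float)
            reps = pivot.to_numpy(dtype=float)
            curves.append(CRCurve(str(cid), conc, np.nanmean(reps, axis=1), reps))
    return curves


def normalize_value(raw: float, v_dmso: float, v_pos: float) -> float:
    """The plate-normalization formula for a single well value."""
    if v_dmso == v_pos:
        raise NormalizationError("degenerate controls")
    return (raw - v_dmso) / (v_dmso - v_pos) * 100.0


def _fit_once(conc, pct, p0, bounds):
    res = optimize.least_squares(
        lambda p: hill(conc, 10.0 ** p[0], p[1], p[2], p[3]) - pct,
        p0, bounds=bounds, xtol=1e-12, ftol=1e-12, max_nfev=500)
    return res


def fit_hill(curve: CRCurve, alpha: float = 0.05, n_starts: int = 5,
             efficacy_min: float = 30.0, residual_sd_max: float = 15.0,
             monotonicity_tol: float = 10.0) -> HillResult:
    """Fit the four-parameter Hill model and categorize the curve.

    Multi-start least squares over a grid of log10(IC50) starting points
    (lowest SSE wins); an F-test against the constant model decides whether
    a concentration response is present at level ``alpha``. Curve class:
    1 = significant fit with both asymptotes observed inside the tested
    range, 2 = significant fit with at most one asymptote, 3 = single-point
    activity (no significant fit but the top-concentration response exceeds
    the efficacy cutoff), 4 = no significant response. |rank| = class base
    (7/5/2/0) + efficacy bonus (+2 if >= 80%, +1 if >= 50%), capped at 9,
    signed by response direction.
    """
    conc = np.asarray(curve.conc, dtype=float)
    pct = np.asarray(curve.pct, dtype=float)
    ok = np.isfinite(conc) & np.isfinite(pct)
    conc, pct = conc[ok], pct[ok]
    n = conc.size
    if n < 4:
        raise FitError(f"{curve.compound_id}: need >= 4 concentration points, got {n}")

    sse_const = float(np.sum((pct - pct.mean()) ** 2))
    lo, hi = np.log10(conc.min()), np.log10(conc.max())
    span = max(pct.max() - pct.min(), 1.0)
    bounds = ([lo - 3.0, 0.1, -250.0, -250.0], [hi + 3.0, 10.0, 150.0, 150.0])

    best, converged = None, False
    for log_ic50 in np.linspace(lo, hi, n_starts):
        p0 = [log_ic50, 1.0, float(pct[0]), float(pct[-1])]
        try:
            res = _fit_once(conc, pct, p0, bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best, converged = res, True
        if best.cost <= 1e-16 * n:   # exact fit; further starts cannot improve
            break

    if not converged:
        # flagged non-convergence: flat-curve summary, class 4
        resid_sd = float(np.std(pct - pct.mean(), ddof=0))
        return HillResult(curve.compound_id, np.nan, np.nan, np.nan, np.nan, 0.0, 0,
                          4, 0, np.nan, 1.0, resid_sd, 0, False, converged=False)

    log_ic50, slope, top, bottom = best.x
    ic50 = 10.0 ** log_ic50
    resid = hill(conc, ic50, slope, top, bottom) - pct
    sse_hill = float(np.sum(resid ** 2))

    # F-test, Hill (4 params) vs constant (1 param)
    df1, df2 = 3, n - 4
    if sse_const <= 1e-12 or df2 <= 0:
        pvalue = 1.0
    elif sse_hill <= 1e-12:
        pvalue = 0.0
    else:
        f = ((sse_const - sse_hill) / df1) / (sse_hill / df2)
        pvalue = float(stats.f.sf(f, df1, df2))
    significant = pvalue < alpha

    efficacy = abs(top - bottom)
    direction = 0
    if efficacy > 0:
        direction = -1 if bottom < top else 1

    # asymptote completeness within the tested concentration range
    r_lo = hill(conc.min(), ic50, slope, top, bottom)
    r_hi = hill(conc.max(), ic50, slope, top, bottom)
    tol = 0.1 * max(efficacy, 1e-9)
    top_seen = abs(r_lo - top) <= tol
    bottom_seen = abs(r_hi - bottom) <= tol

    if significant:
        curve_class = 1 if (top_seen and bottom_seen) else 2
    else:
        last = float(pct[-1])
        if abs(last) > efficacy_min:
            curve_class = 3
            efficacy = abs(last)
            direction = -1 if last < 0 else 1
        else:
            curve_class = 4
            efficacy = 0.0
            direction = 0

    bonus = 2 if efficacy >= 80.0 else (1 if efficacy >= 50.0 else 0)
    magnitude = min(RANK_BASE[curve_class] + (bonus if curve_class < 4 else 0), 9)
    curve_rank = int(direction * magnitude)

    if curve_class == 4:
        # no significant concentration response: potency is undefined
        ic50, slope, top, bottom = np.nan, np.nan, np.nan, np.nan

    resid_sd = float(np.sqrt(sse_hill / n)) if curve_class < 4 else float(np.std(pct, ddof=0))
    diffs = np.diff(pct)
    if direction <= 0:
        violations = int(np.sum(diffs > monotonicity_tol))
    else:
        violations = int(np.sum(diffs < -monotonicity_tol))
    inspection = (resid_sd <= residual_sd_max) and (violations <= 1)

    return HillResult(curve.compound_id, float(ic50), float(slope), float(top),
                      float(bottom), float(efficacy), direction, curve_class,
                      curve_rank, float(-np.log10(ic50)), pvalue, resid_sd,
                      violations, inspection)


def call_activity(h: HillResult, efficacy_min: float = 30.0) -> ActivityCall:
    """Map a fitted curve to an activity outcome by its rank bin.

    Rank 0 -> inactive; -5..-9 -> active antagonist; 5..9 -> agonist;
    the remaining -4..4 band -> inconclusive. A reliable active is an
    antagonist whose efficacy exceeds ``efficacy_min`` percent and whose
    automated curve inspection passed.
    """
    r = h.curve_rank
    if not -9 <= r <= 9:
        raise FitError(f"curve rank {r} outside [-9, 9]")
    if r == 0:
        call = "inactive"
    elif ANTAGONIST_BIN[0] <= r <= ANTAGONIST_BIN[1]:
        call = "active_antagonist"
    elif AGONIST_BIN[0] <= r <= AGONIST_BIN[1]:
        call = "agonist"
    else:
        call = "inconclusive"

    trace = [
        ("antagonist_rank_bin", call == "active_antagonist"),
        ("efficacy_gt_min", h.efficacy > efficacy_min),
        ("inspection_pass", h.inspection_pass),
    ]
    reliable = all(passed for _, passed in trace)
    return ActivityCall(h.compound_id, call, reliable, trace)


def filter_cascade(results: list[HillResult],
                   standardization_ok: dict[str, bool] | None = None,
                   efficacy_min: float = 30.0) -> pd.Series:
    """Sequential active-antagonist selection counts.

    Steps, applied in order (each within the survivors of the previous):
    initial antagonist outcome (negative rank), curve rank in [-9, -5],
    efficacy > ``efficacy_min``, automated curve-inspection pass, and
    structure-standardization pass. Counts are non-increasing.
    """
    survivors = [h for h in results if h.curve_rank < 0]
    counts = {"initial_antagonists": len(survivors)}
    survivors = [h for h in survivors
                 if ANTAGONIST_BIN[0] <= h.curve_rank <= ANTAGONIST_BIN[1]]
    counts["rank_-9_to_-5"] = len(survivors)
    survivors = [h for h in survivors if h.efficacy > efficacy_min]
    counts["efficacy_gt_30"] = len(survivors)
    survivors = [h for h in survivors if h.inspection_pass]
    counts["inspection_pass"] = len(survivors)
    if standardization_ok is not None:
        survivors = [h for h in survivors if standardization_ok.get(h.compound_id, False)]
    counts["standardization_pass"] = len(survivors)
    return pd.Series(counts, name="n_active")


def results_table(results: list[HillResult], calls: list[ActivityCall]) -> pd.DataFrame:
    """Per-compound summary table (one row per compound)."""
    by_id = {c.compound_id: c for c in calls}
    rows = []
    for h in results:
        c = by_id[h.compound_id]
        rows.append({
            "compound_id": h.compound_id, "ic50_M": h.ic50, "pic50": h.pic50,
            "efficacy": h.efficacy, "curve_class": h.curve_class,
            "curve_rank": h.curve_rank, "fit_pvalue": h.fit_pvalue,
            "call": c.call, "reliable_active": c.reliable_active,
        })
    return pd.DataFrame(rows)
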