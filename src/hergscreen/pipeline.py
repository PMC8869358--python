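"""End-to-end orchestration of the screening analysis.

Stages run in order: synthetic generation -> plate normalization and
curve fitting -> activity calls and the sequential filter cascade ->
structure curation and descriptor selection -> SOM clustering ->
chemotype enrichment -> QSAR training with applicability domain ->
external bioactivity integration and the potency-shift model. Every run
lands in its own directory with a manifest recording the configuration
hash and seed; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ad, clustering, curation, enrichment, integration, qhts, qsar, synthetic
from .config import RunConfig
from .errors import PipelineError


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None,
                 run_name: str | None = None) -> dict:
    """Execute the full pipeline; returns in-memory results per stage.

    When ``out_dir`` is given, per-stage CSVs plus ``manifest.json`` are
    written under ``<out_dir>/<run_name or timestamp-confighash>/``. A
    stage failure raises a stage-tagged :class:`PipelineError`; outputs
    written up to that point are preserved.
    """
    results: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    run_dir = None
    if out_dir is not None:
        name = run_name or f"{time.strftime('%Y%m%d-%H%M%S')}-{results['config_hash']}"
        run_dir = Path(out_dir) / name
        run_dir.mkdir(parents=True, exist_ok=True)
        results["run_dir"] = str(run_dir)

    def save(name: str, df: pd.DataFrame, index=False):
        if run_dir is not None:
            df.to_csv(run_dir / f"{name}.csv", index=index)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return deco

    # --- synthetic inputs -------------------------------------------------
    @stage("synth")
    def _():
        wells, truth = synthetic.generate_plate(cfg.synth)
        molecules = synthetic.generate_molecules(cfg.synth)
        chemotypes, planted = synthetic.generate_chemotypes(
            cfg.synth, molecules.set_index("id")["true_label"])
        records = synthetic.generate_bioactivity_records(cfg.synth)
        results.update(wells=wells, truth=truth, molecules=molecules,
                       chemotypes=chemotypes, planted_chemotypes=planted,
                       bioactivity=records)
        save("wells", wells)
        save("molecules", molecules)
        save("bioactivity", records)

    # --- qHTS curve analysis ---------------------------------------------
    @stage("qhts")
    def _():
        curves = qhts.normalize(results["wells"])
        fits = [qhts.fit_hill(c, alpha=cfg.fit_alpha, efficacy_min=cfg.efficacy_min)
                for c in curves]
        calls = [qhts.call_activity(h, efficacy_min=cfg.efficacy_min) for h in fits]
        results.update(fits=fits, calls=calls,
                       qhts_table=qhts.results_table(fits, calls))
        save("qhts_results", results["qhts_table"])

    # --- structure curation ----------------------------------------------
    @stage("curation")
    def _():
        mols = results["molecules"]
        structs = curation.standardize(zip(mols["id"], mols["smiles"]))
        desc = curation.compute_descriptors(structs)
        desc = curation.select_descriptors(desc, rho_max=cfg.rho_max,
                                           ident_frac=cfg.ident_frac, seed=cfg.seed)
        ok = {s.id: s.ok for s in structs}
        cascade = qhts.filter_cascade(results["fits"], standardization_ok=ok,
                                      efficacy_min=cfg.efficacy_min)
        results.update(structures=structs, descriptors=desc, cascade=cascade)
        save("filter_cascade", cascade.to_frame(), index=True)
        save("descriptors", desc.to_frame(retained_only=True), index=True)

    # --- clustering -------------------------------------------------------
    @stage("clustering")
    def _():
        desc = results["descriptors"]
        labels = results["molecules"].set_index("id")["true_label"].reindex(desc.ids)
        som = clustering.train_som(desc, grid=cfg.som_grid,
                                   epochs=cfg.som_epochs, seed=cfg.seed)
        unit_map = clustering.cluster_enrichment_map(som, labels)
        results.update(som=som, unit_map=unit_map)
        save("som_units", unit_map, index=True)
        actives = labels.index[labels.fillna(False)].tolist()
        if len(actives) >= 2:
            results["dendrogram"] = clustering.hcluster_actives(desc, actives)

    # --- chemotype enrichment --------------------------------------------
    @stage("enrichment")
    def _():
        desc = results["descriptors"]
        labels = results["molecules"].set_index("id")["true_label"]
        mat = results["chemotypes"].reindex(labels.index)
        results["enrichment"] = enrichment.screen_chemotypes(mat, labels, alpha=cfg.alpha)
        save("enrichment", results["enrichment"])

    # --- QSAR + applicability domain -------------------------------------
    @stage("qsar")
    def _():
        desc = results["descriptors"]
        X = desc.to_frame(retained_only=True)
        labels = results["molecules"].set_index("id")["true_label"].reindex(X.index)
        plan = qsar.make_split(labels, test_frac=cfg.test_frac,
                               n_subsets=cfg.n_subsets,
                               active_ratio=cfg.active_ratio, seed=cfg.seed)
        bundles = {algo: qsar.train_bundle(X, labels, algo, plan,
                                           cv_folds=cfg.cv_folds,
                                           undersample=cfg.undersample, seed=cfg.seed)
                   for algo in cfg.algorithms}
        results.update(split=plan, bundles=bundles)

        ad_model = ad.fit_ad(X.loc[plan.train_ids].to_numpy(),
                             var_target=cfg.ad_var_target, border=cfg.ad_border)
        scores = ad.score_table(ad_model, X.to_numpy(), list(X.index))
        first = bundles[cfg.algorithms[0]]
        pred = pd.DataFrame({"probability": first.predict_proba(X),
                             "call": first.predict(X)}, index=X.index).join(scores)
        results.update(ad_model=ad_model, predictions=pred)
        save("predictions", pred, index=True)
        for algo, b in bundles.items():
            save(f"metrics_{algo}", b.metric_summary(), index=True)

    # --- external bioactivity integration --------------------------------
    @stage("integration")
    def _():
        integrated = integration.integrate_records(
            results["bioactivity"], paffinity_min=cfg.paffinity_min,
            max_log10_gap=cfg.max_log10_gap)
        results["integrated"] = integrated
        save("integrated_labels", integrated, index=True)

        # potency-shift model on compounds with both flux fits and external
        # patch-clamp potencies (synthetic ids differ, so pair by rank order
        # of potency when no shared ids exist — the model is exercised on
        # whatever paired data the inputs provide)
        table = results["qhts_table"]
        flux = table.loc[table["reliable_active"], "pic50"].dropna()
        ext = integrated["pAffinity"].dropna()
        n = min(len(flux), len(ext))
        if n >= 3:
            x = np.sort(flux.to_numpy())[:n]
            y = np.sort(ext.to_numpy())[:n]
            results["potency_shift"] = integration.fit_potency_shift(x, y)
            if run_dir is not None:
                (run_dir / "potency_shift.json").write_text(
                    json.dumps(results["potency_shift"].to_dict(), indent=2))

    if run_dir is not None:
        manifest = {"config": cfg.to_dict(), "config_hash": results["config_hash"],
                    "seed": cfg.seed}
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
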