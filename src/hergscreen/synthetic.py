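"""Seeded synthetic inputs emulating a qHTS hERG screening campaign.

Four generators produce everything the pipeline consumes:

* ``generate_plate`` — raw fluorescence wells: DMSO-only wells around a
  fixed plate level, positive-control (astemizole-like) wells at the
  fully-inhibited level, and compound wells in triplicate. Active
  compounds follow a four-parameter Hill inhibition curve between those
  two anchors; inactive compounds are flat at the DMSO level. Gaussian
  noise scales with the control signal window. True parameters are
  returned alongside for recovery tests.
* ``generate_molecules`` — a molecule table built from a hardcoded SMILES
  vocabulary (drugs, surfactants, pesticides and small organics typical
  of an environmental-chemical library) plus random substituent sampling.
  Activity labels follow a planted structure-activity rule (tertiary or
  quaternary nitrogen AND MolLogP >= 3 multiplies the odds of activity),
  so descriptor-based models are learnable; an odds multiplier of 1
  removes all signal.
* ``generate_chemotypes`` — a binary chemical x chemotype matrix with a
  planted subset of chemotypes whose prevalence odds in actives are
  multiplied by the configured enrichment effect.
* ``generate_bioactivity_records`` — ChEMBL-style potency records
  (IC50/Ki/EC50, patch-clamp vs other assay formats, exact/censored
  flags) with configurable duplication and occasional >1 log10 conflicts.

Identical config + seed yields byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen
from scipy.optimize import brentq

from .config import SynthConfig
from .errors import ConfigError
from .qhts import hill

# ---------------------------------------------------------------------------
# SMILES vocabulary: named actives from the screen (drugs, quaternary
# ammonium surfactants, pesticides) and generic low-logP organics.
# ---------------------------------------------------------------------------
VOCABULARY: dict[str, str] = {
    # drugs with reported hERG liability (amine-rich, lipophilic)
    "tamoxifen": r"CC/C(=C(\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
    "cyproheptadine": "CN1CCC(=C2c3ccccc3C=Cc3ccccc32)CC1",
    "butenafine": "CC(C)(C)c1ccc(CN(C)Cc2cccc3ccccc23)cc1",
    "haloperidol": "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1",
    "terfenadine": "CC(C)(C)c1ccc(C(O)CCCN2CCC(C(O)(c3ccccc3)c3ccccc3)CC2)cc1",
    "astemizole": "COc1ccc(CCN2CCC(Nc3nc4ccccc4n3Cc3ccc(F)cc3)CC2)cc1",
    "amiodarone": "CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1",
    "loperamide": "CN(C)C(=O)C(CCN1CCC(O)(c2ccc(Cl)cc2)CC1)(c1ccccc1)c1ccccc1",
    "bepridil": "CC(C)COCC(CN(Cc1ccccc1)c1ccccc1)N1CCCC1",
    "fluspirilene": "O=C1NCN(c2ccccc2)C12CCN(CCCC(c1ccc(F)cc1)c1ccc(F)cc1)CC2",
    "pimozide": "O=c1[nH]c2ccccc2n1C1CCN(CCCC(c2ccc(F)cc2)c2ccc(F)cc2)CC1",
    "clemastine": "CC(c1ccc(Cl)cc1)(OCCC1CCCN1C)c1ccccc1",
    "domperidone": "O=c1[nH]c2ccccc2n1C1CCN(CCCN2c3ccccc3NC2=O)CC1",  # simplified analog
    "imipramine": "CN(C)CCCN1c2ccccc2CCc2ccccc21",
    "chlorpromazine": "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "vanoxerine_like": "Fc1ccc(C(OCCN2CCN(CCCc3ccccc3)CC2)c2ccc(F)cc2)cc1",
    # quaternary ammonium surfactants (QACs)
    "dodecyltrimethylammonium": "CCCCCCCCCCCC[N+](C)(C)C",
    "benzyldimethyldodecylammonium": "CCCCCCCCCCCC[N+](C)(C)Cc1ccccc1",
    "didecyldimethylammonium": "CCCCCCCCCC[N+](C)(C)CCCCCCCCCC",
    "benzethonium_like": "CC(C)(C)CC(C)(C)c1ccc(OCCOCC[N+](C)(C)Cc2ccccc2)cc1",
    "methyltrioctylammonium": "CCCCCCCC[N+](C)(CCCCCCCC)CCCCCCCC",
    "n_methyldioctylamine": "CCCCCCCCN(C)CCCCCCCC",
    "tributylamine": "CCCCN(CCCC)CCCC",
    # pesticides / industrial chemicals
    "dicofol": "OC(c1ccc(Cl)cc1)(c1ccc(Cl)cc1)C(Cl)(Cl)Cl",
    "parathion": "CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1",
    "lindane": "ClC1C(Cl)C(Cl)C(Cl)C(Cl)C1Cl",
    "triphenyl_phosphate": "O=P(Oc1ccccc1)(Oc1ccccc1)Oc1ccccc1",
    "tris_dibromopropyl_phosphate": "O=P(OCC(Br)CBr)(OCC(Br)CBr)OCC(Br)CBr",
    "allethrin_like": "CC1(C)C(C=C(C)C)C1C(=O)OC1C(C)=CC(=O)C1CC=C",
    "oxadiazon_like": "CC(C)Oc1cc(N2C(=O)OC(C(C)(C)C)=N2)c(Cl)cc1Cl",
    "ddt": "Clc1ccc(C(c2ccc(Cl)cc2)C(Cl)(Cl)Cl)cc1",
    "pentachlorophenol": "Oc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl",
    # generic low-liability organics
    "ethanol": "CCO",
    "acetic_acid": "CC(=O)O",
    "glycerol": "OCC(O)CO",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "benzoic_acid": "O=C(O)c1ccccc1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "glucose_open": "OCC(O)C(O)C(O)C(O)C=O",
    "urea": "NC(N)=O",
    "citric_acid": "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "nicotinamide": "NC(=O)c1cccnc1",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "salicylic_acid": "O=C(O)c1ccccc1O",
    "vanillin": "COc1cc(C=O)ccc1O",
    "sorbitol": "OCC(O)C(O)C(O)C(O)CO",
    "succinic_acid": "O=C(O)CCC(=O)O",
    "ethyl_acetate": "CCOC(=O)C",
    "dimethyl_phthalate": "COC(=O)c1ccccc1C(=O)OC",
    "hydroquinone": "Oc1ccc(O)cc1",
    "anisole": "COc1ccccc1",
    "cyclohexanol": "OC1CCCCC1",
    "butanoic_acid": "CCCC(=O)O",
    "lactic_acid": "CC(O)C(=O)O",
    "pyridine": "c1ccncc1",
    "morpholine_acetamide": "CC(=O)N1CCOCC1",
    "glycine": "NCC(=O)O",
}


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([seed, tag])


def concentration_series(cfg: SynthConfig) -> np.ndarray:
    """Geometric series descending ``conc_range_decades`` from ``top_conc``."""
    return np.geomspace(cfg.top_conc * 10 ** (-cfg.conc_range_decades),
                        cfg.top_conc, cfg.conc_points)


# ---------------------------------------------------------------------------
# plate generator
# ---------------------------------------------------------------------------

def generate_plate(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw plate wells plus the ground-truth parameter table.

    Returns ``(wells, truth)``. Wells columns: well_id, compound_id,
    conc_M, replicate, raw_value, well_type. Truth columns: compound_id,
    is_active, ic50_M, hill_slope, top, bottom, efficacy.
    """
    rng = _stream_rng(cfg.seed, 1)
    conc = concentration_series(cfg)
    window = cfg.dmso_level - cfg.poscon_level
    sd = cfg.noise_sd * abs(window)

    n_active = int(round(cfg.frac_active * cfg.n_compounds))
    active = np.zeros(cfg.n_compounds, dtype=bool)
    active[rng.choice(cfg.n_compounds, size=n_active, replace=False)] = True

    lo, hi = cfg.planted_ic50_range
    truth_rows, well_rows = [], []
    wid = 0
    for w in range(cfg.n_dmso_wells):
        well_rows.append((f"W{wid:06d}", "", np.nan, 0, cfg.dmso_level + rng.normal(0, sd), "dmso"))
        wid += 1
    for w in range(cfg.n_poscon_wells):
        well_rows.append((f"W{wid:06d}", "", np.nan, 0, cfg.poscon_level + rng.normal(0, sd), "poscon"))
        wid += 1

    for i in range(cfg.n_compounds):
        cid = f"CPD{i:05d}"
        if active[i]:
            ic50 = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            slope = rng.uniform(0.8, 2.0)
            top = 0.0
            bottom = rng.uniform(-100.0, -40.0)
            pct_true = hill(conc, ic50, slope, top, bottom)
        else:
            ic50, slope, top, bottom = np.nan, np.nan, 0.0, 0.0
            pct_true = np.zeros_like(conc)
        truth_rows.append((cid, bool(active[i]), ic50, slope, top, bottom, abs(top - bottom)))
        for rep in range(cfg.n_replicates):
            raw = cfg.dmso_level + pct_true / 100.0 * window + rng.normal(0, sd, conc.size)
            for c, v in zip(conc, raw):
                well_rows.append((f"W{wid:06d}", cid, c, rep, v, "compound"))
                wid += 1

    wells = pd.DataFrame(well_rows, columns=["well_id", "compound_id", "conc_M",
                                             "replicate", "raw_value", "well_type"])
    truth = pd.DataFrame(truth_rows, columns=["compound_id", "is_active", "ic50_M",
                                              "hill_slope", "top", "bottom", "efficacy"])
    return wells, truth


# ---------------------------------------------------------------------------
# molecule generator
# ---------------------------------------------------------------------------

_CHAINS = ["CCCC", "CCCCCC", "CCCCCCCC", "CCCCCCCCCC", "CCCCCCCCCCCC"]
_ARYL_SUBS = ["Cl", "Br", "F", "O", "OC", "C(=O)O", "C(=O)C", "[N+](=O)[O-]", "C(C)C"]


def _random_smiles(rng: np.random.Generator) -> str:
    """Random, valid structure assembled from simple templates."""
    kind = rng.integers(6)
    if kind == 0:   # quaternary ammonium, long chain
        chain = _CHAINS[rng.integers(2, len(_CHAINS))]
        head = "Cc1ccccc1" if rng.random() < 0.5 else "C"
        return f"{chain}[N+](C)(C){head}"
    if kind == 1:   # tertiary amine with aryl/bulky substitution
        chain = _CHAINS[rng.integers(len(_CHAINS))]
        aryl = f"c1ccc({_ARYL_SUBS[rng.integers(len(_ARYL_SUBS))]})cc1"
        return f"{chain}N(C)CC{aryl}"
    if kind == 2:   # substituted aromatic
        sub = _ARYL_SUBS[rng.integers(len(_ARYL_SUBS))]
        return f"c1ccc({sub})cc1"
    if kind == 3:   # ester / small polar
        chain = _CHAINS[rng.integers(2)]
        return f"{chain}OC(=O)C{'C' * int(rng.integers(4))}"
    if kind == 4:   # halogenated alkane
        n = int(rng.integers(2, 6))
        return "Cl" + "C" * n + "Cl"
    # alcohol / acid
    n = int(rng.integers(2, 8))
    return "C" * n + ("O" if rng.random() < 0.5 else "C(=O)O")


_TERT_QUAT_N = [Chem.MolFromSmarts("[NX3;H0;!$(N-C=O);!$(N=*)]"),
                Chem.MolFromSmarts("[NX4+]")]


def planted_rule(smiles: str) -> bool:
    """The planted structure-activity rule: tertiary/quaternary nitrogen
    AND Crippen MolLogP >= 3."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    has_n = any(mol.HasSubstructMatch(p) for p in _TERT_QUAT_N)
    return has_n and Crippen.MolLogP(mol) >= 3.0


def _solve_base_prob(frac_active: float, prevalence: float, effect: float) -> float:
    """Base activity probability p0 such that the rule-satisfying group,
    with odds(p1) = effect * odds(p0), yields the target overall fraction."""
    if effect == 1.0 or prevalence in (0.0, 1.0):
        return frac_active

    def mean_p(p0):
        odds = p0 / (1 - p0) * effect
        p1 = odds / (1 + odds)
        return prevalence * p1 + (1 - prevalence) * p0 - frac_active

    eps = 1e-9
    if mean_p(eps) > 0:
        return eps
    return brentq(mean_p, eps, frac_active)


def generate_molecules(cfg: SynthConfig) -> pd.DataFrame:
    """Molecule table: id, smiles, true_label (bool), rule (bool).

    Labels are Bernoulli with rule-dependent probability: odds are
    multiplied by ``cfg.enrichment_effect`` when the planted rule holds,
    with the base probability solved so the expected active fraction
    equals ``cfg.frac_active``. ``cfg.label_noise`` flips labels at random.
    """
    if not VOCABULARY:
        raise ConfigError("empty SMILES vocabulary")
    rng = _stream_rng(cfg.seed, 2)
    vocab = sorted(VOCABULARY.items())

    ids, smiles = [], []
    for i in range(cfg.n_compounds):
        if rng.random() < 0.4:
            smi = vocab[int(rng.integers(len(vocab)))][1]
        else:
            smi = _random_smiles(rng)
        ids.append(f"CPD{i:05d}")
        smiles.append(smi)

    rule = np.array([planted_rule(s) for s in smiles])
    prevalence = float(rule.mean())
    p0 = _solve_base_prob(cfg.frac_active, prevalence, cfg.enrichment_effect)
    odds1 = p0 / (1 - p0) * cfg.enrichment_effect
    p1 = odds1 / (1 + odds1)
    p = np.where(rule, p1, p0)
    labels = rng.random(cfg.n_compounds) < p
    if cfg.label_noise > 0:
        flip = rng.random(cfg.n_compounds) < cfg.label_noise
        labels = labels ^ flip
    return pd.DataFrame({"id": ids, "smiles": smiles,
                         "true_label": labels, "rule": rule})


# ---------------------------------------------------------------------------
# chemotype matrix
# ---------------------------------------------------------------------------

def generate_chemotypes(cfg: SynthConfig, labels: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Binary chemical x chemotype matrix with planted enrichment.

    The first ``cfg.n_planted_chemotypes`` chemotypes have their
    prevalence odds in active chemicals multiplied by
    ``cfg.enrichment_effect``; the rest share one prevalence in both arms.
    Returns the matrix (indexed by chemical id) and the planted names.
    """
    rng = _stream_rng(cfg.seed, 3)
    n = len(labels)
    active = labels.to_numpy(dtype=bool)
    names = [f"CT{j:04d}" for j in range(cfg.chemotype_count)]
    planted = names[: cfg.n_planted_chemotypes]
    base = rng.uniform(0.05, 0.30, cfg.chemotype_count)

    cols = {}
    for j, name in enumerate(names):
        p = np.full(n, base[j])
        if name in planted:
            odds = base[j] / (1 - base[j]) * cfg.enrichment_effect
            p[active] = odds / (1 + odds)
        cols[name] = rng.random(n) < p
    mat = pd.DataFrame(cols, index=labels.index).astype(int)
    return mat, planted


# ---------------------------------------------------------------------------
# bioactivity records
# ---------------------------------------------------------------------------

def generate_bioactivity_records(cfg: SynthConfig) -> pd.DataFrame:
    """ChEMBL-style potency records with duplicates and planted conflicts.

    Columns: chemical_id, endpoint (IC50|Ki|EC50), value_M, exact (bool),
    assay (patch_clamp|other), source. A ``cfg.duplicate_fraction`` of
    chemicals carry a second concordant record; a ``cfg.conflict_fraction``
    carry a patch-clamp duplicate disagreeing by more than one log10 (these
    chemicals are removed downstream); ``cfg.censored_fraction`` of records
    are censored ("<"/">" style, exact=False).
    """
    rng = _stream_rng(cfg.seed, 4)
    endpoints = np.array(["IC50", "Ki", "EC50"])
    rows = []
    for i in range(cfg.n_compounds):
        cid = f"EXT{i:05d}"
        paff = rng.normal(6.0, 1.0)   # centered on the 1 uM activity cutoff
        value = 10.0 ** (-paff)
        assay = "patch_clamp" if rng.random() < 0.5 else "other"
        exact = rng.random() >= cfg.censored_fraction
        rows.append((cid, endpoints[rng.integers(3)], value, exact, assay, "synthetic"))
        u = rng.random()
        if u < cfg.conflict_fraction:
            # conflicting patch-clamp pair: gap > 1 log10 on both records
            gap = rng.uniform(1.2, 2.5)
            rows[-1] = (cid, "IC50", value, True, "patch_clamp", "synthetic")
            rows.append((cid, "IC50", value * 10 ** gap, True, "patch_clamp", "synthetic"))
        elif u < cfg.conflict_fraction + cfg.duplicate_fraction:
            jitter = rng.uniform(-0.4, 0.4)
            rows.append((cid, endpoints[rng.integers(3)], value * 10 ** jitter,
                         True, assay, "synthetic"))
    return pd.DataFrame(rows, columns=["chemical_id", "endpoint", "value_M",
                                       "exact", "assay", "source"])
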