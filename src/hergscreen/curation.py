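"""Structure curation and descriptor engineering for QSAR modeling.

Structures are brought to a QSAR-ready form (sanitized, metal-free,
desalted to the largest organic fragment, stereochemistry re-perceived;
mixtures rejected), numeric 1D/2D descriptors are computed with RDKit,
and the descriptor block is reduced to an informative, non-redundant set:
null-variance and >90%-identical columns are dropped, then descriptors
are clustered on |Pearson rho| > 0.9 (connected components) and one
seeded-random representative is kept per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.AllChem import ComputeGasteigerCharges

from .errors import CurationError

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

# organic subset: anything outside it is treated as a metal/metalloid ion
_ORGANIC_Z = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}

# common counterions/solvates sieved out before the mixture check
_SALT_SMILES = {
    "O", "Cl", "Br", "I", "F", "N", "O=S(=O)(O)O", "O=[N+]([O-])O",
    "CC(=O)O", "CC(=O)[O-]", "C(=O)O", "OC(=O)C(O)C(O)C(=O)O",
    "OC(=O)/C=C\\C(=O)O", "OC(=O)/C=C/C(=O)O", "OC(=O)C(O)O",
    "CS(=O)(=O)O", "Cc1ccc(S(=O)(=O)O)cc1", "OC(=O)C(F)(F)F",
    "OC(=O)CC(O)(CC(=O)O)C(=O)O", "OC(=O)C(=O)O",
}
_SALT_CANON = {Chem.CanonSmiles(s) for s in _SALT_SMILES}


@dataclass
class CuratedStructure:
    id: str
    smiles_raw: str
    smiles_qsar_ready: str | None
    status: str  # ok | removed_mixture | removed_metal | removed_invalid

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class DescriptorMatrix:
    """Chemicals x numeric descriptors with a retained-descriptor mask."""

    ids: list[str]
    names: list[str]
    values: np.ndarray
    retained_mask: np.ndarray = None
    corr_clusters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.retained_mask is None:
            self.retained_mask = np.ones(len(self.names), dtype=bool)

    def to_frame(self, retained_only: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.names)
        return df.loc[:, self.retained_mask] if retained_only else df


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() not in _ORGANIC_Z for a in mol.GetAtoms())


def standardize(records) -> list[CuratedStructure]:
    """QSAR-ready standardization of (id, smiles) records.

    Applied in order: parse+sanitize, strip explicit hydrogens, reject
    metal-containing species, sieve salt/solvent fragments, keep the
    largest organic fragment, re-perceive stereochemistry. Two or more
    surviving organic fragments constitute a mixture and are rejected.
    Unparseable input is flagged, never raised.
    """
    out = []
    for cid, smi in records:
        cid = str(cid)
        mol = Chem.MolFromSmiles(smi)  # parses + sanitizes
        if mol is None:
            out.append(CuratedStructure(cid, smi, None, "removed_invalid"))
            continue
        mol = Chem.RemoveHs(mol)
        if _contains_metal(mol):
            out.append(CuratedStructure(cid, smi, None, "removed_metal"))
            continue
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        organic, salt_organic = [], []
        for f in frags:
            can = Chem.MolToSmiles(f)
            if not any(a.GetAtomicNum() == 6 for a in f.GetAtoms()):
                continue  # bare inorganic counterion / solvate
            if can in _SALT_CANON:
                salt_organic.append((f.GetNumHeavyAtoms(), can, f))
            else:
                organic.append((f.GetNumHeavyAtoms(), can, f))
        if not organic and salt_organic:
            # the chemical IS a listed counterion species (e.g. acetic acid)
            organic = [max(salt_organic)]
        if not organic:
            out.append(CuratedStructure(cid, smi, None, "removed_invalid"))
            continue
        if len(organic) >= 2:
            out.append(CuratedStructure(cid, smi, None, "removed_mixture"))
            continue
        keep = organic[0][2]
        try:
            Chem.AssignStereochemistry(keep, cleanIt=True, force=True)
            qsar_smiles = Chem.MolToSmiles(keep)
        except Exception:
            out.append(CuratedStructure(cid, smi, None, "removed_invalid"))
            continue
        out.append(CuratedStructure(cid, smi, qsar_smiles, "ok"))
    return out


def write_sdf(structs: list[CuratedStructure], path) -> int:
    """Write the QSAR-ready structures to an SDF file; returns the count."""
    writer = Chem.SDWriter(str(path))
    n = 0
    for s in structs:
        if not s.ok:
            continue
        mol = Chem.MolFromSmiles(s.smiles_qsar_ready)
        mol.SetProp("_Name", s.id)
        writer.write(mol)
        n += 1
    writer.close()
    return n


def _nitrogen_charges(mol: Chem.Mol) -> tuple[float, float]:
    """(QNss, QNmin): sum of squared Gasteiger charges on N and the most
    negative N charge; (0, 0) for nitrogen-free molecules."""
    ns = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 7]
    if not ns:
        return 0.0, 0.0
    ComputeGasteigerCharges(mol)
    q = np.array([float(a.GetProp("_GasteigerCharge")) for a in ns])
    q = q[np.isfinite(q)]
    if q.size == 0:
        return 0.0, 0.0
    return float(np.sum(q ** 2)), float(np.min(q))


_BCUT_NAMES = ["bcut_mwhi", "bcut_mwlo", "bcut_chghi", "bcut_chglo",
               "bcut_logphi", "bcut_logplo", "bcut_mrhi", "bcut_mrlo"]


def _descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    logp = Crippen.MolLogP(mol)
    qnss, qnmin = _nitrogen_charges(mol)
    row = {
        "MolLogP": logp,
        "MolLogP2": logp ** 2,
        "MolMR": Crippen.MolMR(mol),
        "MolWt": Descriptors.MolWt(mol),
        "BalabanJ": Descriptors.BalabanJ(mol),
        "SMR_VSA3": Descriptors.SMR_VSA3(mol),
        "HeavyAtomCount": Descriptors.HeavyAtomCount(mol),
        "ArBondCount": float(sum(b.GetIsAromatic() for b in mol.GetBonds())),
        "QNss": qnss,
        "QNmin": qnmin,
        "TPSA": Descriptors.TPSA(mol),
        "NumHAcceptors": Descriptors.NumHAcceptors(mol),
        "NumHDonors": Descriptors.NumHDonors(mol),
        "NumRotatableBonds": Descriptors.NumRotatableBonds(mol),
        "RingCount": Descriptors.RingCount(mol),
        "NumAromaticRings": Descriptors.NumAromaticRings(mol),
        "FractionCSP3": Descriptors.FractionCSP3(mol),
        "NumHeteroatoms": Descriptors.NumHeteroatoms(mol),
        "NHOHCount": Descriptors.NHOHCount(mol),
        "NOCount": Descriptors.NOCount(mol),
        "Chi0v": Descriptors.Chi0v(mol),
        "Chi1v": Descriptors.Chi1v(mol),
        "Kappa1": Descriptors.Kappa1(mol),
        "Kappa2": Descriptors.Kappa2(mol),
        "HallKierAlpha": Descriptors.HallKierAlpha(mol),
        "LabuteASA": Descriptors.LabuteASA(mol),
    }
    try:
        bcut = rdMolDescriptors.BCUT2D(mol)
        row.update(dict(zip(_BCUT_NAMES, bcut)))
    except Exception:
        # Burden eigenvalues lack parameters for some atoms; leave NaN -> row dropped
        row.update({n: np.nan for n in _BCUT_NAMES})
    return row


def compute_descriptors(structs: list[CuratedStructure],
                        extra: pd.DataFrame | None = None) -> DescriptorMatrix:
    """1D/2D descriptor block for QSAR-ready structures.

    ``extra`` merges optional externally predicted columns (e.g. OPERA-style
    physicochemical predictions) by chemical id. Chemicals whose descriptor
    computation fails (non-finite values) are dropped with a log entry.
    """
    ids, rows = [], []
    for s in structs:
        if not s.ok:
            continue
        mol = Chem.MolFromSmiles(s.smiles_qsar_ready)
        if mol is None:
            log.warning("descriptor computation: %s no longer parses, dropped", s.id)
            continue
        row = _descriptor_row(mol)
        if not all(np.isfinite(v) for v in row.values()):
            log.warning("descriptor computation failed for %s, row dropped", s.id)
            continue
        ids.append(s.id)
        rows.append(row)
    if not rows:
        raise CurationError("no chemical survived descriptor computation")
    df = pd.DataFrame(rows, index=ids)
    if extra is not None:
        df = df.join(extra, how="inner")
        df = df.dropna()
    return DescriptorMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def select_descriptors(m: DescriptorMatrix, rho_max: float = 0.9,
                       ident_frac: float = 0.9, seed: int = 0) -> DescriptorMatrix:
    """Reduce to informative, non-redundant descriptors.

    Removes null-variance columns and columns whose most frequent value
    covers more than ``ident_frac`` of the chemicals; clusters the rest on
    |Pearson rho| > ``rho_max`` (graph connected components) and retains a
    single seeded-random representative per cluster. Representative choice
    is seeded on lexicographically sorted names, so it is invariant to row
    and column order.
    """
    if m.values.shape[0] < 2:
        raise CurationError("descriptor selection needs >= 2 chemicals")
    values, names = m.values, list(m.names)
    n = values.shape[0]

    informative = []
    for j, name in enumerate(names):
        col = values[:, j]
        if np.var(col) == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / n > ident_frac:
            continue
        informative.append(j)
    if not informative:
        raise CurationError("all descriptors removed by variance/identity filters")

    sub = values[:, informative]
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    g = nx.Graph()
    g.add_nodes_from(range(len(informative)))
    hi = np.argwhere(np.triu(np.abs(corr) > rho_max, k=1))
    g.add_edges_from(map(tuple, hi))

    rng = np.random.default_rng(seed)
    retained = np.zeros(len(names), dtype=bool)
    clusters: dict[str, int] = {}
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min(names[informative[i]] for i in c))
    for cluster_id, comp in enumerate(comps):
        members = sorted(names[informative[i]] for i in comp)
        pick = members[int(rng.integers(len(members)))]
        for name in members:
            clusters[name] = cluster_id
        retained[names.index(pick)] = True

    return DescriptorMatrix(list(m.ids), names, values, retained, clusters)
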