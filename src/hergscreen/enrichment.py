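"""Chemotype enrichment in active chemicals.

For every chemotype (a binary structural annotation such as a ToxPrint
fragment), the proportion carrying it among active chemicals is compared
with the proportion among inactive chemicals using a one-tailed
two-proportion Z-test with Yates continuity correction, flagging
chemotypes significantly over-represented in the active space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .errors import EnrichmentError

# Small bundled SMARTS list for chemotype perception in demonstrations;
# production chemotype matrices are an input (ToxPrint-style).
CHEMOTYPE_SMARTS = {
    "ring_hetero_6_N_piperidine": "C1CCNCC1",
    "ring_hetero_6_N_piperazine": "C1CNCCN1",
    "bond_quaternary_ammonium": "[NX4+]",
    "bond_CN_amine_ter_aliphatic": "[NX3;H0;!$(N-C=O);!$(N-a);!$(N=*)]",
    "chain_alkane_hexyl_C6": "CCCCCC",
    "chain_alkane_octyl_C8": "CCCCCCCC",
    "chain_alkane_decyl_C10": "CCCCCCCCCC",
    "chain_aromatic_alkane_Ph_C1": "cC",
    "ring_benzimidazole": "c1ccc2[nX2,nH]cnc2c1",
    "bond_P_O_phosphate": "P(=O)(O)O",
    "bond_aryl_chloride": "cCl",
    "bond_phenol_OH": "c[OX2H]",
}


@dataclass
class EnrichmentResult:
    chemotype_name: str
    k_active: int
    n_active: int
    k_inactive: int
    n_inactive: int
    z: float
    p: float
    enriched: bool


def two_prop_ztest(k1: int, n1: int, k2: int, n2: int,
                   alternative: str = "greater") -> tuple[float, float]:
    """Pooled two-proportion Z-test with Yates continuity correction.

    Tests whether the proportion k1/n1 (actives) exceeds k2/n2
    (inactives). The correction term is capped at |p1 - p2| so it can
    shrink the observed difference to zero but never flip its sign.
    A pooled proportion of exactly 0 or 1 carries no evidence and returns
    (0, 1) by convention.
    """
    if n1 <= 0 or n2 <= 0:
        raise EnrichmentError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise EnrichmentError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    cc = min(0.5 * (1 / n1 + 1 / n2), abs(p1 - p2))
    diff = p1 - p2
    corrected = diff - np.sign(diff) * cc
    z = corrected / se
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        raise EnrichmentError(f"unknown alternative {alternative!r}")
    return float(z), p


def screen_chemotypes(matrix: pd.DataFrame, labels: pd.Series,
                      alpha: float = 0.05, adjust: str | None = None) -> pd.DataFrame:
    """One enrichment test per chemotype column, sorted by p-value.

    ``matrix`` is a binary chemical x chemotype table aligned with the
    boolean ``labels``. ``adjust='bh'`` applies Benjamini-Hochberg control
    before flagging at ``alpha`` (the default is the unadjusted per-test
    flag, matching the original analysis).
    """
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise EnrichmentError("labels do not align with the chemotype matrix rows")
    active = labels.astype(bool).to_numpy()
    n1, n2 = int(active.sum()), int((~active).sum())
    if n1 == 0 or n2 == 0:
        raise EnrichmentError("need both active and inactive chemicals")

    rows = []
    vals = matrix.to_numpy(dtype=bool)
    for j, name in enumerate(matrix.columns):
        k1 = int(vals[active, j].sum())
        k2 = int(vals[~active, j].sum())
        z, p = two_prop_ztest(k1, n1, k2, n2)
        rows.append((name, k1, n1, k2, n2, z, p))
    df = pd.DataFrame(rows, columns=["chemotype", "k_active", "n_active",
                                     "k_inactive", "n_inactive", "z", "p"])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, *_ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["p_adj"] = p_adj
        df["enriched"] = reject
    elif adjust is None:
        df["enriched"] = df["p"] < alpha
    else:
        raise EnrichmentError(f"unknown adjustment {adjust!r}")
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def match_chemotypes(smiles: list[str], ids: list[str] | None = None,
                     smarts: dict[str, str] | None = None) -> pd.DataFrame:
    """Binary chemotype matrix by SMARTS matching (bundled list by default)."""
    smarts = smarts or CHEMOTYPE_SMARTS
    patterns = {name: Chem.MolFromSmarts(s) for name, s in smarts.items()}
    ids = ids if ids is not None else list(range(len(smiles)))
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rows.append({name: 0 for name in patterns})
            continue
        rows.append({name: int(mol.HasSubstructMatch(p)) for name, p in patterns.items()})
    return pd.DataFrame(rows, index=ids)
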