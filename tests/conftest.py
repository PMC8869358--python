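import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hergscreen import curation, synthetic
from hergscreen.config import SynthConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_plate():
    """Small noise-free plate with known true Hill parameters."""
    cfg = SynthConfig(n_compounds=8, frac_active=0.75, noise_sd=0.0, seed=11)
    wells, truth = synthetic.generate_plate(cfg)
    return wells, truth.set_index("compound_id")


@pytest.fixture(scope="session")
def molecule_set():
    """Mid-size molecule table with a strong planted structure-activity rule."""
    cfg = SynthConfig(n_compounds=700, frac_active=0.25,
                      enrichment_effect=100.0, seed=5)
    return synthetic.generate_molecules(cfg)


@pytest.fixture(scope="session")
def descriptor_matrix(molecule_set):
    structs = curation.standardize(zip(molecule_set["id"], molecule_set["smiles"]))
    desc = curation.compute_descriptors(structs)
    return curation.select_descriptors(desc, seed=5)


@pytest.fixture(scope="session")
def labelled_descriptors(molecule_set, descriptor_matrix):
    X = descriptor_matrix.to_frame(retained_only=True)
    labels = molecule_set.set_index("id")["true_label"].reindex(X.index)
    return X, labels


def toy_plate(v_dmso=100.0, v_pos=50.0, compound_values=(75.0,), conc=None):
    """Hand-built plate: constant controls plus one compound series."""
    conc = conc if conc is not None else np.geomspace(1e-8, 1e-4, len(compound_values))
    rows = []
    for i in range(4):
        rows.append((f"D{i}", "", np.nan, 0, v_dmso, "dmso"))
        rows.append((f"P{i}", "", np.nan, 0, v_pos, "poscon"))
    for j, (c, v) in enumerate(zip(conc, compound_values)):
        rows.append((f"C{j}", "CPD", c, 0, v, "compound"))
    return pd.DataFrame(rows, columns=["well_id", "compound_id", "conc_M",
                                       "replicate", "raw_value", "well_type"])
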