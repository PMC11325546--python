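import numpy as np
import pytest
from rdkit import Chem

from micropka.chem_io import record_from_mol, standardize
from micropka.qm import get_backend


@pytest.fixture(scope="session")
def backend():
    return get_backend("mock")


@pytest.fixture(scope="session")
def make_record():
    """Factory: SMILES -> standardized MolRecord with conformer."""

    cache = {}

    def _make(smiles: str, mol_id: str = None):
        key = (smiles, mol_id)
        if key not in cache:
            mol = Chem.MolFromSmiles(smiles)
            assert mol is not None, f"bad test SMILES {smiles!r}"
            cache[key] = standardize(
                record_from_mol(mol, mol_id or smiles, embed=False))
        return cache[key]

    return _make


@pytest.fixture(scope="session")
def small_library(backend):
    """60 synthetic molecules with oracle labels, graphs and QM features."""
    from micropka.graphs import featurize
    from micropka.synthetic import SyntheticSpec, assign_labels, gen_library

    spec = SyntheticSpec(n_molecules=60, seed=11, noise_sd=0.0)
    lib = gen_library(spec)
    out = []
    for rec in lib:
        prot, deprot, pka_map = assign_labels(rec, spec, backend)
        graph = featurize(rec, backend.compute(rec))
        out.append({"record": rec, "graph": graph, "prot": prot,
                    "deprot": deprot, "pka": pka_map, "spec": spec})
    return out
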