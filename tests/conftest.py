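import pytest

import libprof as lp


@pytest.fixture(scope="session")
def small_library():
    """Mixed curated library of drug-like molecules (all distinct)."""
    smiles = [
        "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
        "CC(=O)Nc1ccc(O)cc1",               # paracetamol
        "Cc1ccccc1",                        # toluene
        "c1ccc2ccccc2c1",                   # naphthalene
        "CCN(CC)CCNC(=O)c1ccc(N)cc1",       # procainamide
        "OC(=O)c1ccccc1O",                  # salicylic acid
        "CN1CCC[C@H]1c1cccnc1",             # nicotine
        "Clc1ccc(Cl)cc1",                   # dichlorobenzene
        "CCCCCCCC",                         # octane (acyclic)
        "NCCc1ccc(O)c(O)c1",                # dopamine
    ]
    records = [lp.MoleculeRecord(f"M{i:03d}", s) for i, s in enumerate(smiles)]
    curated, _ = lp.curate(records)
    return lp.curated(curated)


@pytest.fixture(scope="session")
def synthetic_library_50():
    """50-molecule synthetic library with a known chemotype distribution."""
    spec = lp.SyntheticLibrarySpec(
        frequency=[12, 10, 8, 6, 4, 3, 2], n_acyclic=5, seed=421
    )
    records, truth = lp.gen_scaffold_library(spec)
    return records, truth
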