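import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from cb2screen import synthetic

#: Small hyperparameter grid for tests that exercise plumbing, not model
#: quality — keeps the suite fast without touching library defaults.
TINY_GRID = {"n_estimators": [60], "max_depth": [4], "learning_rate": [0.1]}


@pytest.fixture(scope="session")
def clean_dataset():
    """120 unique synthetic compounds with a learnable pKi surface."""
    return synthetic.generate_clean_dataset(120, seed=3, noise_sd=0.2)


@pytest.fixture(scope="session")
def trained_model(clean_dataset):
    from cb2screen.model import QsarModel

    return QsarModel.train(
        clean_dataset, "CB1", seed=1, include_3d=False, param_grid=TINY_GRID
    )


@pytest.fixture(scope="session")
def trained_model_cb2(clean_dataset):
    from cb2screen.model import QsarModel

    df = synthetic.generate_clean_dataset(120, seed=3, noise_sd=0.2, target="CB2")
    return QsarModel.train(df, "CB2", seed=1, include_3d=False, param_grid=TINY_GRID)


@pytest.fixture()
def mols_small():
    smiles = ["c1ccccc1", "CCO", "CCCCCCCCc1ccc(O)cc1", "CC(C)Cc1ccc(C)cc1C(=O)O"]
    return [Chem.MolFromSmiles(s) for s in smiles]


@pytest.fixture()
def activity_table(tmp_path):
    """Synthetic raw activity CSV plus its plant manifest."""
    cfg = synthetic.SyntheticConfig(n_compounds=80, seed=5)
    smiles = synthetic.generate_structures(80, 5, cfg.fraction_invalid_structures)
    pki_cb1, _ = synthetic.assign_true_pki(smiles, cfg)
    table, manifest = synthetic.generate_activity_table(smiles, pki_cb1, cfg, "CB1")
    path = tmp_path / "activity.csv"
    table.to_csv(path, index=False)
    return path, manifest
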