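import numpy as np
import pytest
from hypothesis import settings

from micropka.chemgraph import FeatureConfig
from micropka.model import ModelConfig, init_model

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def tiny_state(feature_config):
    """Small untrained model; deterministic, enough for structural checks."""
    cfg = ModelConfig(n_layers=3, hidden_dim=16, head_hidden_dims=(8,),
                      dropout_rate=0.2, mode="acidic", seed=123)
    return init_model(cfg, feature_config)


# 20 named molecules and their SMILES, shared by the site-rule tests.
NAMED_MOLECULES = {
    "acetic acid": "CC(=O)O",
    "phenol": "Oc1ccccc1",
    "pyridine": "c1ccncc1",
    "propane-1,2,3-triamine": "NCC(N)CN",
    "methanesulfonamide": "CS(N)(=O)=O",
    "tetramethylammonium": "C[N+](C)(C)C",
    "ethanol": "CCO",
    "ethane": "CC",
    "aniline": "Nc1ccccc1",
    "imidazole": "c1c[nH]cn1",
    "benzoic acid": "O=C(O)c1ccccc1",
    "glycine": "NCC(=O)O",
    "piperazine": "C1CNCCN1",
    "thiophenol": "Sc1ccccc1",
    "acetamide": "CC(N)=O",
    "trimethylamine": "CN(C)C",
    "4-nitrophenol": "O=[N+]([O-])c1ccc(O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "pyrrole": "c1cc[nH]c1",
    "morpholine": "C1COCCN1",
}


@pytest.fixture(scope="session")
def named_molecules():
    return dict(NAMED_MOLECULES)
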