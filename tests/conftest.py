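import numpy as np
import pytest
from hypothesis import settings

from ipminer.features import build_raw_pair_matrix

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from ipminer.synthetic import SyntheticConfig, generate_dataset

# small pipeline config used wherever the full model must be fit quickly;
# epochs reduced from the 100/100 defaults, everything else standard
FAST_CONFIG = {
    "pretrain_epochs": 20,
    "finetune_epochs": 20,
    "batch_size": 50,
    "n_trees": 50,
    "stack_folds": 3,
}


@pytest.fixture(scope="session")
def motif_dataset():
    """200 balanced planted-motif pairs (fixed seed)."""
    cfg = SyntheticConfig(n_pairs=200, seed=20160823)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def motif_matrix(motif_dataset):
    pairs, prot, rna = motif_dataset
    X = build_raw_pair_matrix(pairs, prot, rna)
    y = np.array([p[2] for p in pairs], dtype=int)
    return X, y
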