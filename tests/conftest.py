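import numpy as np
import pytest

from pgm_transfer import ModelConfig, TaskSpec
from pgm_transfer.data_io import MoleculeRecord, featurize
from pgm_transfer.synthetic import generate_molecules


@pytest.fixture(scope="session")
def molecules_100():
    return generate_molecules(100, seed=11)


@pytest.fixture(scope="session")
def tiny_classification_dataset(molecules_100):
    """12 molecules, 1 binary subtask: label = contains a ring."""
    from rdkit import Chem

    smiles = molecules_100[:12]
    records = [
        MoleculeRecord(
            s,
            labels=np.array([1.0 if Chem.MolFromSmiles(s).GetRingInfo().NumRings() else 0.0]),
            observed=np.array([True]),
        )
        for s in smiles
    ]
    return records, TaskSpec(task_type="classification", n_subtasks=1, name="tiny")


@pytest.fixture
def small_gin_config():
    return ModelConfig(encoder="gin", encoder_depth=2, hidden_width=8, init_seed=0)


@pytest.fixture
def bag_config():
    return ModelConfig(encoder="bag", hidden_width=8, init_seed=0)


@pytest.fixture
def small_batch(tiny_classification_dataset):
    from pgm_transfer.model import make_batch

    records, _ = tiny_classification_dataset
    graphs = [featurize(r) for r in records[:6]]
    labels = np.stack([r.labels for r in records[:6]])
    observed = np.stack([r.observed for r in records[:6]])
    return make_batch(graphs, labels, observed)
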