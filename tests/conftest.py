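import numpy as np
import pytest

from cellmil import SimulationSpec, simulate_dataset
from cellmil.model import ModelState
from cellmil.training import Stage1Config, pretrain_autoencoder


@pytest.fixture(scope="session")
def tiny_spec():
    """Small dataset spec used across unit tests (fast to generate)."""
    return SimulationSpec(
        n_genes=80,
        n_de_genes_per_signature=8,
        cells_per_sample=40,
        n_control_samples=6,
        n_case_samples=6,
        perturb_fractions=(0.2,),
        de_log2fc=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return simulate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly pretrained small model for shape/contract tests."""
    state = ModelState.build(
        n_genes=tiny_dataset.cells.n_genes,
        encoder_widths=(32, 16, 8),
        attention_hidden=16,
        head_hidden=(8,),
        seed=3,
    )
    counts = np.asarray(tiny_dataset.cells.counts)
    pretrain_autoencoder(
        state,
        counts[tiny_dataset.cells_in("train")],
        counts[tiny_dataset.cells_in("val")],
        Stage1Config(max_epochs=3, patience=3),
        seed=3,
    )
    return state
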