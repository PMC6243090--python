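import numpy as np
import pytest

import emgnms as E
from emgnms.gravity import default_masses


@pytest.fixture(scope="session")
def defaults():
    """Shipped default models plus anthropometry for a 70 kg subject."""
    models, anthro = E.default_models()
    M_a, M_fh = default_masses(70.0)
    return models, anthro.with_masses(M_a=M_a, M_fh=M_fh)


@pytest.fixture(scope="session")
def noiseless_linear_case():
    """Deterministic protocol from a subject whose truth differs from the
    defaults only in the linearly calibrated parameters (F_O, masses)."""
    subject = E.sample_subject(1, mode="linear", noise=E.NoiseConfig.noiseless())
    dataset = E.synthesize_dataset(subject, seed=2)
    split = E.split_dataset(dataset, seed=3)
    return {
        "subject": subject,
        "dataset": dataset,
        "split": split,
        "train": E.build_design(dataset, split.train_ids),
        "val": E.build_design(dataset, split.val_ids),
    }


@pytest.fixture(scope="session")
def noiseless_full_case():
    """Deterministic protocol from a subject with every calibrated
    parameter drawn inside the search bounds."""
    subject = E.sample_subject(1, mode="full", noise=E.NoiseConfig.noiseless())
    dataset = E.synthesize_dataset(subject, seed=2)
    split = E.split_dataset(dataset, seed=3)
    return {
        "subject": subject,
        "dataset": dataset,
        "split": split,
        "train": E.build_design(dataset, split.train_ids),
        "val": E.build_design(dataset, split.val_ids),
    }
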