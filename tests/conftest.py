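"""Shared fixtures: small synthetic datasets and a tiny trained classifier.

Everything is generated programmatically at test time; sizes are kept small
so individual unit tests run in well under a second.
"""

from __future__ import annotations

import numpy as np
import pytest

from selectscreen.activity_nn import ActivityClassifier, NNModelSpec
from selectscreen.dataset_io import ActivityDataset, CompoundRecord, clean_dataset
from selectscreen.fingerprints import fingerprint_matrix
from selectscreen.synthetic_data import GeneratorSpec, generate_receptor_library

TINY_BITS = 256


@pytest.fixture(scope="session")
def tiny_dataset() -> ActivityDataset:
    """150 compounds, 5 scaffolds x 30 substituents, separable labels."""
    spec = GeneratorSpec(
        n_scaffolds=5,
        substituents_per_scaffold=30,
        inactive_fraction=0.0,
        noise_sd=0.2,
        seed=42,
        n_bits=TINY_BITS,
    )
    return generate_receptor_library(spec, receptor="TINY")


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset) -> tuple[np.ndarray, np.ndarray]:
    X = fingerprint_matrix(tiny_dataset.smiles(), n_bits=TINY_BITS)
    return X, tiny_dataset.classes()


@pytest.fixture(scope="session")
def tiny_model(tiny_features) -> ActivityClassifier:
    """A small classifier trained briefly on the tiny dataset."""
    X, y = tiny_features
    spec = NNModelSpec(
        input_width=TINY_BITS, hidden_layers=(64, 32), epochs=30, seed=42
    )
    return ActivityClassifier.build(spec).train(X, y)


@pytest.fixture(scope="session")
def tiny_library(tiny_dataset) -> list[tuple[str, str]]:
    """(id, SMILES) screening library reusing the tiny dataset's structures."""
    return list(zip(tiny_dataset.ids(), tiny_dataset.smiles()))


@pytest.fixture()
def labeled_toy_dataset() -> ActivityDataset:
    """Ten hand-labeled records covering several activity classes."""
    values = [0.0, 3.9, 4.0, 4.5, 5.5, 6.5, 7.5, 8.5, 9.0, 10.2]
    records = [
        CompoundRecord(
            compound_id=f"T{i}", smiles="CCO", pchembl=v, receptor="TOY"
        )
        for i, v in enumerate(values)
    ]
    return clean_dataset(ActivityDataset(receptor="TOY", records=records))
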