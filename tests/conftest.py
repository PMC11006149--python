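"""Shared fixtures: one trained model on the default phantom per session.

Training the built-in CNN takes tens of seconds, so the default-conditions
model and everything derived from it are session-scoped and shared across
test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from convrules.adapter import extract_activations, train_tiny_cnn
from convrules.concepts import assign_concepts
from convrules.phantom import PhantomConfig, generate_dataset
from convrules.quantization import binarize, compute_thresholds, kernel_norms


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(n_per_class=200, seed=1)


@pytest.fixture(scope="session")
def dataset(phantom_config):
    return generate_dataset(phantom_config)


@pytest.fixture(scope="session")
def model(dataset):
    return train_tiny_cnn(dataset, seed=1, epochs=25)


@pytest.fixture(scope="session")
def activations(model, dataset):
    return extract_activations(model, dataset.images)


@pytest.fixture(scope="session")
def norm_table(activations, dataset):
    return kernel_norms(activations, labels=dataset.labels)


@pytest.fixture(scope="session")
def thresholds(norm_table):
    return compute_thresholds(norm_table)


@pytest.fixture(scope="session")
def literal_table(norm_table, thresholds):
    return binarize(norm_table, thresholds)


@pytest.fixture(scope="session")
def cnn_predictions(model, dataset):
    return model.predict(dataset.images)


@pytest.fixture(scope="session")
def concept_map(activations, dataset, phantom_config):
    return assign_concepts(activations, dataset.boxes, image_size=phantom_config.image_size)


@pytest.fixture(scope="session")
def pooled_features(model, dataset):
    """Cached g(x) maps for fast masked-prediction tests."""
    return model.g(dataset.images)


def make_literal_table(values: np.ndarray, labels=None):
    """A LiteralTable straight from a +/-1 matrix (thresholds are dummies)."""
    from convrules.quantization import LiteralTable, ThresholdVector

    values = np.asarray(values)
    return LiteralTable(
        values=values,
        image_ids=np.arange(len(values)),
        thresholds=ThresholdVector(np.zeros(values.shape[1]), provenance="synthetic"),
        labels=labels,
    )
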