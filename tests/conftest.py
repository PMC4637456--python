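"""Shared fixtures: small synthetic datasets and feature matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import jprotpred as jp


@pytest.fixture(scope="session")
def tiny_dataset() -> jp.LabeledDataset:
    """A fast, imbalanced 4-class dataset for unit-level checks."""
    config = jp.SimConfig(
        class_counts={"I": 8, "II": 7, "III": 48, "IV": 5},
        length_range=(60, 120),
        seed=7,
    )
    return jp.simulate_dataset(config)


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    """Hybrid feature matrix and labels for the tiny dataset."""
    X = jp.HybridFeatureExtractor().fit(tiny_dataset.records).transform(
        tiny_dataset.records
    )
    return X, np.asarray(tiny_dataset.labels)


@pytest.fixture(scope="session")
def full_benchmark():
    """The default synthetic benchmark: counts 63/55/1061/20."""
    config = jp.SimConfig()
    dataset = jp.simulate_dataset(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = jp.HybridFeatureExtractor().fit(dataset.records).transform(
            dataset.records
        )
    return dataset, X, np.asarray(dataset.labels)
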