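import dataclasses

import numpy as np
import pytest

from ppiscreen import (ApplicabilityDomain, ConsensusClassifier, DEFAULT_SPEC,
                       FuzzyCMeans, make_classification_set, prepare_matrix,
                       stratified_cluster_split)


@pytest.fixture(scope="session")
def benchmark_set():
    """The standing synthetic benchmark (n=600, p=120, 5 clusters, 10% noise)."""
    return make_classification_set(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def small_set():
    """A quick noise-free, well-separated set for classifier sanity checks."""
    spec = dataclasses.replace(DEFAULT_SPEC, n_compounds=300, n_descriptors=20,
                               n_informative=2, n_redundant=0, n_clusters=1,
                               separation=6.0, label_noise=0.0, seed=7)
    return make_classification_set(spec)


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark_set):
    """Prepared matrix, split, fitted consensus model + domain on the benchmark."""
    D, y, truth = benchmark_set
    prepared = prepare_matrix(D)
    X = prepared.values.to_numpy()
    fcm = FuzzyCMeans(n_clusters=5, random_state=42).fit(X)
    split = stratified_cluster_split(fcm.labels_, prepared.compound_ids, 0.8, seed=42)
    Xtr = prepared.values.loc[split.train_ids].to_numpy()
    ytr = y[split.train_ids].to_numpy()
    model = ConsensusClassifier(random_state=42).fit(Xtr, ytr)
    domain = ApplicabilityDomain().fit(Xtr)
    return {
        "prepared": prepared, "labels": y, "fcm": fcm, "split": split,
        "model": model, "domain": domain,
        "Xtr": Xtr, "ytr": ytr,
        "Xte": prepared.values.loc[split.test_ids].to_numpy(),
        "yte": y[split.test_ids].to_numpy(),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
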