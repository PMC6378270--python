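import warnings

import numpy as np
import pytest

import lipidpanel as lp


@pytest.fixture(scope="session")
def default_cohort():
    return lp.generate_cohort(lp.default_config(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    """Preprocessed default cohort: (matrix, report) with 35 analytes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, report = lp.preprocess_cohort(default_cohort)
    return matrix, report


@pytest.fixture(scope="session")
def dementia_labels(default_cohort):
    return (default_cohort.diagnosis == "dementia").to_numpy()


def make_blobs(n_per_blob, centers, sd=0.3, seed=0):
    """Well-separated isotropic Gaussian blobs with known membership."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(c, sd, size=(n_per_blob, len(c))))
        labels += [i] * n_per_blob
    return np.vstack(X), np.array(labels)
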