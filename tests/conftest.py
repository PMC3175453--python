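"""Shared fixtures: synthetic caps, corpora and trained models.

The expensive objects (leadfield, featurized corpora, corpus-trained
classifier) are session-scoped so the feature and pipeline tests share one
computation.
"""

import warnings

import numpy as np
import pytest

from icaclean import core_io, features, learn, pipeline, synthetic


@pytest.fixture(scope="session")
def cap32() -> core_io.Montage:
    return core_io.make_synthetic_cap(32)


@pytest.fixture(scope="session")
def cap64() -> core_io.Montage:
    return core_io.make_synthetic_cap(64)


@pytest.fixture(scope="session")
def leadfield64(cap64):
    return features.build_leadfield(cap64)


@pytest.fixture(scope="session")
def corpus_train(cap64):
    return synthetic.make_component_corpus(cap64, 300, seed=10)


@pytest.fixture(scope="session")
def corpus_test(cap64):
    return synthetic.make_component_corpus(cap64, 300, seed=11)


@pytest.fixture(scope="session")
def fset_train(corpus_train, cap64):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.featurize_corpus(corpus_train, cap64)


@pytest.fixture(scope="session")
def fset_test(corpus_test, cap64):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.featurize_corpus(corpus_test, cap64)


@pytest.fixture(scope="session")
def trained_model64(fset_train):
    return learn.train_component_classifier(fset_train, select_features=False,
                                            seed=0)


@pytest.fixture(scope="session")
def trained_model32(cap32):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corpus = synthetic.make_component_corpus(cap32, 300, seed=20)
        fset = pipeline.featurize_corpus(corpus, cap32)
    return learn.train_component_classifier(fset, select_features=False, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
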