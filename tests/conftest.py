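import pytest

import gcri


@pytest.fixture(scope="session")
def featurizer():
    return gcri.default_featurizer()


@pytest.fixture(scope="session")
def registry():
    return gcri.default_registry()


@pytest.fixture(scope="session")
def tiny_ensemble(featurizer):
    """A minimally trained four-net ensemble plus its analyte library."""
    from gcri.experiments import train_tiny_ensemble

    nets, registry, library = train_tiny_ensemble(seed=2, n_molecules=40,
                                                  iterations=20,
                                                  featurizer=featurizer)
    return nets, registry, library
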