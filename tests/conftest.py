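from dataclasses import replace

import pytest

from ampcurve import classify, preprocess, simgen


@pytest.fixture(scope="session")
def default_dataset():
    return simgen.simulate_dataset(simgen.SimConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_config():
    return replace(simgen.SimConfig(), noise_sd=0.0)


@pytest.fixture(scope="session")
def split(default_dataset):
    return classify.split_dataset(default_dataset, classify.SplitSpec(seed=0))


@pytest.fixture(scope="session")
def normalizer(split):
    train, _ = split
    return preprocess.normalize_fit(train)


@pytest.fixture(scope="session")
def tuned_svc(split, normalizer):
    """Grid-searched SVC trained on the default training split."""
    train, _ = split
    params, cv_score = classify.grid_search(
        classify.DEFAULT_SPECS["SVC"], train, normalizer, seed=0
    )
    model = classify.train_final("SVC", params, train, normalizer)
    return model, params, cv_score
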