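import numpy as np
import pytest
from hypothesis import settings

import mvtmammo as m

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 synthetic cases at heavily reduced canvas scale, preprocessed to
    16x16 inputs — enough structure for contract tests, fast to build."""
    gen = m.GeneratorConfig(n_cases=20, malignant_fraction=0.5, scale=0.05, seed=11)
    cases, manifest = m.generate_dataset(gen)
    X, y, ids = m.preprocess_dataset(cases, side=16)
    return dict(config=gen, cases=cases, manifest=manifest, X=X, y=y, ids=ids)


@pytest.fixture()
def toy16_config():
    return m.make_config("toy", image_side=16)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
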