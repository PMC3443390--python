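"""Shared fixtures: phantom models and renders are expensive enough to be
worth computing once per session."""

import numpy as np
import pytest

from gatemap.phantom import ConformationParams, build_model, render_density


@pytest.fixture(scope="session")
def closed_model():
    return build_model(ConformationParams.closed())


@pytest.fixture(scope="session")
def open_model():
    return build_model(ConformationParams.open())


@pytest.fixture(scope="session")
def c5_model():
    return build_model(ConformationParams.c5())


@pytest.fixture(scope="session")
def closed_map(closed_model):
    return render_density(closed_model)


@pytest.fixture(scope="session")
def open_map(open_model):
    return render_density(open_model)


@pytest.fixture(scope="session")
def c5_map(c5_model):
    return render_density(c5_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
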