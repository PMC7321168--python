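import numpy as np
import pandas as pd
import pytest

import aqbd
from aqbd import ModelSpec, ResponseModel


@pytest.fixture(scope="session")
def screening():
    design, responses = aqbd.load_screening()
    return design, responses


@pytest.fixture(scope="session")
def rsm():
    design, responses = aqbd.load_rsm()
    return design, responses


@pytest.fixture(scope="session")
def screening_fits(screening):
    design, responses = screening
    spec = ModelSpec.linear(design.factor_names)
    return {
        name: ResponseModel(responses[name], design, spec, name=name).fit()
        for name in responses.columns
    }


@pytest.fixture(scope="session")
def rsm_full_fits(rsm):
    design, responses = rsm
    spec = ModelSpec.full_quadratic(design.factor_names)
    return {
        name: ResponseModel(responses[name], design, spec, name=name).fit()
        for name in responses.columns
    }


@pytest.fixture(scope="session")
def rsm_reduced_fits(rsm_full_fits):
    return {
        name: res.backward_eliminate(alpha=0.05)
        for name, res in rsm_full_fits.items()
    }


@pytest.fixture
def toy_design():
    """4-run full factorial in two coded factors."""
    design = aqbd.generate_fractional_factorial(2, 0, 0)
    return design


def brute_force_press(results):
    """Leave-one-out PRESS by explicit refitting — the independent oracle
    for the leverage shortcut."""
    X = results.model.exog.to_numpy()
    y = results.model.endog.to_numpy()
    press = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        b, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        press += (y[i] - X[i] @ b) ** 2
    return press
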