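import numpy as np
import pytest

from episwitch.landscape import compute_landscape
from episwitch.model import ModelParams, default_x_grid, qss_marks
from episwitch.reference import DEFAULT_CONSTANTS, REFERENCE_THETA, reference_params

ALL_CLASSES = ("LOW_GE", "HIGH_GE", "BISTABLE", "NOISE_INDUCED")


@pytest.fixture(scope="session")
def constants():
    return dict(DEFAULT_CONSTANTS)


@pytest.fixture(scope="session", params=ALL_CLASSES)
def class_label(request):
    return request.param


@pytest.fixture(scope="session")
def params_by_class():
    return {lab: reference_params(lab) for lab in ALL_CLASSES}


@pytest.fixture(scope="session")
def landscape_by_class(params_by_class):
    return {lab: compute_landscape(p) for lab, p in params_by_class.items()}


@pytest.fixture(scope="session")
def bistable_params(params_by_class):
    return params_by_class["BISTABLE"]


@pytest.fixture()
def unit_theta():
    """A neutral all-ones theta for formula-level checks."""
    return {k: 1.0 for k in (
        "A1", "A3", "B2", "K2", "K5", "K6", "lambda_A", "lambda_x",
        "A7", "A9", "B8", "K8", "K9", "K11", "K12", "lambda_I")}


@pytest.fixture()
def decoupled_params(unit_theta):
    """TF decoupled from the marks: C1 = C4 = 0, birth-death with C2 = 1."""
    return ModelParams(theta=unit_theta, rho=1.0, C1=0.0, C2=1.0, C4=0.0,
                       Lambda_A=1.0, Lambda_I=1.0, rho_A=1.0, rho_I=1.0,
                       Omega_T=50, Omega_S=10)
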