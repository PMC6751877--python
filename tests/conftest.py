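import numpy as np
import pytest

import viaspace as v

# Parameter sets printed in the study's figure captions, used throughout the
# suite as known-behavior anchors (order follows parameter_space(model).names).

REPRESSILATOR_OSC = {
    "alpha": 49.61, "alpha0": 1.43, "n": 4.4, "beta": 21.83,
    "delta_m": 1.72, "delta_p": 0.78, "Kd": 123.12,
}
ACDC_OSC = {
    "alpha": 26.26, "n": 3.82, "beta": 18.14, "delta_m": 0.92,
    "delta_p": 1.29, "Kd_a": 151.42, "Kd_b": 197.61, "Kd_c": 41.88,
    "Kd_d": 11.7,
}
ACDC_BISTABLE = {
    "alpha": 5.91, "n": 4.16, "beta": 47.35, "delta_m": 0.63,
    "delta_p": 1.12, "Kd_a": 165.03, "Kd_b": 111.2, "Kd_c": 101.5,
    "Kd_d": 0.48,
}
DFF_COUNTER = {
    "alpha1": 34.73, "alpha2": 49.36, "alpha3": 32.73, "alpha4": 49.54,
    "delta1": 1.93, "delta2": 0.69, "Kd": 4.44, "n": 4.35,
}

REP_Y0 = np.array([0.0, 0.0, 0.0, 150.0, 0.0, 0.0])
ACDC_Y0 = np.array([0.0, 0.0, 0.0, 37.0, 280.0, 280.0])


def point(model, values: dict) -> v.ParameterPoint:
    space = v.parameter_space(model)
    return v.ParameterPoint(np.array([values[n] for n in space.names]))


@pytest.fixture(scope="session")
def repressilator():
    return v.get_model("repressilator")


@pytest.fixture(scope="session")
def acdc():
    return v.get_model("acdc")


@pytest.fixture(scope="session")
def dflipflop():
    return v.get_model("dflipflop", omega1=1, omega2=1)


@pytest.fixture(scope="session")
def rep_caption_traj(repressilator):
    theta = point(repressilator, REPRESSILATOR_OSC)
    return v.simulate(repressilator, theta, REP_Y0, 48.0)


@pytest.fixture(scope="session")
def acdc_osc_traj(acdc):
    theta = point(acdc, ACDC_OSC)
    return v.simulate(acdc, theta, ACDC_Y0, 48.0)


@pytest.fixture(scope="session")
def acdc_bistable_traj(acdc):
    theta = point(acdc, ACDC_BISTABLE)
    return v.simulate(acdc, theta, ACDC_Y0, 48.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
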