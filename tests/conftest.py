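import numpy as np
import pytest

from hepwx.kinetic_models import ConversionConstants, KineticParameterSet
from hepwx.relaxometry import RelaxationParameters
from hepwx.synthetic_data import default_input_models, default_sampling_scheme


@pytest.fixture(scope="session")
def inputs():
    """Default (AIF, PVIF) pair."""
    return default_input_models()


@pytest.fixture(scope="session")
def scheme():
    """20-frame breath-hold sampling grid (minutes)."""
    return default_sampling_scheme(10)


@pytest.fixture(scope="session")
def consts():
    return ConversionConstants()


@pytest.fixture(scope="session")
def relax():
    return RelaxationParameters()


def make_params(model_id, rng=None, **overrides):
    """A valid parameter set per model, optionally randomized in
    physiological ranges."""
    if rng is None:
        base = dict(f=0.3, gamma=0.5, v_I=0.2, t_Lag_T=0.05)
        extra = dict(E=0.6) if model_id in ("TK", "ETK") else dict(ps=0.15)
        if model_id != "TK":
            base["v_P"] = 0.14
    else:
        base = dict(
            f=rng.uniform(0.1, 1.0),
            gamma=rng.uniform(0.1, 0.9),
            v_I=rng.uniform(0.05, 0.45),
            t_Lag_T=rng.uniform(0.0, 0.2),
        )
        extra = (
            dict(E=rng.uniform(0.1, 0.9))
            if model_id in ("TK", "ETK")
            else dict(ps=rng.uniform(0.03, 0.5))
        )
        if model_id != "TK":
            base["v_P"] = rng.uniform(0.02, 0.35)
    base.update(extra)
    base.update(overrides)
    return KineticParameterSet(model_id=model_id, **base)
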