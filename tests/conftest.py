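"""Shared fixtures: default synthetic study conditions and the packaged solution."""

import numpy as np
import pytest

from gapswitch.dynamics import normalizers, run_simulation
from gapswitch.reference import reference_params
from gapswitch.synthetic import SynthConfig, gen_maternal_inputs, gen_targets


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def wt_inputs(synth_config):
    """Default synthetic maternal inputs (Bcd, Hb_mat, Tll)."""
    return gen_maternal_inputs(synth_config)


@pytest.fixture(scope="session")
def ref_params():
    """Packaged best-fit wild-type parameter point (omega unset)."""
    return reference_params()


@pytest.fixture(scope="session")
def ref_params_norm(wt_inputs, ref_params):
    """Packaged solution with normalizers computed on the wild-type inputs."""
    return ref_params.with_omega(normalizers(wt_inputs, ref_params))


@pytest.fixture(scope="session")
def wt_targets(synth_config, ref_params):
    """Noiseless model-forward wild-type gap targets at the packaged solution."""
    return gen_targets(synth_config, ref_params)


@pytest.fixture(scope="session")
def wt_trajectory(wt_inputs, ref_params_norm):
    return run_simulation(wt_inputs, ref_params_norm)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
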