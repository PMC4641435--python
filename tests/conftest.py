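import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tractometry as tm
from tractometry.synthetic import BundleSpec, curved_core

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

START = np.array([0.0, 0.0, 0.0])
END = np.array([20.0, 60.0, 0.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def core_curve():
    return curved_core(START, END)


def make_bundle_spec(**kw):
    defaults = dict(
        core_curve=curved_core(START, END),
        n_fascicles=100,
        jitter_sd=1.0,
        outlier_fraction=0.0,
        outlier_offset=10.0,
        rng_seed=0,
    )
    defaults.update(kw)
    return BundleSpec(**defaults)


@pytest.fixture
def clean_bundle_file():
    """A coherent bundle with no planted outliers."""
    return tm.gen_bundle(make_bundle_spec())


@pytest.fixture
def outlier_bundle_file():
    """100 fascicles, 10 planted positional outliers at 10x jitter offset."""
    return tm.gen_bundle(make_bundle_spec(outlier_fraction=0.10, rng_seed=1))


@pytest.fixture
def constant_volume():
    """A constant FA=0.5 volume covering the fixture bundle geometry."""
    data = np.full((30, 40, 12), 0.5)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-40.0, -20.0, -15.0)
    return tm.ScalarVolume(data=data, affine=affine, kind="FA")
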