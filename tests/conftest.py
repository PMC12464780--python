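import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import memcurve as mc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def linear_model():
    """π = 70 − A on A ∈ [20, 70] Å²; exact closed forms everywhere."""
    return mc.IsothermModel("linear", (70.0, -1.0), (20.0, 70.0), n_points=200)


@pytest.fixture
def hyperbolic_model():
    """π·A = 1000; Cs⁻¹(π) = π identically."""
    return mc.IsothermModel("hyperbolic", (1000.0,), (20.0, 60.0), n_points=200)


@pytest.fixture
def linear_iso(linear_model):
    return mc.gen_isotherm(linear_model)


@pytest.fixture
def hyperbolic_iso(hyperbolic_model):
    return mc.gen_isotherm(hyperbolic_model)


@pytest.fixture
def trough_models():
    """Linear pure-component stand-ins hitting the trough calibration:
    pure CER 41 Å² and pure SM 54 Å² at 25 mN/m."""
    pure_cer = mc.IsothermModel("linear", (90.6, -1.6), (30.0, 52.0))
    pure_sm = mc.IsothermModel("linear", (73.6, -0.9), (30.0, 75.0))
    return pure_cer, pure_sm


@pytest.fixture
def single_bump_model():
    """One Gaussian bump: 100 bar, μ = 1 nm, σ = 0.2 nm on 512 points."""
    return mc.StressFieldModel(
        bumps=((100.0, 1.0, 0.2),), z_range=(-3.0, 3.0), n_points=512
    )


@pytest.fixture
def wide_bounds():
    return mc.MembraneBounds(-3.0, 3.0)


@pytest.fixture
def plane_cloud():
    model = mc.SurfaceModel(
        "plane", {"height": 3.0}, box=(8.0, 8.0),
        n_lipids_per_leaflet=128, jitter_sd=0.0, seed=7,
    )
    return mc.gen_surface_cloud(model)


def sinusoid_model(amplitude=1.0, n=4000, seed=11, jitter=0.0):
    return mc.SurfaceModel(
        "sinusoid",
        {"height": 2.0, "amplitude": amplitude, "wavelength": 10.0},
        box=(10.0, 10.0),
        n_lipids_per_leaflet=n,
        jitter_sd=jitter,
        seed=seed,
    )


@pytest.fixture
def dense_sinusoid():
    return sinusoid_model()


def assert_rel_close(value, expected, rtol):
    assert expected != 0
    assert abs(value / expected - 1.0) < rtol, (value, expected)
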