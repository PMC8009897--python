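import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spinaxis.phantom import CurveSpec, MidlineSpec, render_radiograph
from spinaxis.pipeline import run_pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def straight_case():
    """Noise-free straight-spine phantom."""
    return render_radiograph(MidlineSpec(noise_sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def bump_case():
    """Noise-free single right-convex curve, amplitude 30 px."""
    spec = MidlineSpec(
        curves=(CurveSpec(462.5, 200.0, 30.0),), noise_sigma=0.0, seed=1
    )
    return render_radiograph(spec)


@pytest.fixture(scope="session")
def noisy_bump_case():
    """Single-curve phantom at the study noise level (sigma 10)."""
    spec = MidlineSpec(
        curves=(CurveSpec(462.5, 200.0, 30.0),), noise_sigma=10.0, seed=2
    )
    return render_radiograph(spec)


@pytest.fixture(scope="session")
def s_case():
    """Noise-free S-shaped (double) curve phantom."""
    spec = MidlineSpec(
        curves=(CurveSpec(280.0, 160.0, 30.0), CurveSpec(640.0, 160.0, -30.0)),
        noise_sigma=0.0,
        seed=3,
    )
    return render_radiograph(spec)


@pytest.fixture(scope="session")
def bump_report(bump_case):
    return run_pipeline(bump_case.image)


@pytest.fixture(scope="session")
def straight_report(straight_case):
    return run_pipeline(straight_case.image)


@pytest.fixture(scope="session")
def s_report(s_case):
    return run_pipeline(s_case.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
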