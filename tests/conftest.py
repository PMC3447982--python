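import numpy as np
import pytest

from spinedyn import PlasticityParams, RateLaw, TraceParams, default_fixture_params


@pytest.fixture
def intrinsic_params() -> PlasticityParams:
    """Activity-independent model: zero-amplitude laws, unit intrinsic rate."""
    return PlasticityParams(
        maturation=RateLaw(0.0, 0.0, "thin"),
        shrinkage=RateLaw(0.0, 0.0, "large"),
        delta=1.0,
        gamma=1.0,
        trace=TraceParams(lambda_resp=0.0),
    )


@pytest.fixture
def fixture_params() -> PlasticityParams:
    """Cooperative model whose stationary contact pmf is bimodal."""
    return default_fixture_params()


def random_params(rng: np.random.Generator, activity: bool = True) -> PlasticityParams:
    """A random, irreducible, moderately scaled parameter draw."""
    tau = rng.uniform(50.0, 200.0)
    trace = TraceParams(
        tau=tau,
        nu=rng.uniform(2.0, 8.0),
        c=rng.uniform(0.5, 1.5),
        sigma_thin=rng.uniform(0.5, 2.0),
        sigma_large=rng.uniform(0.5, 2.0),
        p0=0.5,
        lambda_resp=rng.uniform(0.005, 0.02) if activity else 0.0,
        u_epsp=1.0,
    )
    sd_scale = np.sqrt(0.5 * tau * (trace.nu * trace.c**2 + 1.0))
    def law(spine_class):
        return RateLaw(
            amplitude=rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 3.0),
            threshold=rng.uniform(-2.0, 2.0) * sd_scale,
            spine_class=spine_class,
        )
    return PlasticityParams(
        maturation=law("thin"),
        shrinkage=law("large"),
        delta=rng.uniform(0.05, 1.0),
        gamma=1.0,
        trace=trace,
    )
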