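import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadkit import MomentSummary, datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def qol_summary() -> MomentSummary:
    """Four-variable study moments (depression + total QoL, both roles)."""
    return datasets.couples_summary("qol")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_summary(
    rng: np.random.Generator, p: int = 4, n: int = 60, names=None
) -> MomentSummary:
    """A random valid MomentSummary (PD correlations via a Wishart draw)."""
    A = rng.standard_normal((p, p + 3))
    W = A @ A.T
    d = np.sqrt(np.diag(W))
    R = W / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return MomentSummary(
        variables=names or [f"v{i}_male" if i % 2 == 0 else f"v{i}_female" for i in range(p)],
        means=rng.normal(0, 5, size=p),
        sds=rng.uniform(0.5, 4.0, size=p),
        correlations=(R + R.T) / 2.0,
        n=n,
    )


def random_apim_summary(rng: np.random.Generator, n: int = 60) -> MomentSummary:
    """Random moments over the canonical APIM variable quartet."""
    return random_summary(
        rng, p=4, n=n,
        names=["depression_male", "depression_female", "qol_male", "qol_female"],
    )
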