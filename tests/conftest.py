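import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pathsom as ps

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_toy():
    """Scaled-down toy instance (120 points) for fast training tests."""
    spec = ps.ToySpec(n_per_group=30, n_linked_per_group=3, seed=5)
    return ps.make_toy(spec)


@pytest.fixture(scope="session")
def default_toy():
    """The full 400-point toy instance with package defaults."""
    return ps.make_toy()


@pytest.fixture
def tiny_conn():
    """Hand-built connectivity: a-{P1,P2}, b-{P2,P3}, c-{P4}."""
    ann = ps.PathwayAnnotation({("a", "P1"), ("a", "P2"),
                                ("b", "P2"), ("b", "P3"),
                                ("c", "P4")})
    return ps.build_rho(ann, ["a", "b", "c"])


def purity(labels: np.ndarray, truth: np.ndarray) -> float:
    """Weighted majority-class purity of a clustering vs ground truth."""
    total = 0
    for m in np.unique(labels):
        total += np.bincount(truth[labels == m]).max()
    return total / len(truth)
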