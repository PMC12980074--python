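import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kann import ComponentMatrix, ProfileMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_components(scores, eigenvalues, prefix="s", standardized=False):
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    ids = tuple(f"{prefix}{i}" for i in range(scores.shape[0]))
    return ComponentMatrix(ids, scores, np.asarray(eigenvalues, float),
                           standardized)


def make_profiles(proportions, prefix="s", labels=None):
    props = np.atleast_2d(np.asarray(proportions, dtype=float))
    ids = tuple(f"{prefix}{i}" for i in range(props.shape[0]))
    if labels is None:
        labels = tuple(f"POP{j + 1}" for j in range(props.shape[1]))
    return ProfileMatrix(ids, tuple(labels), props)


def random_simplex(rng, n, s):
    """Rows uniform on the simplex (Dirichlet(1))."""
    return rng.dirichlet(np.ones(s), size=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
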