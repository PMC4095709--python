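import numpy as np
import pytest

from diffmix import (
    Dataset,
    ExponentialPair,
    MixtureModel,
    NormalComponent,
    UniformComponent,
)


def random_model(model_class: str, rng: np.random.Generator) -> MixtureModel:
    """A random valid mixture model of the requested class."""
    K = 1 if model_class == "NUDGE" else int(rng.integers(1, 4))
    gammas = rng.dirichlet(np.ones(K))
    normals = [
        NormalComponent(
            mu=float(rng.uniform(-5, 5)),
            sigma2=float(rng.uniform(0.1, 4.0)),
            gamma=float(g),
        )
        for g in gammas
    ]
    pi = float(rng.uniform(0, 1))
    if model_class == "GNG":
        f1 = ExponentialPair(
            rho=float(rng.uniform(0, 1)),
            beta1=float(rng.uniform(0.2, 3.0)),
            beta2=float(rng.uniform(0.2, 3.0)),
            xi1=float(rng.uniform(0.05, 2.0)),
            xi2=float(rng.uniform(0.05, 2.0)),
        )
    else:
        a = float(rng.uniform(-10, -1))
        f1 = UniformComponent(a, a + float(rng.uniform(2, 15)))
    return MixtureModel(model_class, pi, normals, f1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_mixture_data(rng) -> Dataset:
    """~600 points from a 10% uniform + 90% normal mixture."""
    n_sig, n_null = 60, 540
    y = np.concatenate(
        [rng.uniform(-5, 5, n_sig), rng.normal(0, 0.5, n_null)]
    )
    rng.shuffle(y)
    return Dataset.from_arrays(y)


@pytest.fixture
def two_sided_data(rng) -> Dataset:
    """Data with clear two-sided heavy tails, suitable for GNG."""
    n_sig, n_null = 100, 900
    sign = np.where(rng.random(n_sig) < 0.5, -1.0, 1.0)
    tails = sign * (1.0 + rng.exponential(1.5, n_sig))
    y = np.concatenate([tails, rng.normal(0, 0.3, n_null)])
    rng.shuffle(y)
    return Dataset.from_arrays(y)
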