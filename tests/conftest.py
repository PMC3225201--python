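import numpy as np
import pytest

from midfuse.datamodel import OmicsBlock, align_blocks
from midfuse.synthetic import SimulationConfig, BlockSpec, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_blocks():
    """Two small hand-made blocks sharing some samples."""
    a = OmicsBlock("a", ["s1", "s2", "s3"], ["m1", "m2"],
                   np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
    b = OmicsBlock("b", ["s1", "s3", "s4"], ["x1", "x2", "x3"],
                   np.arange(9, dtype=float).reshape(3, 3))
    return a, b


@pytest.fixture
def tiny_labels():
    return {"s1": 1, "s2": 1, "s3": 2, "s4": 2}


def small_sim_config(seed=0, **kw):
    """A scaled-down two-block study that runs in well under a second."""
    defaults = dict(
        g=3,
        samples_per_class=10,
        seed=seed,
        processes=((-0.5, -0.5, 1.0), (-1.0, 0.5, 0.5)),
        blocks=[
            BlockSpec("prot", p=120, n_discriminant=(8, 4), effect_sizes=(2.0, 1.0),
                      batch=True, n_missing=2, peptides_per_protein=4, id_prefix="pep"),
            BlockSpec("met", p=40, n_discriminant=(3, 6), effect_sizes=(1.0, 2.0),
                      n_missing=2, id_prefix="met"),
        ],
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_study():
    return simulate_study(small_sim_config(seed=0))


def whitened_two_class(rng, n_per_class=20, p=5, sep=3.0):
    """Two-class data whose pooled sample within-class covariance is exactly
    isotropic: each class's noise is empirically whitened before the class
    mean is added."""
    mu = np.vstack([np.zeros(p), rng.standard_normal(p)])
    mu[1] *= sep / np.linalg.norm(mu[1])
    labels = np.repeat([1, 2], n_per_class)
    X = np.empty((2 * n_per_class, p))
    for c in (1, 2):
        Z = rng.standard_normal((n_per_class, p))
        Zc = Z - Z.mean(axis=0)
        C = Zc.T @ Zc / (n_per_class - 1)
        Wh = np.linalg.inv(np.linalg.cholesky(C)).T
        X[labels == c] = Zc @ Wh + mu[c - 1]
    return X, labels, mu[0] - mu[1]
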