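import numpy as np
import pytest

from craniomorph.synthetic import SimulationSpec, make_template


@pytest.fixture(scope="session")
def sim_spec():
    return SimulationSpec()


@pytest.fixture(scope="session")
def template_pack(sim_spec):
    """(template configuration, bilateral pairing, curve topology)."""
    return make_template(sim_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_similarity(rng, scale_range=(0.5, 2.0)):
    from craniomorph.geometry import SimilarityTransform
    return SimilarityTransform(
        rotation=random_rotation(rng),
        scale=float(rng.uniform(*scale_range)),
        translation=rng.normal(scale=20.0, size=3),
    )
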