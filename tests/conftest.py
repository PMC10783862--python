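import numpy as np
import pytest

from bbvae import BackboneEnsembleVAE, make_ensemble
from bbvae.synthetic import HELIX_BASIN


@pytest.fixture(scope="session")
def helix_ensemble():
    """32 single-basin helical conformations of poly-alanine, L = 6."""
    return make_ensemble(basins=(HELIX_BASIN,), L=6, n=32, seed=1, label="helix-fixture")


@pytest.fixture(scope="session")
def overfit_model(helix_ensemble):
    """A model overfitted on the small helix fixture (shared across tests).

    Desk-scale training protocol: 600 iterations, batch 8, step size 1e-3.
    """
    est = BackboneEnsembleVAE(
        total_iterations=600, batch_size=8, learning_rate=1e-3, random_state=0
    )
    est.fit(helix_ensemble)
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t
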