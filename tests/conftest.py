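import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wordmanifold as wm

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def random_embeddings():
    """A 20x10 random embedding set for I/O round-trips."""
    rng = np.random.default_rng(12345)
    vocab = [f"tok{i:02d}" for i in range(20)]
    return wm.WordEmbeddingSet(vocab=vocab, vectors=rng.standard_normal((20, 10)))


@pytest.fixture(scope="session")
def swiss_small():
    """Noiseless swiss roll, n=300, ambient D=10; (embeddings, latent)."""
    spec = wm.SyntheticManifoldSpec(
        n_words=300, latent_dim=2, ambient_dim=10, manifold="swiss_roll",
        noise_sigma=0.0, seed=11,
    )
    return wm.generate_manifold_embeddings(spec)


@pytest.fixture(scope="session")
def swiss_model(swiss_small):
    """Fitted model on the small swiss roll (normalized geodesic metric)."""
    emb, _ = swiss_small
    return wm.fit(emb.vectors, k=10, d=2, seed=0)


@pytest.fixture(scope="session")
def planar_data():
    """Noiseless 2-d linear subspace lifted to D=50; (X, latent)."""
    spec = wm.SyntheticManifoldSpec(
        n_words=300, latent_dim=2, ambient_dim=50, manifold="linear_subspace",
        noise_sigma=0.0, seed=5,
    )
    emb, lat = wm.generate_manifold_embeddings(spec)
    return emb.vectors, lat


def affine_residual(latent, Y):
    """Relative residual of the best affine map latent -> Y."""
    A = np.column_stack([latent, np.ones(len(latent))])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    denom = np.linalg.norm(Y - Y.mean(axis=0))
    return np.linalg.norm(Y - A @ coef) / denom
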