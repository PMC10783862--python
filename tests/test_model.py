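import numpy as np
import pytest

from bbvae.autograd import Tensor
from bbvae.features import build_graph
from bbvae.model import (
    ModelConfig,
    count_parameters,
    decode,
    embed_nodes,
    encode,
    gcn_layer,
    init_params,
    load_checkpoint,
    pool_to_residues,
    sample_latent,
    save_checkpoint,
)
from bbvae.synthetic import make_ensemble

from conftest import random_rigid_transform

CFG = ModelConfig()


@pytest.fixture(scope="module")
def params():
    return init_params(CFG, seed=0)


class TestEmbedding:
    def test_shape_and_type_sharing(self, params):
        onehot = np.zeros((72, 60))
        onehot[np.arange(72), np.arange(72) % 60] = 1
        out = embed_nodes(onehot, params)
        assert out.shape == (72, 64)
        np.testing.assert_array_equal(out[0], out[60])  # same atom type

    def test_invalid_rows_rejected(self, params):
        bad = np.zeros((4, 60))
        with pytest.raises(ValueError):
            embed_nodes(bad, params)
        bad[0, :2] = 1
        with pytest.raises(ValueError):
            embed_nodes(bad, params)

    def test_zero_weights_zero_output(self):
        onehot = np.eye(60)
        out = embed_nodes(onehot, {"embed.W": np.zeros((60, 64))})
        assert (out == 0).all()


class TestGcnLayer:
    def test_closed_gate_is_identity(self, rng):
        v = rng.standard_normal((5, 4))
        e = rng.standard_normal((8, 23))
        src = np.array([0, 1, 2, 3, 4, 0, 1, 2])
        dst = np.array([1, 2, 3, 4, 0, 2, 3, 4])
        h_in = 4 + 23 + 4
        out = gcn_layer(
            v, e, src, dst,
            Wg=np.zeros((h_in, 4)), bg=np.full(4, -1e9),
            Wc=rng.standard_normal((h_in, 4)), bc=np.zeros(4),
        )
        np.testing.assert_allclose(out.value, v, atol=1e-12)

    def test_isolated_node_unchanged(self, rng):
        v = rng.standard_normal((3, 4))
        e = rng.standard_normal((1, 23))
        out = gcn_layer(
            v, e, np.array([1]), np.array([2]),
            Wg=np.zeros((31, 4)), bg=np.zeros(4),
            Wc=rng.standard_normal((31, 4)), bc=np.ones(4),
        )
        np.testing.assert_array_equal(out.value[0], v[0])  # no in-edges
        assert np.abs(out.value[2] - v[2]).max() > 0  # receiver updated

    def test_hand_arithmetic_single_edge(self):
        # 1-d features, one edge 0 -> 1; h = [v1, e, v0]
        v = np.array([[2.0], [1.0]])
        e = np.array([[0.5]])
        Wg = np.array([[0.1], [0.2], [0.3]])
        Wc = np.array([[1.0], [-1.0], [2.0]])
        out = gcn_layer(
            v, e, np.array([0]), np.array([1]),
            Wg=Wg, bg=np.array([0.0]), Wc=Wc, bc=np.array([0.0]),
        )
        h = np.array([1.0, 0.5, 2.0])
        expected = 1.0 + (1 / (1 + np.exp(-(h @ Wg)[0]))) * max(0.0, (h @ Wc)[0])
        assert out.value[1, 0] == pytest.approx(float(expected), abs=1e-12)
        assert out.value[0, 0] == 2.0


class TestPooling:
    def test_shape(self, rng):
        out = pool_to_residues(rng.standard_normal((6, 4)), 2)
        assert out.shape == (2, 12)

    def test_order_sensitive(self, rng):
        x = rng.standard_normal((6, 4))
        swapped = x.copy()
        swapped[[0, 1]] = swapped[[1, 0]]
        a = pool_to_residues(x, 2).value
        b = pool_to_residues(swapped, 2).value
        assert np.abs(a - b).max() > 0

    def test_indivisible_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_to_residues(rng.standard_normal((7, 4)), 2)


class TestEncoder:
    def test_shapes_and_determinism(self, params):
        conf = make_ensemble(L=24, n=1, seed=0)[0]
        g = build_graph(conf, k=CFG.k_neighbors)
        mu1, lv1 = encode(g, params, CFG)
        mu2, lv2 = encode(g, params, CFG)
        assert mu1.shape == (24, 32) and lv1.shape == (24, 32)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(lv1, lv2)

    def test_se3_invariance(self, params, rng):
        conf = make_ensemble(L=8, n=1, seed=3)[0]
        mu0, lv0 = encode(build_graph(conf, k=10), params, CFG)
        worst = 0.0
        for _ in range(20):
            R, t = random_rigid_transform(rng)
            mu1, _ = encode(build_graph(conf.transformed(R, t), k=10), params, CFG)
            worst = max(worst, np.abs(mu1 - mu0).max())
        assert worst < 1e-5


class TestLatentSampling:
    def test_temperature_zero_returns_mean(self, rng):
        mu = rng.standard_normal((4, 3))
        logvar = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(sample_latent(mu, logvar, 0.0, rng), mu)

    def test_seeded_reproducibility(self, rng):
        mu = np.zeros((4, 3))
        logvar = np.zeros((4, 3))
        a = sample_latent(mu, logvar, 1.0, rng=7)
        b = sample_latent(mu, logvar, 1.0, rng=7)
        np.testing.assert_array_equal(a, b)

    def test_moments_match_reparameterization(self):
        n = 100_000
        z = sample_latent(np.zeros((n, 1)), np.zeros((n, 1)), 1.0, rng=0)
        se_mean = 1.0 / np.sqrt(n)
        assert abs(z.mean()) < 3 * se_mean
        assert abs(z.var() - 1.0) < 3 * np.sqrt(2.0 / n)
        z2 = sample_latent(np.zeros((n, 1)), np.full((n, 1), np.log(4.0)), 0.5, rng=0)
        # sigma * T = 2 * 0.5 = 1
        assert abs(z2.var() - 1.0) < 3 * np.sqrt(2.0 / n)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            sample_latent(np.zeros(3), np.zeros(3), -0.1)


class TestDecoder:
    def test_shape_and_determinism(self, params, rng):
        z = rng.standard_normal((24, 32))
        a = decode(z, "A" * 24, params, CFG)
        b = decode(z, "A" * 24, params, CFG)
        assert a.shape == (24, 3, 3)
        np.testing.assert_array_equal(a, b)

    def test_positional_encoding_breaks_permutation_symmetry(self, params, rng):
        z = rng.standard_normal((6, 32))
        perm = np.array([3, 1, 0, 5, 4, 2])
        out = decode(z, "A" * 6, params, CFG)
        out_perm = decode(z[perm], "A" * 6, params, CFG)
        assert np.abs(out_perm - out[perm]).max() > 1e-3

    def test_length_mismatch_rejected(self, params, rng):
        with pytest.raises(ValueError):
            decode(rng.standard_normal((5, 32)), "A" * 6, params, CFG)


class TestParameterCount:
    def test_independent_of_protein_length(self, params):
        # parameters are built from the config alone; encode/decode two very
        # different lengths with the same dict and verify nothing resizes
        for L in (24, 140):
            conf = make_ensemble(L=L, n=1, seed=0)[0]
            g = build_graph(conf, k=10)
            mu, lv = encode(g, params, CFG)
            decode(mu, conf.sequence, params, CFG)
        assert count_parameters(params) == count_parameters(init_params(CFG, seed=1))

    def test_order_of_magnitude_compact(self, params):
        assert 5e4 < count_parameters(params) < 5e5

    def test_monotone_in_latent_dim(self):
        small = init_params(ModelConfig(latent_dim=16), seed=0)
        big = init_params(ModelConfig(latent_dim=32), seed=0)
        assert count_parameters(big) > count_parameters(small)


class TestConfigAndCheckpoint:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(decoder_width=65, attention_heads=4)
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=0)

    def test_checkpoint_roundtrip(self, params, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, CFG, iteration=123)
        loaded, cfg, it = load_checkpoint(path)
        assert it == 123 and cfg == CFG
        assert set(loaded) == set(params)
        for k in params:
            np.testing.assert_array_equal(loaded[k], params[k])
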