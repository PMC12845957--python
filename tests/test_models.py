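"""Architecture contracts: patch tiling, layer wiring, probability outputs."""

import numpy as np
import pytest

from whalesong import nn
from whalesong.models import CNNConfig, ViTConfig, build_cnn, build_vit, extract_patches


def _image(seed=0, shape=(125, 50, 3)):
    return np.random.default_rng(seed).standard_normal(shape).astype(np.float32)


class TestExtractPatches:
    def test_standard_image_gives_90_tokens_of_192(self):
        patches = extract_patches(_image())
        assert patches.shape == (90, 192)

    def test_single_patch_image_is_its_own_flattening(self):
        img = _image(shape=(8, 8, 3))
        patches = extract_patches(img)
        assert patches.shape == (1, 192)
        assert np.array_equal(patches[0], img.reshape(-1))

    def test_16x10_matches_brute_force_slices(self):
        img = _image(shape=(16, 10, 3))
        patches = extract_patches(img)
        assert patches.shape == (2, 192)
        assert np.array_equal(patches[0], img[0:8, 0:8, :].reshape(-1))
        assert np.array_equal(patches[1], img[8:16, 0:8, :].reshape(-1))

    def test_tiles_are_disjoint_and_cover_120x48(self):
        img = _image()
        patches = extract_patches(img)
        rebuilt = np.zeros((120, 48, 3), dtype=np.float32)
        for idx in range(90):
            r, c = divmod(idx, 6)  # raster order: rows of the 15x6 grid
            rebuilt[8 * r : 8 * r + 8, 8 * c : 8 * c + 8, :] = patches[idx].reshape(8, 8, 3)
        assert np.array_equal(rebuilt, img[:120, :48, :])

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(_image(shape=(4, 4, 3)))
        with pytest.raises(ValueError):
            extract_patches(_image(), stride=4)


class TestCNN:
    def test_first_conv_weight_count(self):
        model = build_cnn(seed=0)
        conv1 = model.layers[0]
        assert conv1.w.value.size + conv1.b.value.size == 16 * (6 * 6 * 3 + 1) == 1744

    def test_forward_gives_probability_pairs(self):
        model = build_cnn(seed=0)
        p = model.predict_proba(_image()[None])
        assert p.shape == (1, 2)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-6

    def test_same_seed_same_weights(self):
        w1 = build_cnn(seed=3).get_weights()
        w2 = build_cnn(seed=3).get_weights()
        w3 = build_cnn(seed=4).get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
        assert any(not np.array_equal(a, b) for a, b in zip(w1, w3))

    def test_incompatible_input_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(CNNConfig(input_shape=(4, 4, 3)), seed=0)


class TestViT:
    def test_token_count_is_90(self):
        cfg = ViTConfig()
        assert cfg.n_patches == (125 // 8) * (50 // 8) == 90
        assert cfg.token_len == 192

    def test_forward_gives_probability_pairs(self):
        model = build_vit(seed=0)
        p = model.predict_proba(np.stack([_image(0), _image(1)]))
        assert p.shape == (2, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_mlp_width_must_close_the_residual(self):
        with pytest.raises(ValueError, match="residual"):
            build_vit(ViTConfig(mlp_units=(128, 32)), seed=0)

    def test_pooled_logits_permutation_invariant_without_positions(self):
        """With positional embeddings zeroed, attention + average pooling
        cannot distinguish patch orderings."""
        model = build_vit(seed=0)
        pos = model.layers[2]
        assert isinstance(pos, nn.PositionalEmbedding)
        pos.pos.value[...] = 0.0
        img = _image(5)
        tokens = model.layers[0].forward(img[None])
        perm = np.random.default_rng(9).permutation(90)

        def run_from_tokens(tok):
            h = tok.astype(np.float32)
            for layer in model.layers[1:-1]:
                h = layer.forward(h, training=False)
            return h

        a = run_from_tokens(tokens)
        b = run_from_tokens(tokens[:, perm, :])
        assert np.allclose(a, b, atol=1e-4)


class TestGradients:
    """Backward passes agree with central finite differences on tiny shapes."""

    @pytest.mark.parametrize(
        "layer_factory,x_shape",
        [
            (lambda rng: nn.Dense(5, 4, rng), (3, 5)),
            (lambda rng: nn.Conv2D(2, 3, 3, rng), (2, 6, 5, 2)),
            (lambda rng: nn.MultiHeadAttention(6, 2, 4, 0.0, rng), (2, 7, 6)),
            (lambda rng: nn.LayerNorm(6), (2, 7, 6)),
            (lambda rng: nn.BatchNorm(4), (5, 4)),
            (lambda rng: nn.GELU(), (3, 6)),
            (lambda rng: nn.MaxPool2D(), (2, 6, 6, 2)),
        ],
    )
    def test_input_gradient(self, layer_factory, x_shape):
        rng = np.random.default_rng(0)
        layer = layer_factory(rng)
        x = rng.standard_normal(x_shape).astype(np.float64).astype(np.float32)

        def loss_of(xv):
            y = layer.forward(xv.astype(np.float32), training=True, rng=np.random.default_rng(1))
            return float((y.astype(np.float64) ** 2).sum())

        y = layer.forward(x, training=True, rng=np.random.default_rng(1))
        dx = layer.backward((2.0 * y).astype(np.float32))
        eps = 1e-2
        flat_idx = [0, x.size // 2, x.size - 1]
        for fi in flat_idx:
            idx = np.unravel_index(fi, x_shape)
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            numeric = (loss_of(xp) - loss_of(xm)) / (2 * eps)
            assert dx[idx] == pytest.approx(numeric, rel=0.05, abs=0.02)

    def test_parameter_gradients_dense(self):
        rng = np.random.default_rng(0)
        layer = nn.Dense(4, 3, rng)
        x = rng.standard_normal((5, 4)).astype(np.float32)
        y = layer.forward(x)
        layer.backward((2 * y).astype(np.float32))
        eps = 1e-2
        g = layer.w.grad[1, 2]
        layer.w.value[1, 2] += eps
        up = float((layer.forward(x) ** 2).sum())
        layer.w.value[1, 2] -= 2 * eps
        dn = float((layer.forward(x) ** 2).sum())
        assert g == pytest.approx((up - dn) / (2 * eps), rel=0.02)
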