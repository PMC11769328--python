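"""Network building blocks: reference conv, attention gates, PCA, training."""

import numpy as np
import pytest

from hyperseed.nn import (
    ArchitectureSpec,
    GlobalAttention,
    KernelSet,
    SqueezeExcite,
    TrainConfig,
    apply_pca,
    build_model,
    conv3d_reference,
    fit_pca,
    predict,
    train,
)


def _bruteforce_conv3d(volume, kernel):
    a, b, c = kernel.shape
    out = np.zeros(tuple(v - k + 1 for v, k in zip(volume.shape, kernel.shape)))
    for x in range(out.shape[0]):
        for y in range(out.shape[1]):
            for z in range(out.shape[2]):
                acc = 0.0
                for i in range(a):
                    for j in range(b):
                        for k in range(c):
                            acc += volume[x + i, y + j, z + k] * kernel[i, j, k]
                out[x, y, z] = acc
    return out


class TestConv3dReference:
    def test_scalar_kernel_scales_input(self):
        vol = np.arange(27.0).reshape(3, 3, 3)
        np.testing.assert_allclose(conv3d_reference(vol, np.full((1, 1, 1), 2.0)),
                                   2 * vol)

    def test_ones_kernel_counts_window(self):
        out = conv3d_reference(np.ones((3, 3, 3)), np.ones((2, 2, 2)))
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out, 8.0)

    def test_full_size_kernel_is_dot_product(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(3, 4, 5))
        ker = rng.normal(size=(3, 4, 5))
        out = conv3d_reference(vol, ker)
        assert out.shape == (1, 1, 1)
        np.testing.assert_allclose(out[0, 0, 0], np.sum(vol * ker))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            vshape = tuple(rng.integers(2, 7, 2)) + (int(rng.integers(2, 11)),)
            kshape = tuple(int(rng.integers(1, s + 1)) for s in vshape)
            vol = rng.normal(size=vshape)
            ker = rng.normal(size=kshape)
            np.testing.assert_allclose(conv3d_reference(vol, ker),
                                       _bruteforce_conv3d(vol, ker), atol=1e-9)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv3d_reference(np.ones((2, 2, 2)), np.ones((3, 2, 2)))


class TestChannelGates:
    def test_zero_weight_attention_halves_input(self):
        block = GlobalAttention(channels=4)  # zero-initialized gate
        x = np.random.default_rng(2).normal(size=(3, 5, 5, 6, 4))
        out = block.forward(x, train=False)
        np.testing.assert_allclose(out, 0.5 * x)

    def test_zero_weight_se_halves_input(self):
        block = SqueezeExcite(channels=4, reduction=2)
        x = np.random.default_rng(3).normal(size=(3, 5, 5, 4))
        out = block.forward(x, train=False)
        np.testing.assert_allclose(out, 0.5 * x)

    def test_two_channel_hand_computation(self):
        block = GlobalAttention(channels=2)
        block.params["w1"] = np.array([[1.0], [0.0]])
        block.params["b1"] = np.array([0.5])
        block.params["w2"] = np.array([[1.0, -1.0]])
        block.params["b2"] = np.array([0.0, 0.0])
        x = np.ones((1, 2, 1, 1, 2))
        x[0, :, 0, 0, 1] = 3.0
        g = np.array([1.0, 3.0])  # pooled per channel
        h1 = max(g[0] * 1.0 + 0.5, 0.0)
        a = 1 / (1 + np.exp(-np.array([h1, -h1])))
        out = block.forward(x, train=False)
        np.testing.assert_allclose(out[0, 0, 0, 0], g * 0 + np.array([1.0, 3.0]) * a)

    def test_se_constant_map_squeeze_is_exact(self):
        block = SqueezeExcite(channels=2, reduction=2,
                              rng=np.random.default_rng(0))
        x = np.full((1, 4, 4, 2), 0.7)
        block.forward(x, train=True)
        cached_g = block._cache[1]
        np.testing.assert_allclose(cached_g, 0.7)

    def test_gates_bounded_and_shape_preserved(self):
        rng = np.random.default_rng(4)
        block = GlobalAttention(channels=6, rng=rng)
        x = rng.normal(size=(2, 3, 3, 4, 6))
        out = block.forward(x, train=True)
        assert out.shape == x.shape
        gate = block._cache[3]
        assert np.all((gate > 0) & (gate < 1))


class TestPCA:
    def test_complete_basis_reconstructs(self):
        rng = np.random.default_rng(5)
        pixels = rng.normal(size=(200, 6))
        reducer = fit_pca(pixels, 6)
        projected = apply_pca(pixels.reshape(10, 20, 6), reducer)
        back = projected.reshape(-1, 6) @ reducer.components + reducer.mean
        np.testing.assert_allclose(back, pixels, atol=1e-8)

    def test_rank_one_data_captured_by_one_component(self):
        rng = np.random.default_rng(6)
        direction = rng.normal(size=8)
        pixels = np.outer(rng.normal(size=300), direction)
        reducer = fit_pca(pixels, 1)
        assert reducer.explained_variance[0] >= 0.999

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(7)
        reducer = fit_pca(rng.normal(size=(100, 10)), 10)
        assert np.all(np.diff(reducer.explained_variance) <= 1e-12)

    def test_k_larger_than_bands_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((10, 4)), 5)


class TestBuildModel:
    def test_depth_arithmetic_for_standard_kernel_set(self):
        arch = ArchitectureSpec(kernel_set=1)
        model = build_model(arch, input_depth=30, input_hw=(32, 32))
        x = np.random.default_rng(8).normal(size=(2, 32, 32, 30, 1))
        out = model.forward(x, train=False)
        assert out.shape == (2, 1)

    def test_classification_rows_sum_to_one(self):
        arch = ArchitectureSpec(kernel_set="compact", task="classification",
                                conv3d_filters=(2, 2, 2), conv2d_filters=4,
                                dense_units=(8, 4))
        model = build_model(arch, input_depth=8, input_hw=(12, 12))
        x = np.random.default_rng(9).normal(size=(5, 12, 12, 8, 1))
        probs = predict(model, x)
        assert probs.shape == (5, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_kernel_set_exhausting_depth_rejected(self):
        arch = ArchitectureSpec(kernel_set=3)  # needs depth >= 33
        with pytest.raises(ValueError):
            build_model(arch, input_depth=8)

    def test_batch_size_invariance(self):
        arch = ArchitectureSpec(kernel_set="compact", conv3d_filters=(2, 2, 2),
                                conv2d_filters=4, dense_units=(8, 4))
        model = build_model(arch, input_depth=8, input_hw=(10, 10))
        x = np.random.default_rng(10).normal(size=(6, 10, 10, 8, 1))
        whole = predict(model, x)
        singles = np.concatenate([predict(model, x[i:i + 1]) for i in range(6)])
        np.testing.assert_allclose(whole, singles, atol=1e-5)


class TestTraining:
    @staticmethod
    def _toy_data(n=40, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 10, 10, 8, 1))
        scale = rng.uniform(0.5, 2.0, n)
        x *= scale[:, None, None, None, None]
        y = 3.0 * scale + 1.0
        return x, y

    @staticmethod
    def _small_arch(task="regression"):
        return ArchitectureSpec(kernel_set="compact", conv3d_filters=(2, 3, 4),
                                conv2d_filters=4, dense_units=(16, 8), task=task)

    def test_loss_decreases(self):
        x, y = self._toy_data()
        model = build_model(self._small_arch(), 8, (10, 10), rng_seed=0)
        history = train(model, x, y, TrainConfig(epochs=15, rng_seed=0))
        assert history[-1] < history[0]

    def test_same_seed_identical_history(self):
        x, y = self._toy_data()
        runs = []
        for _ in range(2):
            model = build_model(self._small_arch(), 8, (10, 10), rng_seed=1)
            runs.append(train(model, x, y, TrainConfig(epochs=5, rng_seed=1)))
        assert runs[0] == runs[1]

    def test_onehot_toy_classification_memorized(self):
        rng = np.random.default_rng(11)
        n = 30
        classes = rng.integers(0, 3, n)
        x = np.zeros((n, 10, 10, 8, 1))
        for i, c in enumerate(classes):
            x[i, :, :, 2 * c:2 * c + 2, 0] = 1.0 + 0.1 * rng.normal(size=(10, 10, 2))
        model = build_model(self._small_arch("classification"), 8, (10, 10),
                            rng_seed=2)
        train(model, x, classes,
              TrainConfig(epochs=60, batch_size=8,
                          loss="categorical_cross_entropy", rng_seed=2))
        preds = predict(model, x).argmax(axis=1)
        assert np.mean(preds == classes) == 1.0

    def test_loss_task_mismatch_rejected(self):
        x, y = self._toy_data(10)
        model = build_model(self._small_arch(), 8, (10, 10))
        with pytest.raises(ValueError):
            train(model, x, y, TrainConfig(loss="categorical_cross_entropy"))


def test_kernel_set_constants_match_documented_shapes():
    from hyperseed.nn import KERNEL_SETS

    assert KERNEL_SETS[1].shapes == ((3, 3, 7), (3, 3, 5), (3, 3, 3))
    assert KERNEL_SETS[2].shapes == ((3, 3, 11), (3, 3, 9), (3, 3, 7))
    assert KERNEL_SETS[3].shapes == ((5, 5, 15), (5, 5, 11), (5, 5, 9))


def test_invalid_kernel_shape_rejected():
    with pytest.raises(ValueError):
        KernelSet((3, 3), (3, 3, 3), (3, 3, 3))
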