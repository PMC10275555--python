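import numpy as np
import pytest

from sleeparousal import (
    BackboneConfig,
    ConfigurationError,
    TrainConfig,
    ValidationError,
    build_extractor,
    extract_features,
    finetune,
)
from sleeparousal.backbone.layers import (
    BatchNorm2d,
    ConcatBranches,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    ResidualBlock,
    Sequential,
    softmax_cross_entropy,
)
from sleeparousal.backbone.network import FeatureExtractor


@pytest.fixture(scope="module")
def tiny_fx():
    return build_extractor(BackboneConfig(scale="tiny", seed=0))


@pytest.fixture(scope="module")
def tiny_images():
    rng = np.random.default_rng(5)
    images = rng.random((20, 75, 75))
    labels = np.arange(20) % 2
    # give the two classes a systematic intensity difference
    images[labels == 1] = np.clip(images[labels == 1] * 0.5 + 0.4, 0, 1)
    return images, labels


class TestArchitecture:
    def test_tiny_feature_length_is_width_scaled(self, tiny_fx):
        assert tiny_fx.feature_dim == 192  # 1536 * 0.125
        feats = extract_features(tiny_fx, np.random.default_rng(0).random((2, 75, 75)))
        assert feats.shape == (2, 192)

    def test_off_size_input_rejected(self, tiny_fx):
        with pytest.raises(ValidationError):
            extract_features(tiny_fx, np.zeros((1, 74, 74)))

    def test_input_too_small_for_reduction_chain(self):
        with pytest.raises(ConfigurationError):
            build_extractor(BackboneConfig(scale="tiny", input_hw=20))

    def test_seeded_init_reproducible(self):
        fx1 = build_extractor(BackboneConfig(scale="tiny", seed=9))
        fx2 = build_extractor(BackboneConfig(scale="tiny", seed=9))
        for (n1, p1), (n2, p2) in zip(
            fx1.net.named_parameters(), fx2.net.named_parameters()
        ):
            assert n1 == n2
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_residual_block_reduces_to_identity_when_zeroed(self, tiny_fx):
        """Zeroing all residual-branch weights turns the block into
        relu(x): the scaled branch output vanishes."""
        fx = build_extractor(BackboneConfig(scale="tiny", seed=2))
        block = fx.net.modules_list[1]
        assert isinstance(block, ResidualBlock)
        for _, p in block.inner.named_parameters():
            p.value[...] = 0.0
        c = 48  # tiny stem output channels
        x = np.random.default_rng(3).standard_normal((2, c, 17, 17)).astype(np.float32)
        out = block.forward(x, mode="eval")
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-6)


class TestExtraction:
    def test_identical_images_identical_rows(self, tiny_fx):
        img = np.random.default_rng(1).random((75, 75))
        feats = extract_features(tiny_fx, [img, img])
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_eval_mode_repeatable(self, tiny_fx):
        imgs = np.random.default_rng(2).random((3, 75, 75))
        f1 = extract_features(tiny_fx, imgs)
        f2 = extract_features(tiny_fx, imgs)
        np.testing.assert_array_equal(f1, f2)

    def test_permutation_equivariance(self, tiny_fx):
        imgs = np.random.default_rng(4).random((5, 75, 75))
        perm = np.array([3, 0, 4, 1, 2])
        f = extract_features(tiny_fx, imgs)
        fp = extract_features(tiny_fx, imgs[perm])
        np.testing.assert_allclose(fp, f[perm], rtol=0, atol=1e-5)

    def test_checkpoint_round_trip(self, tmp_path, tiny_fx):
        imgs = np.random.default_rng(6).random((2, 75, 75))
        path = str(tmp_path / "weights.npz")
        tiny_fx.save(path)
        loaded = FeatureExtractor.load(path)
        np.testing.assert_array_equal(
            extract_features(tiny_fx, imgs), extract_features(loaded, imgs)
        )


class TestFinetune:
    def test_zero_epochs_leaves_parameters_unchanged(self, tiny_images):
        images, labels = tiny_images
        fx = build_extractor(BackboneConfig(scale="tiny", seed=1))
        before = {n: p.value.copy() for n, p in fx.net.named_parameters()}
        finetune(fx, images, labels, TrainConfig(epochs=0))
        for name, p in fx.net.named_parameters():
            np.testing.assert_array_equal(before[name], p.value)

    def test_single_class_rejected(self, tiny_images):
        images, _ = tiny_images
        fx = build_extractor(BackboneConfig(scale="tiny", seed=1))
        with pytest.raises(ValidationError):
            finetune(fx, images, np.zeros(len(images), dtype=int))

    def test_default_learning_rate(self):
        assert TrainConfig().lr == 0.001

    def test_overfits_small_two_class_set(self, tiny_images):
        """An over-parameterised network driven by full-batch gradient
        descent must reach >=99% training accuracy on 20 images."""
        images, labels = tiny_images
        fx = build_extractor(BackboneConfig(scale="tiny", seed=1))
        finetune(fx, images, labels,
                 TrainConfig(optimizer="rmsprop", epochs=80, seed=0))
        assert fx.finetune_history_[-1]["train_accuracy"] >= 0.99
        losses = [h["loss"] for h in fx.finetune_history_]
        assert losses[-1] < losses[0]


class TestGradients:
    def test_backward_matches_numerical_gradients(self):
        """Reverse-mode gradients of a small composite network agree with
        central finite differences in float64."""
        rng = np.random.default_rng(0)
        net = Sequential(
            Conv2d(3, 4, 3, stride=2, padding="valid", rng=rng, dtype=np.float64),
            BatchNorm2d(4, dtype=np.float64),
            ReLU(),
            ConcatBranches(
                Sequential(Conv2d(4, 3, 1, rng=rng, dtype=np.float64),
                           BatchNorm2d(3, dtype=np.float64), ReLU()),
                Sequential(Conv2d(4, 2, (1, 3), rng=rng, dtype=np.float64), ReLU()),
            ),
            ResidualBlock(
                Sequential(Conv2d(5, 4, 3, rng=rng, dtype=np.float64), ReLU(),
                           Conv2d(4, 5, 1, bias=True, rng=rng, dtype=np.float64)),
                0.2,
            ),
            MaxPool2d(3, 2, "valid"),
            GlobalAvgPool(),
        )
        head = Linear(5, 2, rng=rng, dtype=np.float64)
        x = rng.random((4, 3, 13, 13))
        y = np.array([0, 1, 0, 1])

        def loss_fn():
            feats = net.forward(x, mode="train", cache=True)
            return softmax_cross_entropy(head.forward(feats, cache=True), y)

        loss, dlogits = loss_fn()
        for p in net.parameters() + head.parameters():
            p.grad[...] = 0.0
        net.backward(head.backward(dlogits))
        for name, p in list(net.named_parameters()) + [("head", head.weight)]:
            flat = p.value.ravel()
            for i in rng.integers(0, flat.size, size=min(3, flat.size)):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                up, _ = loss_fn()
                flat[i] = old - eps
                down, _ = loss_fn()
                flat[i] = old
                numeric = (up - down) / (2 * eps)
                analytic = p.grad.ravel()[i]
                assert abs(numeric - analytic) <= 1e-5 + 1e-4 * abs(numeric), name
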