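"""Architectures, parameter counting, forward/backward passes, training."""

import dataclasses
import warnings

import numpy as np
import pytest

from ccdnet import nn
from ccdnet.models import (
    ArchitectureSpec,
    ConvBlock,
    ModelState,
    TrainConfig,
    build_architecture,
    count_parameters,
    cross_entropy,
    feature_maps,
    forward,
    train,
)


class TestArchitectureSpecs:
    @pytest.mark.parametrize(
        "name, flatten",
        [("lenet5_1d", 1088), ("cpcnn4", 1152), ("cpcnn5", 784), ("alexnet_1d", 1024)],
    )
    def test_flatten_lengths(self, name, flatten):
        assert build_architecture(name).flatten_length == flatten

    def test_cpcnn5_kernel_sequence(self):
        spec = build_architecture("cpcnn5")
        assert [b.kernel_length for b in spec.conv_blocks] == [11, 7, 5, 3]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_architecture("resnet50")

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ConvBlock(8, 4)

    def test_collapsing_pool_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(
                name="x",
                input_length=8,
                conv_blocks=tuple(ConvBlock(4, 3) for _ in range(5)),
                fc_widths=(8,),
            )


class TestCountParameters:
    def test_single_conv_by_hand(self):
        spec = ArchitectureSpec(
            name="tiny", input_length=8, conv_blocks=(ConvBlock(1, 3),), fc_widths=()
        )
        # conv contributes 1*(1*3+1)=4; output dense 2*(4+1)=10
        assert count_parameters(spec) == 4 + 2 * (spec.flatten_length + 1)

    @pytest.mark.parametrize(
        "name, expected",
        [("lenet5_1d", 158_274), ("cpcnn4", 191_234)],
    )
    def test_published_totals_without_batch_norm(self, name, expected):
        assert count_parameters(build_architecture(name), include_batch_norm=False) == expected

    @pytest.mark.parametrize("name", ["lenet5_1d", "cpcnn4", "cpcnn5", "alexnet_1d"])
    def test_closed_form_matches_materialized_network(self, name):
        spec = build_architecture(name)
        assert count_parameters(spec) == ModelState(spec, seed=0).n_parameters()


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        model = ModelState(build_architecture("cpcnn4"), seed=1)
        probs = forward(model, rng.normal(size=(7, 72)))
        assert probs.shape == (7, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_hand_computed_valid_convolution(self):
        np.testing.assert_allclose(nn.conv1d_valid([1, 2, 3], [1, 1]), [3, 5])
        np.testing.assert_allclose(nn.conv1d_valid([1, 2, 3], [1, 0, -1], bias=1.0), [-1])

    def test_zero_parameters_give_uniform_posterior(self, rng):
        model = ModelState(build_architecture("lenet5_1d"), seed=0)
        for _, _, arr in model.net.parameters():
            arr[...] = 0.0
        probs = forward(model, rng.normal(size=(4, 70)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        model = ModelState(build_architecture("cpcnn4"), seed=0)
        with pytest.raises(ValueError):
            forward(model, rng.normal(size=(3, 70)))

    def test_translation_covariance_before_flatten(self, rng):
        """Shifting the input by 2 samples shifts feature maps by 1 pool stride."""
        spec = ArchitectureSpec(
            name="cov", input_length=64, conv_blocks=(ConvBlock(6, 5),), fc_widths=(8,)
        )
        model = ModelState(spec, seed=3)
        content = rng.normal(size=20)
        x0 = np.zeros(64)
        x1 = np.zeros(64)
        x0[20:40] = content
        x1[22:42] = content  # shifted by 2 input samples
        f0 = feature_maps(model, x0)[0]
        f1 = feature_maps(model, x1)[0]
        # compare away from the padded edges
        np.testing.assert_allclose(f0[:, 8:24], f1[:, 9:25], atol=1e-10)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        spec = ArchitectureSpec(
            name="grad",
            input_length=12,
            conv_blocks=(ConvBlock(3, 3, batch_norm=True), ConvBlock(4, 3)),
            fc_widths=(6,),
            dropout_after_last_conv=0.0,
            dropout_after_first_fc=0.0,
        )
        model = ModelState(spec, seed=5)
        model.train_mode(True)
        X = rng.normal(size=(6, 12))
        y = np.array([0, 1, 1, 0, 1, 0])
        onehot = np.eye(2)[y]

        def loss_value():
            logits = model.net.forward(X[:, None, :])
            return cross_entropy(nn.softmax(logits), y)

        logits = model.net.forward(X[:, None, :])
        probs = nn.softmax(logits)
        model.net.backward((probs - onehot) / len(y))
        params = model.net.parameters()
        grads = model.net.gradients()
        eps = 1e-6
        checked = 0
        for (_, _, p), g in zip(params, grads):
            flat = p.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_value()
                flat[idx] = orig - eps
                lm = loss_value()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-6)
                checked += 1
        assert checked >= 25


class TestCrossEntropy:
    def test_half_probability_gives_log2(self):
        assert cross_entropy([0.5], [1]) == pytest.approx(np.log(2))

    def test_confident_correct_prediction_tends_to_zero(self):
        assert cross_entropy([1 - 1e-9], [1]) < 1e-6

    def test_batch_mean_contract(self):
        a = cross_entropy([0.9], [1])
        b = cross_entropy([0.2], [0])
        both = cross_entropy([0.9, 0.2], [1, 0])
        assert both == pytest.approx((a + b) / 2)

    def test_clamped_at_extremes(self):
        assert np.isfinite(cross_entropy([0.0, 1.0], [1, 0]))

    def test_positive_unless_exact(self):
        assert cross_entropy([0.7, 0.3], [1, 0]) > 0


class TestTraining:
    def test_loss_decreases_on_separable_data(self, separable_splits):
        train_set, _, _ = separable_splits
        drops = []
        for seed in range(5):
            _, hist = train(
                build_architecture("cpcnn4"),
                (train_set.X, train_set.y),
                cfg=TrainConfig(iterations=50, seed=seed),
            )
            loss = np.asarray(hist["loss"])
            drops.append(loss[:5].mean() - loss[-5:].mean())
        assert np.median(drops) > 0

    def test_same_seed_identical_final_loss(self, separable_splits):
        train_set, _, _ = separable_splits
        cfg = TrainConfig(iterations=30, seed=7)
        _, h1 = train(build_architecture("cpcnn4"), (train_set.X, train_set.y), cfg=cfg)
        _, h2 = train(build_architecture("cpcnn4"), (train_set.X, train_set.y), cfg=cfg)
        assert h1["loss"][-1] == h2["loss"][-1]

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 72))
        y = np.ones(20, dtype=int)
        with pytest.raises(ValueError):
            train(build_architecture("cpcnn4"), (X, y))

    def test_wider_first_kernel_soft_guard(self, separable_splits):
        """Wide first filters should not learn slower (soft regression guard)."""
        train_set, _, _ = separable_splits
        threshold = 0.25

        def iters_to_threshold(first_kernel, seed):
            spec = build_architecture("cpcnn4")
            blocks = (ConvBlock(32, first_kernel, True),) + spec.conv_blocks[1:]
            spec = dataclasses.replace(spec, name=f"k{first_kernel}", conv_blocks=blocks)
            _, hist = train(
                spec, (train_set.X, train_set.y), cfg=TrainConfig(iterations=80, seed=seed)
            )
            loss = np.asarray(hist["loss"])
            hit = np.nonzero(loss <= threshold)[0]
            return hit[0] if hit.size else len(loss)

        wide = np.median([iters_to_threshold(11, s) for s in range(5)])
        narrow = np.median([iters_to_threshold(5, s) for s in range(5)])
        if wide > narrow:
            warnings.warn(
                f"wide first kernel reached loss {threshold} in {wide} iterations "
                f"vs {narrow} for the narrow kernel (soft guard)"
            )


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
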