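import dataclasses

import numpy as np
import pytest

from neurotdb.nn import Adam, softmax_cross_entropy
from neurotdb.ssm import (
    MfNet,
    SfeAutoNet,
    SfeImageConfig,
    SfeImageNet,
    SieNet,
    SsmModel,
    TrainConfig,
    accuracy_f1,
    augment_rotations,
    evaluate,
    mf_forward,
    normalize_image,
    sfe_auto_forward,
    sfe_image_forward,
    sie_forward,
    train_stagewise,
)
from neurotdb.synth import SynthConfig, generate_labeled_corpus


@pytest.fixture(scope="module")
def small_corpus():
    cfg = SynthConfig(seed=21, n_neurons=2, nodes_per_neuron=700, volume_shape=(64, 160, 160))
    blocks, _ = generate_labeled_corpus(cfg)
    assert len(blocks) >= 10
    return blocks


@pytest.fixture(scope="module")
def tiny_image_net():
    return SfeImageNet(SfeImageConfig(base_channels=2), seed=0)


class TestSfeImage:
    def test_stage_chain_spatial_sizes(self, tiny_image_net, rng):
        # channel width does not affect the spatial chain
        x = rng.random((1, 1, 32, 64, 64)).astype(np.float32)
        shapes = tiny_image_net.stage_output_shapes(x)
        assert shapes["conv"] == (32, 32, 32)
        assert shapes["maxpool"] == (16, 16, 16)
        assert shapes["layer1"] == (16, 16, 16)
        assert shapes["layer2"] == (8, 8, 8)
        assert shapes["layer3"] == (4, 4, 4)
        assert shapes["layer4"] == (2, 2, 2)
        assert shapes["avgpool"] == (1, 1, 1)
        assert shapes["fc"] == (2,)

    def test_softmax_of_output_sums_to_one(self, tiny_image_net, rng):
        from neurotdb.nn import softmax

        out = sfe_image_forward(tiny_image_net, rng.random((32, 64, 64)))
        assert out.shape == (2,)
        assert softmax(out).sum() == pytest.approx(1.0, abs=1e-6)

    def test_wrong_shape_rejected(self, tiny_image_net, rng):
        with pytest.raises(ValueError):
            sfe_image_forward(tiny_image_net, rng.random((64, 64, 32)))

    def test_eval_mode_deterministic(self, tiny_image_net, rng):
        x = rng.random((32, 64, 64))
        a = sfe_image_forward(tiny_image_net, x)
        b = sfe_image_forward(tiny_image_net, x)
        np.testing.assert_array_equal(a, b)  # dropout disabled at evaluation


class TestSfeAuto:
    def test_zero_vector_finite(self):
        net = SfeAutoNet(seed=0)
        out = sfe_auto_forward(net, np.zeros(32))
        assert out.shape == (2,) and np.all(np.isfinite(out))

    def test_width_validated(self):
        net = SfeAutoNet(seed=0)
        with pytest.raises(ValueError):
            sfe_auto_forward(net, np.zeros(31))

    def test_distinct_inputs_distinct_outputs(self, rng):
        net = SfeAutoNet(seed=0)
        a = sfe_auto_forward(net, rng.normal(size=32))
        b = sfe_auto_forward(net, rng.normal(size=32))
        assert not np.allclose(a, b)

    def test_layer_widths(self):
        net = SfeAutoNet(seed=0)
        widths = [m.out_features for m in net.net.steps if hasattr(m, "out_features")]
        assert widths == [100, 50, 2]


class TestAugmentation:
    def _blocks(self, rng, n=5):
        from test_sequences import make_block

        out = []
        for i in range(n):
            blk = make_block(order=i * 100, label="low" if i % 2 else "high", index=i)
            blk = dataclasses.replace(blk, image=rng.random((32, 64, 64)).astype(np.float32))
            out.append(blk)
        return out

    def test_three_new_samples_per_block(self, rng):
        blocks = self._blocks(rng, 5)
        assert len(augment_rotations(blocks)) == 15

    def test_labels_copied(self, rng):
        blocks = self._blocks(rng, 4)
        out = augment_rotations(blocks)
        for i, blk in enumerate(blocks):
            for k in range(3):
                assert out[3 * i + k].label == blk.label

    def test_four_rotations_identity(self, rng):
        img = rng.random((32, 64, 64))
        rotated = img
        for _ in range(4):
            rotated = np.rot90(rotated, 1, axes=(1, 2))
        np.testing.assert_array_equal(rotated, img)

    def test_rotation_index_map_oracle(self, rng):
        blocks = self._blocks(rng, 1)
        img = blocks[0].image
        out = augment_rotations(blocks)
        quarter = out[0].image  # 90° in the 64×64 plane
        for _ in range(8):
            z, y, x = (int(v) for v in rng.integers(0, (32, 64, 64)))
            assert quarter[z, y, x] == img[z, x, 63 - y]

    def test_shape_preserved(self, rng):
        for blk in augment_rotations(self._blocks(rng, 2)):
            assert blk.image.shape == (32, 64, 64)


class TestSie:
    def test_s1_zero_context(self, rng):
        net = SieNet(seed=0)
        out = sie_forward(net, [rng.normal(size=2)], [np.zeros(2)])
        assert out.shape == (2,) and np.all(np.isfinite(out))

    def test_deterministic(self, rng):
        net = SieNet(seed=0)
        sfe = [rng.normal(size=2) for _ in range(3)]
        ctx = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.zeros(2)]
        np.testing.assert_array_equal(sie_forward(net, sfe, ctx), sie_forward(net, sfe, ctx))

    def test_width_mismatch(self, rng):
        net = SieNet(seed=0)
        with pytest.raises(ValueError):
            sie_forward(net, [rng.normal(size=3)], [np.zeros(2)])
        with pytest.raises(ValueError):
            sie_forward(net, [rng.normal(size=2)], [np.zeros(2), np.zeros(2)])

    def test_learns_markov_context_rule(self, rng):
        # previous label fully determines the next (flip rule); SFE inputs
        # are pure noise, so beating the 50% marginal proves context use
        net = SieNet(seed=1)
        n = 400
        prev = rng.integers(0, 2, n)
        target = 1 - prev
        x = np.zeros((n, 2, 4), dtype=np.float32)
        x[np.arange(n), 0, prev] = 1.0
        x[:, :, 2:] = rng.normal(0, 0.3, (n, 2, 2))
        opt = Adam(net.parameters(), lr=0.01)
        for _ in range(120):
            logits = net.forward(x, train=True)
            _, grad = softmax_cross_entropy(logits, target)
            opt.zero_grad()
            net.backward(grad)
            opt.step()
        acc = (net.forward(x).argmax(axis=1) == target).mean()
        assert acc > 0.9


class TestMf:
    def test_softmax_output(self, rng):
        net = MfNet(seed=0)
        out = mf_forward(net, rng.normal(size=2), rng.normal(size=2))
        assert out.shape == (2,)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_asymmetric_in_inputs(self, rng):
        net = MfNet(seed=3)
        a, b = rng.normal(size=2), rng.normal(size=2)
        assert not np.allclose(mf_forward(net, a, b), mf_forward(net, b, a))

    def test_width_validated(self, rng):
        net = MfNet(seed=0)
        with pytest.raises(ValueError):
            mf_forward(net, rng.normal(size=3), rng.normal(size=2))


class TestMetricsHelpers:
    def test_f1_worked_example(self):
        # TP=3, FP=1, FN=1, TN=5 → F1 = 0.75, accuracy = 0.8
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        acc, f1 = accuracy_f1(pred, truth)
        assert acc == pytest.approx(0.8)
        assert f1 == pytest.approx(0.75)

    def test_perfect(self):
        y = np.array([0, 1, 1, 0])
        assert accuracy_f1(y, y) == (1.0, 1.0)

    def test_random_predictions_near_chance(self, rng):
        accs = []
        for _ in range(5):
            truth = rng.integers(0, 2, 2000)
            pred = rng.integers(0, 2, 2000)
            accs.append(accuracy_f1(pred, truth)[0])
        assert abs(np.mean(accs) - 0.5) < 0.05


@pytest.fixture(scope="module")
def trained(small_corpus, tmp_path_factory):
    ckpt = tmp_path_factory.mktemp("ckpt")
    cfg = TrainConfig(
        base_channels=2,
        epochs_sfe=1,
        epochs_sie=2,
        epochs_mf_warmup=2,
        epochs_joint=1,
        augment=False,
        seed=0,
    )
    model, report = train_stagewise(small_corpus, cfg, checkpoint_dir=ckpt)
    return model, report, ckpt


class TestTrainStagewise:

    def test_checkpoints_exist(self, trained):
        _, _, ckpt = trained
        for stage in ("stage1", "stage2", "stage3"):
            assert (ckpt / f"{stage}.npz").exists()

    def test_stage3_changes_every_module_group(self, trained):
        _, _, ckpt = trained
        s2 = np.load(ckpt / "stage2.npz")
        s3 = np.load(ckpt / "stage3.npz")
        changed = {}
        for key in s2.files:
            group = key.split(".", 1)[0]
            if key.startswith("morpho"):
                continue
            if not np.array_equal(s2[key], s3[key]):
                changed[group] = True
        assert set(changed) == {"sfe_image", "sfe_auto", "sie_image", "sie_auto", "mf"}

    def test_report_carries_histories(self, trained):
        _, report, _ = trained
        assert len(report["stage1_loss_image"]) == 1
        assert len(report["stage2_loss"]) == 2
        assert len(report["stage3_loss"]) == 1

    def test_loss_decreases_on_separable_morphometrics(self, small_corpus):
        from neurotdb.ssm import _Prepared, _train_classifier

        prep = _Prepared.from_blocks(small_corpus)
        model = SsmModel(image_config=SfeImageConfig(base_channels=2), seed=0)
        model.fit_standardization(prep.morpho)
        history = []
        _train_classifier(
            model.sfe_auto,
            model.standardize(prep.morpho),
            prep.labels,
            TrainConfig(),
            20,
            np.random.default_rng(0),
            history,
        )
        assert np.mean(history[-5:]) < np.mean(history[:5])

    def test_unlabeled_corpus_rejected(self, small_corpus):
        blocks = [dataclasses.replace(small_corpus[0], label=None)]
        with pytest.raises(ValueError):
            train_stagewise(blocks, TrainConfig(base_channels=2, epochs_sfe=1))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_stagewise([], TrainConfig())


class TestEvaluate:
    def test_split_leakage_rejected(self, small_corpus):
        with pytest.raises(ValueError, match="leakage"):
            evaluate(small_corpus, small_corpus, TrainConfig(), runs=1)

    def test_model_state_roundtrip(self, small_corpus, tmp_path):
        cfg = TrainConfig(
            base_channels=2, epochs_sfe=1, epochs_sie=1, epochs_mf_warmup=1,
            epochs_joint=1, augment=False, seed=3,
        )
        model, _ = train_stagewise(small_corpus[:8], cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = SsmModel(image_config=SfeImageConfig(base_channels=2), seed=99)
        clone.load(path)
        x = np.random.default_rng(0).random((32, 64, 64))
        np.testing.assert_array_equal(
            sfe_image_forward(model.sfe_image, x), sfe_image_forward(clone.sfe_image, x)
        )
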