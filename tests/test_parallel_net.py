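import numpy as np
import pytest

import hep2al as h
from hep2al.parallel_net import (EarlyStopping, ParallelWaveletNetClassifier,
                                 cross_entropy, softmax)
from hep2al.synthetic_data import SynthSpec, TARGET_CLASSES, generate
from tests.conftest import SMALL_SIDE


TINY = dict(input_side=16, stem_channels=4, branch_channels=4,
            batch_size=16, learning_rate=2e-3)


def _tiny_cfg(**kw):
    base = dict(num_classes=6, **TINY, patience=5, max_epochs=3, seed=0)
    base.update(kw)
    return h.NetConfig(**base)


def _planes(ds):
    a, d = h.batch_decompose(ds)
    return a, d, ds.label_indices()


class TestArchitecture:
    def test_printed_shape_contract(self):
        """112x112 image -> 56x56 planes -> 128-channel concat at 14x14 ->
        128-long GAP vector; five residual blocks."""
        model = h.build_model(h.NetConfig(num_classes=5))
        img = np.random.default_rng(0).random((112, 112)).astype(np.float32)
        pair = h.dwt_decompose(img)
        cap = {}
        logits = model.forward(pair.A[None], pair.D[None], capture=cap)
        assert cap["concat"].shape == (1, 128, 14, 14)
        assert cap["gap"].shape == (1, 128)
        assert logits.shape == (1, 5)
        assert model.residual_block_count() == 5

    def test_residual_block_composition(self):
        from hep2al.nn import BatchNorm2d, Conv2d, ReLU
        block = h.build_model(_tiny_cfg()).branches["a"]["block1"]
        subs = [block.conv1, block.bn1, block.relu1, block.conv2, block.bn2,
                block.relu2]
        assert sum(isinstance(s, Conv2d) for s in subs) == 2
        assert sum(isinstance(s, BatchNorm2d) for s in subs) == 2
        assert sum(isinstance(s, ReLU) for s in subs) == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            h.NetConfig(num_classes=1)
        with pytest.raises(ValueError):
            h.NetConfig(num_classes=3, learning_rate=0)
        with pytest.raises(ValueError):
            h.NetConfig(num_classes=3, patience=0)
        with pytest.raises(ValueError):
            h.NetConfig(num_classes=3, fused_channels=64, branch_channels=64)

    def test_shape_mismatch_rejected(self):
        model = h.build_model(_tiny_cfg())
        bad = np.zeros((1, 20, 20), dtype=np.float32)
        with pytest.raises(ValueError, match="side"):
            model.forward(bad, bad)


class TestSoftmaxAndLoss:
    def test_equal_logits_give_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(5)), 0.2, atol=1e-12)

    def test_rows_sum_to_one(self):
        z = np.random.default_rng(1).normal(size=(7, 6)) * 10
        np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-6)

    def test_extreme_logits_do_not_overflow(self):
        p = softmax(np.array([1000.0, 0.0, 0.0]))
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p, [1.0, 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("probs,label,expected", [
        ((1.0, 0.0), 0, 0.0),
        ((0.5, 0.5), 0, np.log(2)),
        ((0.7, 0.2, 0.1), 1, 1.6094),
    ])
    def test_cross_entropy_closed_forms(self, probs, label, expected):
        assert cross_entropy(np.array(probs), label) == pytest.approx(expected, abs=1e-4)

    def test_zero_probability_clamped_finite(self):
        loss = cross_entropy(np.array([0.0, 1.0]), 0)
        assert np.isfinite(loss) and loss > 20  # -ln(1e-12) ~ 27.6


class TestEarlyStopping:
    def test_hand_simulated_sequence(self):
        """Losses [1.0,.9,.8,.81,...,.85] with patience 5: the minimum is at
        epoch 3 and five straight non-improvements end training at epoch 8."""
        stopper = EarlyStopping(patience=5)
        stops = [stopper.update(v) for v in [1.0, .9, .8, .81, .82, .83, .84, .85]]
        assert stops == [False] * 7 + [True]
        assert stopper.epoch == 8 and stopper.best_epoch == 3

    def test_improvement_resets_the_streak(self):
        stopper = EarlyStopping(patience=2)
        assert [stopper.update(v) for v in [1.0, 1.1, 0.9, 1.0, 1.1]] == \
            [False, False, False, False, True]
        assert stopper.best_epoch == 3


@pytest.fixture(scope="module")
def tiny_data(tiny_target):
    a, d, y = _planes(tiny_target)
    return ((a[:36], d[:36]), y[:36]), ((a[36:], d[36:]), y[36:])


class TestTraining:
    def test_seeded_training_is_reproducible(self, tiny_data):
        tr, va = tiny_data
        runs = []
        for _ in range(2):
            model = h.build_model(_tiny_cfg(max_epochs=3))
            model, hist = h.train(model, tr, va, _tiny_cfg(max_epochs=3))
            runs.append((hist, model.state_dict()))
        assert runs[0][0].val_loss == runs[1][0].val_loss
        assert runs[0][0].train_loss == runs[1][0].train_loss
        for k in runs[0][1]:
            np.testing.assert_array_equal(runs[0][1][k], runs[1][1][k])

    def test_all_frozen_leaves_weights_untouched(self, tiny_data):
        tr, va = tiny_data
        model = h.build_model(_tiny_cfg())
        model.set_trainable({n: False for n in model.segment_names()})
        before = model.state_dict()
        model, hist = h.train(model, tr, va, _tiny_cfg())
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k], err_msg=k)

    def test_empty_train_set_rejected(self, tiny_data):
        _, va = tiny_data
        model = h.build_model(_tiny_cfg())
        empty = ((np.zeros((0, 16, 16), np.float32),) * 2, np.zeros(0, np.int64))
        with pytest.raises(ValueError, match="empty"):
            h.train(model, empty, va, _tiny_cfg())

    def test_best_epoch_weights_are_restored(self, tiny_data):
        tr, va = tiny_data
        cfg = _tiny_cfg(max_epochs=6, patience=2)
        model = h.build_model(cfg)
        model, hist = h.train(model, tr, va, cfg)
        assert hist.stopped_epoch >= hist.best_epoch
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)

    def test_overfits_a_small_sample(self):
        """On 32 images the network memorises the training set."""
        spec = SynthSpec(classes=tuple((n, n, 8) for n in TARGET_CLASSES[:4]),
                         image_side=SMALL_SIDE, seed=21, id_prefix="ov")
        ds = generate(spec)
        a, d, y = _planes(ds)
        cfg = h.NetConfig(num_classes=4, **TINY, patience=200,
                          max_epochs=200, seed=1)
        model = h.build_model(cfg)
        model, hist = h.train(model, ((a, d), y), ((a, d), y), cfg)
        assert max(hist.train_acc) >= 0.95

    def test_checkpoint_roundtrip_bit_exact(self, tiny_data, tmp_path):
        tr, va = tiny_data
        cfg = _tiny_cfg(max_epochs=2)
        model = h.build_model(cfg)
        model, _ = h.train(model, tr, va, cfg)
        model.class_names = list(TARGET_CLASSES)
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        loaded = h.ParallelNet.load(path)
        assert loaded.class_names == list(TARGET_CLASSES)
        assert loaded.cfg == model.cfg
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, loaded.state_dict()[k], err_msg=k)
        (A, D), yy = va
        np.testing.assert_array_equal(model.forward(A, D), loaded.forward(A, D))


class TestSklearnEstimator:
    def test_fit_predict_interface(self, tiny_target):
        X = tiny_target.pixels_array()
        y = np.array([im.label for im in tiny_target.items])
        clf = ParallelWaveletNetClassifier(branch_channels=4, batch_size=16,
                                           max_epochs=2, random_state=0)
        clf.fit(X, y)
        probs = clf.predict_proba(X)
        assert probs.shape == (len(y), 6)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(clf.predict(X)) <= set(clf.classes_)

    def test_get_set_params_roundtrip(self):
        clf = ParallelWaveletNetClassifier(branch_channels=8)
        params = clf.get_params()
        assert params["branch_channels"] == 8
        clf.set_params(branch_channels=2)
        assert clf.branch_channels == 2

    def test_single_class_rejected(self):
        clf = ParallelWaveletNetClassifier(max_epochs=1)
        X = np.random.default_rng(0).random((8, 16, 16)).astype(np.float32)
        with pytest.raises(ValueError, match="classes"):
            clf.fit(X, np.zeros(8))
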