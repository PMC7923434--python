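import numpy as np
import pytest

import hep2al as h
from hep2al.transfer import (TransferPlan, apply_transfer_plan, fine_tune,
                             pretrain, split_validation)

TINY = dict(input_side=16, stem_channels=4, branch_channels=4,
            batch_size=16, learning_rate=2e-3, patience=5)


def _cfg(num_classes, **kw):
    base = dict(num_classes=num_classes, **TINY, max_epochs=2, seed=0)
    base.update(kw)
    return h.NetConfig(**base)


@pytest.fixture(scope="module")
def pretrained(tiny_source):
    model, hist = pretrain(tiny_source, _cfg(5))
    return model


class TestPretrain:
    def test_head_matches_source_class_count(self, pretrained):
        assert pretrained.head_size == 5
        assert pretrained.class_names is not None and len(pretrained.class_names) == 5

    def test_single_class_source_rejected(self, tiny_source):
        one = tiny_source.subset([i for i in tiny_source.ids()
                                  if i.startswith("ts_homogeneous")])
        one = h.Dataset(items=one.items, class_names=["homogeneous"])
        with pytest.raises(ValueError, match="2 classes"):
            pretrain(one, _cfg(2))

    def test_seeded_pretrain_reproducible(self, tiny_source):
        m1, h1 = pretrain(tiny_source, _cfg(5))
        m2, h2 = pretrain(tiny_source, _cfg(5))
        assert h1.val_loss == h2.val_loss
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k], err_msg=k)


class TestTransferPlan:
    def test_head_swap_preserves_every_other_tensor(self, pretrained):
        model = h.ParallelNet(pretrained.cfg)
        model.load_state_dict(pretrained.state_dict())
        before = model.state_dict()
        model = apply_transfer_plan(model, TransferPlan(new_head_size=6))
        assert model.head_size == 6
        after = model.state_dict()
        for k, v in before.items():
            if not k.startswith("head."):
                np.testing.assert_array_equal(v, after[k], err_msg=k)

    def test_plan_partitions_parameters(self, pretrained):
        model = h.ParallelNet(pretrained.cfg)
        model.load_state_dict(pretrained.state_dict())
        model = apply_transfer_plan(model, TransferPlan(new_head_size=6))
        frozen = [n for n in model.segment_names() if not model.trainable[n]]
        trainable = [n for n in model.segment_names() if model.trainable[n]]
        assert {"a.stem", "a.pool1", "a.block1", "a.pool2",
                "d.stem", "d.pool1", "d.block1", "d.pool2"} == set(frozen)
        assert {"a.block2", "d.block2", "fusion", "post_block", "gap",
                "head"} == set(trainable)
        assert len(model.parameters(trainable_only=True)) > 0
        n_frozen = len(model.parameters()) - len(model.parameters(trainable_only=True))
        assert n_frozen > 0

    def test_unknown_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            TransferPlan(freeze_through="nowhere").frozen_segments()

    def test_head_size_validated(self):
        with pytest.raises(ValueError):
            TransferPlan(new_head_size=1)


class TestFineTune:
    def test_frozen_tensors_bit_identical_after_fine_tune(self, pretrained,
                                                          tiny_target):
        model = h.ParallelNet(pretrained.cfg)
        model.load_state_dict(pretrained.state_dict())
        model = apply_transfer_plan(model, TransferPlan(new_head_size=6))
        before = model.state_dict()
        model, hist = fine_tune(model, tiny_target, _cfg(6, max_epochs=2))
        after = model.state_dict()
        frozen_prefixes = tuple(f"{br}.{seg}" for br in ("a", "d")
                                for seg in ("stem", "pool1", "block1", "pool2"))
        changed = 0
        for k in before:
            if k.startswith(frozen_prefixes):
                np.testing.assert_array_equal(before[k], after[k], err_msg=k)
            elif not np.array_equal(before[k], after[k]):
                changed += 1
        assert changed > 0  # the trainable span actually moved

    def test_all_frozen_rejected(self, pretrained):
        model = h.ParallelNet(pretrained.cfg)
        model.load_state_dict(pretrained.state_dict())
        model.set_trainable({n: False for n in model.segment_names()})
        with pytest.raises(ValueError, match="trainable"):
            fine_tune(model, None, _cfg(5))

    def test_small_labeled_set_warns_and_shrinks_batch(self, pretrained,
                                                       tiny_target):
        model = h.ParallelNet(pretrained.cfg)
        model.load_state_dict(pretrained.state_dict())
        model = apply_transfer_plan(model, TransferPlan(new_head_size=6))
        small = tiny_target.subset(tiny_target.ids()[:12])
        with pytest.warns(UserWarning, match="batch"):
            fine_tune(model, small, _cfg(6, batch_size=64, max_epochs=1))

    def test_seeded_fine_tune_reproducible(self, pretrained, tiny_target):
        hists = []
        for _ in range(2):
            model = h.ParallelNet(pretrained.cfg)
            model.load_state_dict(pretrained.state_dict())
            model = apply_transfer_plan(model, TransferPlan(new_head_size=6))
            _, hist = fine_tune(model, tiny_target, _cfg(6, max_epochs=2))
            hists.append(hist)
        assert hists[0].val_loss == hists[1].val_loss


def test_split_validation_arithmetic():
    tr, va = split_validation(1500, 0.1, seed=0)
    assert len(tr) == 1350 and len(va) == 150
    assert sorted(np.concatenate([tr, va])) == list(range(1500))
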