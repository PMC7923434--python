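"""Cross-modal transfer learning: pretrain, freeze, swap head, fine-tune.

The networks are first trained on a small labeled source corpus from the
same imaging domain.  For every subsequent fine-tuning on the target
corpus, all layers strictly before each branch's second residual block —
from the first convolution through the second pooling — are frozen: they
carry generic low-level features shared by the two domains.  The second
residual blocks, the fusion convolution, the post-fusion block and a
freshly initialised classification head (sized to the target's class
count) remain trainable.

Frozen batch-normalization layers run on their stored running statistics
during fine-tuning, so a frozen segment is bit-invariant end to end.
Early stopping during fine-tuning monitors a seeded carve-out of the
labeled pool, never the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_pipeline import Dataset
from .parallel_net import (NetConfig, ParallelNet, TrainHistory,
                           build_model, train)
from .wavelet_frontend import DEFAULT_WAVELET, batch_decompose


@dataclass
class TransferPlan:
    """What to freeze and how to re-head the pretrained network.

    ``freeze_through`` names the last frozen branch segment (inclusive);
    the default freezes everything strictly before the second residual
    block.  ``freeze_bn_stats`` keeps frozen batch-norm layers in
    inference mode so their running statistics never drift.
    """

    freeze_through: str = "pool2"
    new_head_size: int = 6
    freeze_bn_stats: bool = True
    head_seed: int = 0

    def frozen_segments(self) -> list[str]:
        from .parallel_net import BRANCH_SEGMENTS
        if self.freeze_through not in BRANCH_SEGMENTS:
            raise ValueError(f"freeze boundary {self.freeze_through!r} not found; "
                             f"branch segments: {BRANCH_SEGMENTS}")
        upto = BRANCH_SEGMENTS.index(self.freeze_through) + 1
        return [f"{br}.{seg}" for br in ("a", "d")
                for seg in BRANCH_SEGMENTS[:upto]]

    def __post_init__(self):
        if self.new_head_size < 2:
            raise ValueError("new_head_size must be >= 2")


def split_validation(n: int, val_fraction: float, seed: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded (train_idx, val_idx) split; val gets round(val_fraction*n)."""
    n_val = int(round(val_fraction * n))
    n_val = max(1, min(n - 1, n_val))
    perm = np.random.default_rng(seed).permutation(n)
    return perm[n_val:], perm[:n_val]


def _planes(ds: Dataset, wavelet: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, d = batch_decompose(ds, wavelet)
    return a, d, ds.label_indices()


def pretrain(source_set: Dataset, cfg: NetConfig, *,
             wavelet: str = DEFAULT_WAVELET, val_fraction: float = 0.1
             ) -> tuple[ParallelNet, TrainHistory]:
    """Train a fresh, fully trainable network on the labeled source corpus.

    The head is sized to the number of source classes.  Returns the model
    (best-epoch weights restored) and its training history.
    """
    if len(source_set.class_names) < 2:
        raise ValueError("source dataset must contain at least 2 classes")
    y = source_set.label_indices()
    if (y < 0).any():
        raise ValueError("source dataset must be fully labeled")
    a, d, y = _planes(source_set, wavelet)
    if cfg.num_classes != len(source_set.class_names):
        raise ValueError(f"cfg.num_classes={cfg.num_classes} but source has "
                         f"{len(source_set.class_names)} classes")
    tr, va = split_validation(len(y), val_fraction, cfg.seed)
    model = build_model(cfg)
    model.class_names = list(source_set.class_names)
    model, hist = train(model, ((a[tr], d[tr]), y[tr]), ((a[va], d[va]), y[va]), cfg)
    return model, hist


def apply_transfer_plan(model: ParallelNet, plan: TransferPlan) -> ParallelNet:
    """Freeze the early layers and install a fresh classification head.

    Modifies ``model`` in place and returns it.  All non-head weights are
    retained bit-exactly.
    """
    frozen = set(plan.frozen_segments())
    flags = {name: name not in frozen for name in model.segment_names()}
    model.set_trainable(flags)
    model.freeze_bn_stats = plan.freeze_bn_stats
    rng = np.random.default_rng(plan.head_seed)
    model.replace_head(plan.new_head_size, rng)
    model.class_names = None  # target class names attach at fine-tune time
    return model


def fine_tune(model: ParallelNet, labeled_set: Dataset, cfg: NetConfig, *,
              wavelet: str = DEFAULT_WAVELET, val_fraction: float = 0.1,
              monitor_set: Dataset | None = None
              ) -> tuple[ParallelNet, TrainHistory]:
    """Fine-tune the trainable layers on the labeled pool.

    Early stopping monitors either ``monitor_set`` or, by default, a
    seeded ``val_fraction`` carve-out of ``labeled_set``.
    """
    if not model.parameters(trainable_only=True):
        raise ValueError("no trainable layers: nothing to optimize")
    a, d, y = _planes(labeled_set, wavelet)
    if (y < 0).any():
        raise ValueError("labeled_set contains unlabeled images")
    if len(y) < cfg.batch_size:
        warnings.warn(f"labeled set ({len(y)}) smaller than batch size "
                      f"({cfg.batch_size}); shrinking batch", stacklevel=2)
    if monitor_set is not None:
        av, dv, yv = _planes(monitor_set, wavelet)
        tr_data, va_data = ((a, d), y), ((av, dv), yv)
    else:
        tr, va = split_validation(len(y), val_fraction, cfg.seed)
        tr_data = ((a[tr], d[tr]), y[tr])
        va_data = ((a[va], d[va]), y[va])
    model.class_names = list(labeled_set.class_names)
    return train(model, tr_data, va_data, cfg)
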