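"""The two-branch parallel residual network and its training loop.

Architecture (per branch, operating on one 56x56 coefficient plane):
stem convolution -> max pool (56->28) -> residual block -> max pool
(28->14) -> residual block.  The two branch outputs are concatenated
along channels, fused by a 1x1 convolution, passed through a final
residual block, global-average-pooled into a feature vector, and
classified by a fully connected softmax head.  Five residual blocks in
total (two per branch plus one after fusion); every convolution preserves
spatial dimensions and only the pooling layers downsample.

Training minimises the softmax cross-entropy with Adam, stopping early
when the validation loss fails to improve its running minimum a fixed
number of consecutive epochs, and restoring the best epoch's weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import (Adam, BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d,
                 ReLU, ResidualBlock, Sequential)
from .nn.losses import PROB_EPS, cross_entropy_batch, one_hot
from .nn.losses import softmax as _softmax
from .wavelet_frontend import DEFAULT_WAVELET, batch_decompose

BRANCH_SEGMENTS = ("stem", "pool1", "block1", "pool2", "block2")
TRUNK_SEGMENTS = ("fusion", "post_block", "gap", "head")

#: Freezing span used for cross-modal fine-tuning: everything strictly
#: before each branch's second residual block.
DEFAULT_FREEZE = ("stem", "pool1", "block1", "pool2")


@dataclass
class NetConfig:
    """Hyperparameters of the network and its training loop.

    ``input_side`` is the side of one coefficient plane (half the image
    side).  ``fused_channels`` must equal twice the branch channels, the
    width of the concatenated volume.
    """

    num_classes: int
    input_side: int = 56
    stem_channels: int = 64
    branch_channels: int = 64
    fused_channels: int | None = None
    kernel_size: int = 3
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 5
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.fused_channels is None:
            self.fused_channels = 2 * self.branch_channels
        if self.fused_channels != 2 * self.branch_channels:
            raise ValueError("fused_channels must be 2x branch_channels")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.input_side % 4:
            raise ValueError("input_side must be divisible by 4 (two poolings)")


@dataclass
class TrainHistory:
    """Per-epoch metrics plus the early-stopping outcome (1-indexed epochs)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss, "train_acc": self.train_acc,
            "val_loss": self.val_loss, "val_acc": self.val_acc,
        }).to_csv(path, index=False)


class EarlyStopping:
    """Stop when the monitored loss fails to beat its running minimum
    ``patience`` times in a row; remembers the best (minimum-loss) epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.streak = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; return True if training should stop."""
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
            self.streak = 0
        else:
            self.streak += 1
        return self.streak >= self.patience


class ParallelNet:
    """The two-branch residual network with per-segment trainable flags.

    Segments are addressed as ``a.stem`` ... ``a.block2`` and ``d.stem``
    ... ``d.block2`` for the approximation and detail branches, plus the
    shared trunk ``fusion``, ``post_block``, ``gap`` and ``head``.
    """

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w, fused, k = cfg.branch_channels, cfg.fused_channels, cfg.kernel_size
        self.branches: dict[str, dict[str, object]] = {}
        for br in ("a", "d"):
            self.branches[br] = {
                "stem": Sequential([Conv2d(1, cfg.stem_channels, k, rng=rng),
                                    BatchNorm2d(cfg.stem_channels), ReLU()]),
                "pool1": MaxPool2d(),
                "block1": ResidualBlock(w, k, rng=rng),
                "pool2": MaxPool2d(),
                "block2": ResidualBlock(w, k, rng=rng),
            }
            if cfg.stem_channels != w:
                raise ValueError("stem_channels must equal branch_channels "
                                 "(identity shortcuts only)")
        self.trunk: dict[str, object] = {
            "fusion": Sequential([Conv2d(fused, fused, 1, rng=rng),
                                  BatchNorm2d(fused), ReLU()]),
            "post_block": ResidualBlock(fused, k, rng=rng),
            "gap": GlobalAvgPool(),
            "head": Linear(fused, cfg.num_classes, rng=rng, init_std=0.01),
        }
        self.trainable: dict[str, bool] = {name: True for name in self.segment_names()}
        self.freeze_bn_stats = True  # frozen BN layers run in inference mode
        self.class_names: list[str] | None = None

    # ---- structure ----------------------------------------------------
    def segment_names(self) -> list[str]:
        return ([f"{br}.{seg}" for br in ("a", "d") for seg in BRANCH_SEGMENTS]
                + list(TRUNK_SEGMENTS))

    def _segment(self, name: str):
        if "." in name:
            br, seg = name.split(".", 1)
            return self.branches[br][seg]
        return self.trunk[name]

    @property
    def head_size(self) -> int:
        return self.trunk["head"].out_features

    def residual_block_count(self) -> int:
        return sum(isinstance(self._segment(n), ResidualBlock)
                   for n in self.segment_names())

    def parameters(self, trainable_only: bool = False):
        out = []
        for name in self.segment_names():
            if trainable_only and not self.trainable[name]:
                continue
            out.extend(self._segment(name).params())
        return out

    def set_trainable(self, flags: dict[str, bool]) -> None:
        for name, val in flags.items():
            if name not in self.trainable:
                raise KeyError(f"unknown segment {name!r}")
            self.trainable[name] = bool(val)

    # ---- forward / backward -------------------------------------------
    def _seg_train_mode(self, name: str, train: bool) -> bool:
        if not train:
            return False
        if self.freeze_bn_stats and not self.trainable[name]:
            return False  # frozen batch norm runs on its running statistics
        return train

    def forward(self, A: np.ndarray, D: np.ndarray, train: bool = False,
                capture: dict | None = None) -> np.ndarray:
        """Forward a batch of coefficient-plane pairs to logits.

        ``A`` and ``D`` are ``(B, side, side)`` or ``(B, 1, side, side)``
        arrays.  When ``capture`` is a dict it receives the intermediate
        ``concat`` volume and ``gap`` feature vector.
        """
        def prep(x):
            x = np.asarray(x, dtype=np.float32)
            if x.ndim == 3:
                x = x[:, None, :, :]
            if x.shape[2] != self.cfg.input_side:
                raise ValueError(f"expected plane side {self.cfg.input_side}, "
                                 f"got {x.shape[2]}")
            return x

        outs = {}
        for br, x in (("a", prep(A)), ("d", prep(D))):
            for seg in BRANCH_SEGMENTS:
                name = f"{br}.{seg}"
                x = self.branches[br][seg].forward(x, train=self._seg_train_mode(name, train))
            outs[br] = x
        x = np.concatenate([outs["a"], outs["d"]], axis=1)
        self._concat_channels = outs["a"].shape[1]
        if capture is not None:
            capture["concat"] = x
        for seg in TRUNK_SEGMENTS:
            x = self.trunk[seg].forward(x, train=self._seg_train_mode(seg, train))
            if capture is not None and seg == "gap":
                capture["gap"] = x
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.astype(np.float32)
        for seg in reversed(TRUNK_SEGMENTS):
            g = self.trunk[seg].backward(g)
        ga, gd = g[:, :self._concat_channels], g[:, self._concat_channels:]
        for br, gb in (("a", ga), ("d", gd)):
            # skip backprop below the lowest trainable segment of the branch
            names = [f"{br}.{seg}" for seg in BRANCH_SEGMENTS]
            lowest = next((i for i, n in enumerate(names) if self.trainable[n]
                           and self._segment(n).params()), len(names))
            for i in range(len(BRANCH_SEGMENTS) - 1, lowest - 1, -1):
                gb = self.branches[br][BRANCH_SEGMENTS[i]].backward(gb)

    # ---- state --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name in self.segment_names():
            for key, arr in self._segment(name).arrays().items():
                out[f"{name}.{key}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in self.segment_names():
            prefix = name + "."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            if sub:
                self._segment(name).load_arrays(sub)

    def replace_head(self, new_size: int, rng: np.random.Generator) -> None:
        """Swap the classification head for a fresh one of ``new_size``
        outputs; every other tensor is untouched."""
        if new_size < 2:
            raise ValueError("head must have at least 2 outputs")
        self.trunk["head"] = Linear(self.cfg.fused_channels, new_size,
                                    rng=rng, init_std=0.01)
        self.cfg = NetConfig(**{**asdict(self.cfg), "num_classes": new_size})

    # ---- persistence ---------------------------------------------------
    def save(self, path: str) -> None:
        meta = {"config": asdict(self.cfg), "trainable": self.trainable,
                "freeze_bn_stats": self.freeze_bn_stats,
                "class_names": self.class_names, "format_version": 1}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "ParallelNet":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if k != "__meta__"}
        model = cls(NetConfig(**meta["config"]))
        if model.head_size != meta["config"]["num_classes"]:  # pragma: no cover
            raise ValueError("checkpoint head mismatch")
        model.load_state_dict(state)
        model.trainable = dict(meta["trainable"])
        model.freeze_bn_stats = bool(meta["freeze_bn_stats"])
        model.class_names = meta["class_names"]
        return model


def build_model(cfg: NetConfig) -> ParallelNet:
    """Construct the parallel network for the given configuration."""
    return ParallelNet(cfg)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Class probabilities from logits (row-wise, overflow-safe)."""
    return _softmax(logits)


def cross_entropy(probs: np.ndarray, true_label) -> float:
    """Cross-entropy −Σ_j y_j ln σ(z)_j with a one-hot target.

    Accepts one probability vector with an integer label, or a batch with
    a label array (returning the mean).  Probabilities are clamped at
    ``1e-12`` so an exactly-zero true-class probability yields a large
    finite loss rather than infinity.
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 1:
        return float(-np.log(max(p[int(true_label)], PROB_EPS)))
    return cross_entropy_batch(p, np.asarray(true_label))


def _iter_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _eval_pass(model: ParallelNet, A, D, y, batch_size: int) -> tuple[float, float]:
    total_loss, correct = 0.0, 0
    for start in range(0, len(y), batch_size):
        sl = slice(start, start + batch_size)
        probs = softmax(model.forward(A[sl], D[sl], train=False))
        total_loss += cross_entropy_batch(probs, y[sl]) * len(y[sl])
        correct += int((probs.argmax(axis=1) == y[sl]).sum())
    n = len(y)
    return total_loss / n, correct / n


def train(model: ParallelNet, train_data, val_data, cfg: NetConfig
          ) -> tuple[ParallelNet, TrainHistory]:
    """Train with Adam and patience-based early stopping.

    ``train_data`` and ``val_data`` are ``((A, D), y)`` tuples of
    coefficient-plane stacks and integer labels.  Only segments whose
    trainable flag is set are updated; on stop, the weights of the best
    (minimum validation loss) epoch are restored.
    """
    (At, Dt), yt = train_data
    (Av, Dv), yv = val_data
    if len(yt) == 0:
        raise ValueError("empty training set")
    if len(yv) == 0:
        raise ValueError("empty validation set")
    params = model.parameters(trainable_only=True)
    if not params:
        # nothing to optimise: return unchanged with an empty history
        hist = TrainHistory()
        vl, va = _eval_pass(model, Av, Dv, yv, cfg.batch_size)
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
        hist.stopped_epoch = hist.best_epoch = 0
        return model, hist

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(params, lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    hist = TrainHistory()
    best_state = None
    bs = min(cfg.batch_size, len(yt))
    n_classes = model.head_size

    for epoch in range(1, cfg.max_epochs + 1):
        ep_loss, ep_correct, seen = 0.0, 0, 0
        for idx in _iter_minibatches(len(yt), bs, rng):
            logits = model.forward(At[idx], Dt[idx], train=True)
            probs = softmax(logits)
            loss = cross_entropy_batch(probs, yt[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or inspect the inputs")
            dlogits = (probs - one_hot(yt[idx], n_classes)) / len(idx)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((probs.argmax(axis=1) == yt[idx]).sum())
            seen += len(idx)
        vl, va = _eval_pass(model, Av, Dv, yv, cfg.batch_size)
        hist.train_loss.append(ep_loss / seen)
        hist.train_acc.append(ep_correct / seen)
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
        stop = stopper.update(vl)
        if stopper.best_epoch == epoch:
            best_state = model.state_dict()
        if stop:
            break
    hist.stopped_epoch = stopper.epoch
    hist.best_epoch = stopper.best_epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, hist


def predict_proba(model: ParallelNet, A: np.ndarray, D: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Inference-mode class probabilities for a stack of plane pairs."""
    out = []
    for start in range(0, len(A), batch_size):
        sl = slice(start, start + batch_size)
        out.append(softmax(model.forward(A[sl], D[sl], train=False)))
    return np.concatenate(out, axis=0) if out else np.zeros((0, model.head_size))


class ParallelWaveletNetClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the wavelet front end + network.

    ``fit`` takes raw grayscale images ``X`` of shape ``(n, side, side)``
    with string or integer labels ``y``; it decomposes them to coefficient
    planes, carves out a seeded validation fraction for early stopping,
    and trains the parallel network.  ``predict_proba`` returns softmax
    class probabilities in ``classes_`` order.
    """

    def __init__(self, branch_channels: int = 64, kernel_size: int = 3,
                 batch_size: int = 128, learning_rate: float = 1e-3,
                 patience: int = 5, max_epochs: int = 200,
                 val_fraction: float = 0.1, wavelet: str = DEFAULT_WAVELET,
                 random_state: int = 0):
        self.branch_channels = branch_channels
        self.kernel_size = kernel_size
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.wavelet = wavelet
        self.random_state = random_state

    def _config(self, num_classes: int, input_side: int) -> NetConfig:
        return NetConfig(num_classes=num_classes, input_side=input_side,
                         stem_channels=self.branch_channels,
                         branch_channels=self.branch_channels,
                         kernel_size=self.kernel_size,
                         batch_size=self.batch_size,
                         learning_rate=self.learning_rate,
                         patience=self.patience, max_epochs=self.max_epochs,
                         seed=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes to fit a classifier")
        a, d = batch_decompose(X, self.wavelet)
        cfg = self._config(len(self.classes_), a.shape[1])
        rng = np.random.default_rng(self.random_state)
        n_val = max(1, int(round(self.val_fraction * len(y_idx))))
        perm = rng.permutation(len(y_idx))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("validation carve-out leaves no training data")
        self.model_ = build_model(cfg)
        self.model_.class_names = [str(c) for c in self.classes_]
        _, self.history_ = train(
            self.model_,
            ((a[tr_idx], d[tr_idx]), y_idx[tr_idx]),
            ((a[val_idx], d[val_idx]), y_idx[val_idx]), cfg)
        self.config_ = cfg
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        a, d = batch_decompose(np.asarray(X, dtype=np.float32), self.wavelet)
        return predict_proba(self.model_, a, d, batch_size=max(64, self.batch_size))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
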