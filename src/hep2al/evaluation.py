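"""Evaluation metrics and the four-case experiment harness.

Two headline metrics, reported as percentages:

* ACA (average classification accuracy) — correctly classified count
  divided by the total count; dominated by the majority classes.
* MCA (mean class accuracy) — the unweighted mean of the per-class
  accuracies; sensitive to minority-class performance.  Under class
  imbalance the two diverge, and closing that gap is exactly what
  uncertainty-driven annotation is meant to achieve.

The harness runs the four experiment arms: random sampling from scratch
(RS), active learning from scratch (AL), and both repeated on top of a
pretrained source model (IN-RS, IN-AL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .active_learning import al_loop, make_state
from .data_pipeline import Dataset
from .parallel_net import NetConfig, ParallelNet, predict_proba
from .transfer import TransferPlan, apply_transfer_plan, fine_tune, pretrain
from .wavelet_frontend import DEFAULT_WAVELET, batch_decompose

CASE_IDS = ("RS", "AL", "IN-RS", "IN-AL")


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, columns = predicted) plus accuracies.

    ``per_class_accuracy``, ``ACA`` and ``MCA`` are percentages; a class
    absent from the test set has NaN accuracy and is excluded from MCA
    (with a warning at construction time).
    """

    confusion: np.ndarray
    class_names: list[str]
    per_class_accuracy: np.ndarray = field(init=False)
    ACA: float = field(init=False)
    MCA: float = field(init=False)

    def __post_init__(self):
        cm = np.asarray(self.confusion, dtype=np.int64)
        if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
            raise ValueError("confusion matrix must be square")
        self.confusion = cm
        row = cm.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            acc = np.where(row > 0, cm.diagonal() / np.maximum(row, 1), np.nan)
        self.per_class_accuracy = 100.0 * acc
        self.ACA = 100.0 * cm.trace() / cm.sum()
        if (row == 0).any():
            absent = [self.class_names[i] for i in np.flatnonzero(row == 0)]
            warnings.warn(f"classes absent from the test set: {absent}; "
                          "MCA computed over present classes", stacklevel=2)
        self.MCA = float(np.nanmean(self.per_class_accuracy))

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {"class_names": self.class_names,
                "confusion": self.confusion.tolist(),
                "per_class_accuracy": [None if np.isnan(v) else round(float(v), 2)
                                       for v in self.per_class_accuracy],
                "ACA": round(float(self.ACA), 2), "MCA": round(float(self.MCA), 2)}

    def __str__(self) -> str:
        lines = [f"{'class':>18s}  accuracy"]
        for name, acc in zip(self.class_names, self.per_class_accuracy):
            lines.append(f"{name:>18s}  {acc:6.2f}%")
        lines.append(f"{'ACA':>18s}  {self.ACA:6.2f}%")
        lines.append(f"{'MCA':>18s}  {self.MCA:6.2f}%")
        return "\n".join(lines)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            class_names: list[str]) -> EvalReport:
    labels = np.arange(len(class_names))
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    return EvalReport(confusion=cm, class_names=list(class_names))


def evaluate(model: ParallelNet, test_set: Dataset, *,
             wavelet: str = DEFAULT_WAVELET) -> EvalReport:
    """Score a labeled test set: argmax prediction, ties to the lowest index."""
    if model.head_size != len(test_set.class_names):
        raise ValueError(f"model head ({model.head_size}) does not match test "
                         f"class count ({len(test_set.class_names)})")
    y = test_set.label_indices()
    if (y < 0).any():
        raise ValueError("test set must be fully labeled")
    a, d = batch_decompose(test_set, wavelet)
    probs = predict_proba(model, a, d)
    return report_from_predictions(y, probs.argmax(axis=1), test_set.class_names)


def budget_arithmetic(train_count: int, fraction: float) -> tuple[int, int, int]:
    """Budget, initial draw k (15% of budget) and round size m (10%)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    budget = int(round(fraction * train_count))
    if budget < 2:
        raise ValueError(f"budget {budget} too small to train on")
    return budget, int(round(0.15 * budget)), int(round(0.10 * budget))


@dataclass
class ExperimentCase:
    """One experiment arm at one labeling budget, over one or more seeds."""

    case_id: str
    budget_fraction: float
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.case_id not in CASE_IDS:
            raise ValueError(f"case_id must be one of {CASE_IDS}")
        if not 0 < self.budget_fraction <= 1:
            raise ValueError("budget_fraction must be in (0, 1]")


@dataclass
class CaseResult:
    case: ExperimentCase
    reports: list[EvalReport]
    selected_ids: list[list[str]]
    states: list = field(default_factory=list)  # ALState per seed (AL arms)
    per_round: list[list[EvalReport]] | None = None

    @property
    def mean_mca(self) -> float:
        return float(np.mean([r.MCA for r in self.reports]))

    @property
    def mean_aca(self) -> float:
        return float(np.mean([r.ACA for r in self.reports]))


def _scratch_model(cfg: NetConfig, class_names: list[str], seed: int) -> ParallelNet:
    mcfg = NetConfig(**{**cfg.__dict__, "num_classes": len(class_names), "seed": seed})
    model = ParallelNet(mcfg)
    model.class_names = list(class_names)
    return model, mcfg


def run_case(case: ExperimentCase, source_set: Dataset | None,
             target_train: Dataset, target_test: Dataset, cfg: NetConfig, *,
             wavelet: str = DEFAULT_WAVELET, measure: str = "entropy",
             pretrained: ParallelNet | None = None,
             k_frac: float = 0.15, m_frac: float = 0.10,
             round_max_epochs: int | None = None,
             per_round_eval: bool = False) -> CaseResult:
    """Execute one experiment arm.

    RS: draw the budget uniformly at random, train from scratch.
    AL: active-learning loop from scratch (no source pretraining).
    IN-RS / IN-AL: pretrain on ``source_set`` (or reuse ``pretrained``),
    freeze the early layers, re-head to the target classes, then fine-tune
    on the random draw / run the loop.

    Returns one report (and the annotated id list) per seed.
    """
    n_pool = len(target_train)
    budget, k, m = budget_arithmetic(n_pool, case.budget_fraction)
    if (k_frac, m_frac) != (0.15, 0.10):
        k = max(1, int(round(k_frac * budget)))
        m = max(1, int(round(m_frac * budget)))
    labels = {sid: target_train.by_id(sid).label for sid in target_train.ids()}
    oracle = labels.__getitem__
    needs_source = case.case_id.startswith("IN-")
    if needs_source and source_set is None and pretrained is None:
        raise ValueError(f"case {case.case_id} requires a source set or a "
                         "pretrained model")

    base_pretrained = pretrained
    if needs_source and base_pretrained is None:
        pre_cfg = NetConfig(**{**cfg.__dict__,
                               "num_classes": len(source_set.class_names),
                               "seed": cfg.seed})
        base_pretrained, _ = pretrain(source_set, pre_cfg, wavelet=wavelet)

    reports, selected, states, per_round_all = [], [], [], []
    for seed in case.seeds:
        seed_cfg = NetConfig(**{**cfg.__dict__,
                                "num_classes": len(target_train.class_names),
                                "seed": seed})
        if needs_source:
            model = ParallelNet(base_pretrained.cfg)
            model.load_state_dict(base_pretrained.state_dict())
            plan = TransferPlan(new_head_size=len(target_train.class_names),
                                head_seed=seed)
            model = apply_transfer_plan(model, plan)
        else:
            model, seed_cfg = _scratch_model(seed_cfg, target_train.class_names, seed)

        if case.case_id.endswith("RS"):
            rng = np.random.default_rng(seed)
            draw = [target_train.ids()[i] for i in
                    rng.choice(n_pool, size=budget, replace=False)]
            labeled = target_train.subset(draw)
            model, _ = fine_tune(model, labeled, seed_cfg, wavelet=wavelet)
            reports.append(evaluate(model, target_test, wavelet=wavelet))
            selected.append(draw)
        else:  # AL arms
            state = make_state(target_train, budget, k, m, seed=seed)
            model, state, rounds = al_loop(
                model, target_train, state, seed_cfg, oracle, measure=measure,
                wavelet=wavelet, round_max_epochs=round_max_epochs,
                test_set=target_test if per_round_eval else None)
            reports.append(evaluate(model, target_test, wavelet=wavelet))
            selected.append(list(state.labeled_ids))
            states.append(state)
            per_round_all.append(rounds)
    return CaseResult(case=case, reports=reports, selected_ids=selected,
                      states=states, per_round=per_round_all or None)
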