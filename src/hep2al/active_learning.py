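"""Pool-based active learning with uncertainty sampling.

The annotation loop: train an initial model on ``k`` randomly drawn pool
images; then repeatedly (i) score every still-unlabeled image with the
current model, (ii) rank by uncertainty, least confident first, (iii)
annotate the top ``m`` (truncated so the labeling budget is hit exactly),
and (iv) fine-tune on the full labeled set — until the budget is
exhausted.

Three uncertainty measures are provided.  Shannon entropy −Σ p ln p is
the default: it uses the whole probability vector and is the best suited
to multiclass problems.  Least confidence (the maximum class probability)
and the top-two margin use only one or two entries and rank identically
to entropy in the binary case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .data_pipeline import CellImage, Dataset
from .parallel_net import NetConfig, ParallelNet, predict_proba
from .wavelet_frontend import DEFAULT_WAVELET, batch_decompose

MEASURES = ("entropy", "least_confidence", "margin")


def _as_batch(probs: np.ndarray) -> tuple[np.ndarray, bool]:
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 1:
        return p[None, :], True
    return p, False


def entropy_uncertainty(probs: np.ndarray):
    """Shannon entropy −Σ_j p_j ln p_j (0·ln 0 := 0); higher = more uncertain.

    Bounded by [0, ln N], the maximum attained only at the uniform vector.
    """
    p, single = _as_batch(probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    return float(h[0]) if single else h


def least_confidence(probs: np.ndarray):
    """The model's confidence: max_j p_j.  LOWER = more uncertain."""
    p, single = _as_batch(probs)
    c = p.max(axis=1)
    return float(c[0]) if single else c


def margin(probs: np.ndarray):
    """Top-two margin p1 − p2.  LOWER = more uncertain."""
    p, single = _as_batch(probs)
    if p.shape[1] < 2:
        raise ValueError("margin requires at least 2 classes")
    part = np.partition(p, -2, axis=1)
    m = part[:, -1] - part[:, -2]
    return float(m[0]) if single else m


def score_batch(probs: np.ndarray, measure: str = "entropy") -> np.ndarray:
    if measure == "entropy":
        return entropy_uncertainty(probs)
    if measure == "least_confidence":
        return least_confidence(probs)
    if measure == "margin":
        return margin(probs)
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


@dataclass
class UncertaintyScore:
    sample_id: str
    measure: str
    value: float


def rank_for_annotation(scores: Sequence[UncertaintyScore]) -> list[str]:
    """Order sample ids least-confident-first.

    Entropy ranks descending (high entropy = uncertain); least confidence
    and margin rank ascending.  Ties break by ascending sample_id.
    """
    measures = {s.measure for s in scores}
    if len(measures) > 1:
        raise ValueError(f"mixed uncertainty measures in one ranking: {sorted(measures)}")
    if measures - set(MEASURES):
        raise ValueError(f"unknown measure {measures}")
    descending = measures == {"entropy"}
    key = (lambda s: (-s.value, s.sample_id)) if descending else \
          (lambda s: (s.value, s.sample_id))
    return [s.sample_id for s in sorted(scores, key=key)]


@dataclass
class ALState:
    """Labeled/unlabeled partition of the pool plus budget bookkeeping."""

    pool_ids: list[str]
    budget: int
    k: int
    m: int
    seed: int = 0
    labeled_ids: list[str] = field(default_factory=list)
    iteration: int = 0
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if self.budget > len(self.pool_ids):
            raise ValueError(f"budget {self.budget} exceeds pool size {len(self.pool_ids)}")
        if self.k > self.budget:
            raise ValueError("initial draw k cannot exceed the budget")
        if self.m < 1:
            raise ValueError("per-round draw m must be >= 1")

    @property
    def unlabeled_ids(self) -> list[str]:
        labeled = set(self.labeled_ids)
        return [s for s in self.pool_ids if s not in labeled]

    def check_invariants(self) -> None:
        labeled = set(self.labeled_ids)
        if len(labeled) != len(self.labeled_ids):
            raise AssertionError("an id was annotated twice")
        if not labeled <= set(self.pool_ids):
            raise AssertionError("labeled ids outside the pool")
        if len(labeled) > self.budget:
            raise AssertionError("budget exceeded")
        expected = min(self.k + self.iteration * self.m, self.budget)
        if self.labeled_ids and len(labeled) != expected:
            raise AssertionError(
                f"labeled count {len(labeled)} != min(k + i*m, budget) = {expected}")

    def to_json(self) -> str:
        import json
        return json.dumps({
            "pool_ids": self.pool_ids, "budget": self.budget, "k": self.k,
            "m": self.m, "seed": self.seed, "labeled_ids": self.labeled_ids,
            "iteration": self.iteration, "audit": self.audit})

    @classmethod
    def from_json(cls, payload: str) -> "ALState":
        import json
        return cls(**json.loads(payload))

    def audit_csv(self, path: str) -> None:
        """Round-by-round annotation log: one row per purchased label."""
        with open(path, "w") as fh:
            fh.write("round,selected_id,measure,score,labeled_total\n")
            for row in self.audit:
                score = "" if row["score"] is None else f"{row['score']:.6f}"
                fh.write(f"{row['round']},{row['selected_id']},"
                         f"{row['measure']},{score},{row['labeled_total']}\n")

    def annotate(self, ids: Iterable[str], round_no: int, measure: str,
                 score_of: dict[str, float] | None = None) -> None:
        labeled = set(self.labeled_ids)
        for s in ids:
            if s in labeled:
                raise AssertionError(f"id {s} queried twice")
            self.labeled_ids.append(s)
            labeled.add(s)
            self.audit.append({
                "round": round_no, "selected_id": s, "measure": measure,
                "score": None if score_of is None else score_of.get(s),
                "labeled_total": len(self.labeled_ids)})


def selection_schedule(budget: int, k: int, m: int) -> list[int]:
    """Per-event annotation counts: the initial draw of ``k`` followed by
    rounds of ``m``, the last truncated so the total equals the budget."""
    if k > budget:
        raise ValueError("k cannot exceed budget")
    counts = [k]
    remaining = budget - k
    while remaining > 0:
        take = min(m, remaining)
        counts.append(take)
        remaining -= take
    return counts


def run_selection_loop(state: ALState, *,
                       score_ids: Callable[[list[str]], np.ndarray],
                       fit_on_labeled: Callable[[list[str], int], None],
                       measure: str = "entropy") -> ALState:
    """The bookkeeping core of the annotation loop, decoupled from the
    network so it can run on a bare id pool with any scorer.

    ``score_ids(ids)`` returns one uncertainty-measure value per id (on
    the measure's own scale); ``fit_on_labeled(labeled_ids, round_no)``
    (re)trains the model after each annotation event.
    """
    rng = np.random.default_rng(state.seed)
    if state.labeled_ids:
        raise ValueError("loop expects a fresh state with no labeled ids")
    # initial uniform draw of k
    initial = [state.pool_ids[i] for i in
               rng.choice(len(state.pool_ids), size=state.k, replace=False)]
    state.annotate(initial, round_no=0, measure="random")
    fit_on_labeled(state.labeled_ids, 0)
    round_no = 0
    while len(state.labeled_ids) < state.budget:
        round_no += 1
        remaining = state.unlabeled_ids
        values = np.asarray(score_ids(remaining), dtype=float)
        scores = [UncertaintyScore(s, measure, float(v))
                  for s, v in zip(remaining, values)]
        ranked = rank_for_annotation(scores)
        take = min(state.m, state.budget - len(state.labeled_ids))
        chosen = ranked[:take]
        state.annotate(chosen, round_no, measure,
                       {s.sample_id: s.value for s in scores})
        state.iteration = round_no
        state.check_invariants()
        fit_on_labeled(state.labeled_ids, round_no)
    return state


def al_loop(pretrained: ParallelNet, pool: Dataset, state: ALState,
            cfg: NetConfig, oracle: Callable[[str], str], *,
            measure: str = "entropy", wavelet: str = DEFAULT_WAVELET,
            warm_start: bool = True, val_fraction: float = 0.1,
            round_max_epochs: int | None = None,
            test_set: Dataset | None = None):
    """Run the full active-learning scheme with the parallel network.

    ``pool`` is the unlabeled target pool (labels hidden); ``oracle`` maps
    a source_id to its class name and is called exactly once per selected
    image.  Each round fine-tunes from the current weights (warm start) or
    from a copy of the pretrained checkpoint (cold start).  Intermediate
    rounds may be capped at ``round_max_epochs`` (warm starting makes the
    training effort cumulative); the final fit after the budget is
    exhausted always uses the full ``cfg`` epoch budget.  Returns
    ``(model, state, reports)`` where ``reports`` holds one evaluation per
    round when ``test_set`` is given.
    """
    from .evaluation import evaluate  # local import to avoid a cycle
    from .transfer import fine_tune

    if state.budget > len(pool):
        raise ValueError("budget exceeds pool size")
    a_pool, d_pool = batch_decompose(pool, wavelet)
    id_to_row = {sid: i for i, sid in enumerate(pool.ids())}
    class_names = pool.class_names
    pretrained_state = pretrained.state_dict() if not warm_start else None
    model = pretrained
    reports = []

    def labeled_dataset(labeled_ids: list[str]) -> Dataset:
        items = [CellImage(pixels=pool.by_id(s).pixels, label=oracle(s),
                           source_id=s) for s in labeled_ids]
        return Dataset(items=items, class_names=list(class_names))

    def fit_on_labeled(labeled_ids: list[str], round_no: int) -> None:
        nonlocal model
        if not warm_start and pretrained_state is not None and round_no > 0:
            model.load_state_dict(pretrained_state)
        final = len(labeled_ids) >= state.budget
        epochs = cfg.max_epochs if (final or round_max_epochs is None) \
            else min(round_max_epochs, cfg.max_epochs)
        round_cfg = NetConfig(**{**cfg.__dict__, "seed": cfg.seed + round_no,
                                 "max_epochs": epochs})
        fine_tune(model, labeled_dataset(labeled_ids), round_cfg,
                  wavelet=wavelet, val_fraction=val_fraction)
        if test_set is not None:
            reports.append(evaluate(model, test_set, wavelet=wavelet))

    def score_ids(ids: list[str]) -> np.ndarray:
        rows = np.array([id_to_row[s] for s in ids])
        probs = predict_proba(model, a_pool[rows], d_pool[rows])
        return score_batch(probs, measure)

    state = run_selection_loop(state, score_ids=score_ids,
                               fit_on_labeled=fit_on_labeled, measure=measure)
    return model, state, reports


def make_state(pool: Dataset | Sequence[str], budget: int,
               k: int | None = None, m: int | None = None, seed: int = 0) -> ALState:
    """Build an ALState; k and m default to 15% and 10% of the budget."""
    ids = pool.ids() if isinstance(pool, Dataset) else list(pool)
    if k is None:
        k = int(round(0.15 * budget))
    if m is None:
        m = int(round(0.10 * budget))
    return ALState(pool_ids=ids, budget=budget, k=max(1, k), m=max(1, m), seed=seed)


class ActiveLearner:
    """Object-style wrapper around :func:`al_loop` holding its results.

    Attributes after ``fit``: ``model_``, ``state_``, ``reports_``.
    """

    def __init__(self, pretrained: ParallelNet, cfg: NetConfig, *,
                 measure: str = "entropy", wavelet: str = DEFAULT_WAVELET,
                 warm_start: bool = True):
        self.pretrained = pretrained
        self.cfg = cfg
        self.measure = measure
        self.wavelet = wavelet
        self.warm_start = warm_start

    def fit(self, pool: Dataset, oracle: Callable[[str], str], state: ALState,
            test_set: Dataset | None = None) -> "ActiveLearner":
        self.model_, self.state_, self.reports_ = al_loop(
            self.pretrained, pool, state, self.cfg, oracle,
            measure=self.measure, wavelet=self.wavelet,
            warm_start=self.warm_start, test_set=test_set)
        return self
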