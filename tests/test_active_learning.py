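import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hep2al.active_learning import (ALState, UncertaintyScore,
                                    entropy_uncertainty, least_confidence,
                                    make_state, margin, rank_for_annotation,
                                    run_selection_loop, selection_schedule)


class TestUncertaintyMeasures:
    @pytest.mark.parametrize("probs,expected", [
        ((0.5, 0.5), np.log(2)),
        ((1.0, 0.0, 0.0), 0.0),
        ((0.7, 0.2, 0.1), 0.8018),
    ])
    def test_entropy_closed_forms(self, probs, expected):
        assert entropy_uncertainty(np.array(probs)) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("probs,expected", [
        (np.full(6, 1 / 6), 1 / 6),
        ((1.0, 0.0), 1.0),
        ((0.7, 0.2, 0.1), 0.7),
    ])
    def test_least_confidence_closed_forms(self, probs, expected):
        assert least_confidence(np.array(probs)) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("probs,expected", [
        ((0.6, 0.3, 0.1), 0.3),
        (np.full(4, 0.25), 0.0),
        ((1.0, 0.0, 0.0), 1.0),
    ])
    def test_margin_closed_forms(self, probs, expected):
        assert margin(np.array(probs)) == pytest.approx(expected, abs=1e-9)

    def test_margin_needs_two_classes(self):
        with pytest.raises(ValueError):
            margin(np.array([1.0]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8))
    def test_entropy_bounds(self, raw):
        p = np.array(raw) / np.sum(raw)
        e = entropy_uncertainty(p)
        assert -1e-9 <= e <= np.log(len(p)) + 1e-9

    def test_entropy_maximum_only_at_uniform(self):
        n = 5
        uniform = entropy_uncertainty(np.full(n, 1 / n))
        assert uniform == pytest.approx(np.log(n), abs=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(np.ones(n))
            if np.max(np.abs(p - 1 / n)) > 1e-3:
                assert entropy_uncertainty(p) < uniform


class TestRanking:
    def test_entropy_ranks_descending(self):
        scores = [UncertaintyScore(i, "entropy", v)
                  for i, v in zip("abc", (0.1, 1.6, 0.9))]
        assert rank_for_annotation(scores) == ["b", "c", "a"]

    def test_ties_break_by_ascending_id(self):
        scores = [UncertaintyScore("z", "entropy", 1.0),
                  UncertaintyScore("a", "entropy", 1.0)]
        assert rank_for_annotation(scores) == ["a", "z"]

    def test_margin_ranks_ascending(self):
        scores = [UncertaintyScore("p", "margin", 0.5),
                  UncertaintyScore("q", "margin", 0.0)]
        assert rank_for_annotation(scores) == ["q", "p"]

    def test_mixed_measures_rejected(self):
        scores = [UncertaintyScore("p", "margin", 0.5),
                  UncertaintyScore("q", "entropy", 0.1)]
        with pytest.raises(ValueError, match="mixed"):
            rank_for_annotation(scores)

    def test_binary_orderings_agree(self):
        """For two classes all three measures induce the same ranking
        (checked against brute-force sorting of 1000 random vectors)."""
        rng = np.random.default_rng(42)
        p1 = rng.uniform(0.0, 1.0, 1000)
        probs = np.stack([p1, 1 - p1], axis=1)
        mx = probs.max(axis=1)
        keep = np.ones(len(mx), bool)  # drop (near-)ties in max-probability
        order = np.argsort(mx, kind="stable")
        keep[order[np.flatnonzero(np.diff(mx[order]) < 1e-12)]] = False
        idx = np.flatnonzero(keep)
        ids = [f"s{i:04d}" for i in idx]
        by_entropy = rank_for_annotation(
            [UncertaintyScore(s, "entropy", entropy_uncertainty(probs[i]))
             for s, i in zip(ids, idx)])
        by_lc = rank_for_annotation(
            [UncertaintyScore(s, "least_confidence", least_confidence(probs[i]))
             for s, i in zip(ids, idx)])
        by_margin = rank_for_annotation(
            [UncertaintyScore(s, "margin", margin(probs[i]))
             for s, i in zip(ids, idx)])
        brute = [s for _, s in sorted(zip(mx[idx], ids))]  # least confident first
        assert by_entropy == by_lc == by_margin == brute


class TestScheduleAndState:
    def test_counter_example(self):
        """Pool 100, budget 20, k=3, m=2: labeled sizes per annotation event."""
        sizes = np.cumsum(selection_schedule(20, 3, 2))
        assert list(sizes) == [3, 5, 7, 9, 11, 13, 15, 17, 19, 20]

    def test_reference_budget_schedule(self):
        """Budget 10,152 with k=1500, m=1000: nine selection rounds, the
        last truncated to 652."""
        counts = selection_schedule(10_152, 1500, 1000)
        assert counts[0] == 1500
        assert len(counts) - 1 == 9
        assert counts[1:9] == [1000] * 8 and counts[9] == 652
        assert sum(counts) == 10_152

    def test_state_validation(self):
        ids = [f"i{j}" for j in range(10)]
        with pytest.raises(ValueError):
            ALState(pool_ids=ids, budget=0, k=1, m=1)
        with pytest.raises(ValueError):
            ALState(pool_ids=ids, budget=20, k=1, m=1)
        with pytest.raises(ValueError):
            ALState(pool_ids=ids, budget=5, k=6, m=1)
        with pytest.raises(ValueError):
            ALState(pool_ids=ids, budget=5, k=2, m=0)

    def test_defaults_are_fractions_of_budget(self):
        state = make_state([f"i{j}" for j in range(1000)], budget=200)
        assert state.k == 30 and state.m == 20


class TestSelectionLoop:
    def _run(self, pool_size, budget, k, m, seed=0):
        ids = [f"p{j:05d}" for j in range(pool_size)]
        state = ALState(pool_ids=ids, budget=budget, k=k, m=m, seed=seed)
        rng = np.random.default_rng(99)
        fits = []
        run_selection_loop(
            state,
            score_ids=lambda rem: rng.random(len(rem)),
            fit_on_labeled=lambda labeled, rnd: fits.append((len(labeled), rnd)),
            measure="entropy")
        return state, fits

    def test_set_algebra_and_no_requery(self):
        state, fits = self._run(100, 20, 3, 2)
        state.check_invariants()
        assert len(state.labeled_ids) == 20
        assert len(set(state.labeled_ids)) == 20
        assert set(state.labeled_ids) | set(state.unlabeled_ids) == set(state.pool_ids)
        assert not set(state.labeled_ids) & set(state.unlabeled_ids)
        assert [n for n, _ in fits] == [3, 5, 7, 9, 11, 13, 15, 17, 19, 20]

    def test_budget_equals_pool_and_k_degenerates(self):
        state, fits = self._run(10, 10, 10, 3)
        assert len(fits) == 1  # one fit, zero selection rounds
        assert sorted(state.labeled_ids) == sorted(state.pool_ids)

    def test_loop_is_seed_deterministic(self):
        s1, _ = self._run(50, 12, 4, 3, seed=5)
        s2, _ = self._run(50, 12, 4, 3, seed=5)
        assert s1.labeled_ids == s2.labeled_ids

    def test_audit_tracks_every_annotation(self):
        state, _ = self._run(60, 15, 5, 4)
        assert len(state.audit) == 15
        assert state.audit[0]["round"] == 0 and state.audit[-1]["round"] == 3
        assert state.audit[-1]["labeled_total"] == 15

    def test_audit_csv_and_json_roundtrip(self, tmp_path):
        state, _ = self._run(60, 15, 5, 4)
        csv_path = tmp_path / "audit.csv"
        state.audit_csv(str(csv_path))
        lines = csv_path.read_text().strip().splitlines()
        assert lines[0] == "round,selected_id,measure,score,labeled_total"
        assert len(lines) - 1 == 15
        restored = ALState.from_json(state.to_json())
        assert restored.labeled_ids == state.labeled_ids
        assert restored.budget == state.budget and restored.iteration == state.iteration
        restored.check_invariants()
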