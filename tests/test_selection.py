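"""Edge selection: mixture thresholds, conservative limits, task-class
labels and unique/shared status."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taskpotency.selection import (
    ThresholdPair,
    classify,
    conservative_limits,
    mixture_threshold,
    select_sensitive,
    sharedness,
)

TASKS = ("WM", "REWARD", "STOP")


class TestMixtureThreshold:
    def test_pure_null_keeps_false_positives_low(self):
        fps, cuts = [], []
        for seed in range(10):
            v = np.random.default_rng(seed).normal(0, 1, 1770)
            tp = mixture_threshold(v)
            cuts.append((tp.neg_cut, tp.pos_cut))
            fps.append(((v < tp.neg_cut) | (v > tp.pos_cut)).mean())
        assert np.mean(fps) < 0.05
        # cutoffs typically sit beyond two null SDs on standard-normal data
        assert np.mean([pos for _, pos in cuts]) >= 2.0
        assert np.mean([neg for neg, _ in cuts]) <= -2.0

    def test_planted_outliers_all_exceed_cutoffs(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 1, 1770)
        v[:30] = 5 + 0.2 * rng.standard_normal(30)
        v[30:60] = -5 + 0.2 * rng.standard_normal(30)
        tp = mixture_threshold(v)
        assert (v[:30] > tp.pos_cut).all()
        assert (v[30:60] < tp.neg_cut).all()

    def test_location_equivariance(self):
        v = np.random.default_rng(3).normal(0, 1, 2000)
        a = mixture_threshold(v)
        b = mixture_threshold(v + 0.7)
        assert b.pos_cut - a.pos_cut == pytest.approx(0.7, abs=0.02)
        assert b.neg_cut - a.neg_cut == pytest.approx(0.7, abs=0.02)

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            mixture_threshold(np.zeros(50) + np.arange(50))

    def test_deterministic(self):
        v = np.random.default_rng(5).normal(0, 1, 500)
        a, b = mixture_threshold(v), mixture_threshold(v)
        assert (a.neg_cut, a.pos_cut) == (b.neg_cut, b.pos_cut)


class TestConservativeLimits:
    def test_strictest_tail_per_side(self):
        pairs = {
            "control": ThresholdPair(-2.0, 2.2),
            "sibling": ThresholdPair(-2.4, 1.9),
            "proband": ThresholdPair(-2.1, 2.0),
        }
        lim = conservative_limits(pairs)
        assert (lim.neg_cut, lim.pos_cut) == (-2.4, 2.2)

    def test_identical_pairs_unchanged(self):
        pairs = {g: ThresholdPair(-1.5, 1.5) for g in ("a", "b", "c")}
        lim = conservative_limits(pairs)
        assert (lim.neg_cut, lim.pos_cut) == (-1.5, 1.5)

    def test_selection_monotone_under_conservative_limits(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 400)
        pairs = {
            "a": ThresholdPair(-1.8, 2.3),
            "b": ThresholdPair(-2.5, 1.7),
        }
        lim = conservative_limits(pairs)
        n_cons = select_sensitive(v, lim).size
        for p in pairs.values():
            assert n_cons <= select_sensitive(v, p).size

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPair(2.0, -2.0)


class TestSelectSensitive:
    def test_all_zero_gives_empty(self):
        assert select_sensitive(np.zeros(200), ThresholdPair(-2, 2)).size == 0

    def test_boundary_is_strict(self):
        v = np.zeros(200)
        v[7] = 2.0 + 1e-9
        v[8] = 2.0
        sel = select_sensitive(v, ThresholdPair(-2, 2))
        assert sel.tolist() == [7]

    @given(st.integers(0, 2**31 - 1))
    def test_raising_cutoffs_never_selects_more(self, seed):
        v = np.random.default_rng(seed).normal(0, 2, 300)
        small = select_sensitive(v, ThresholdPair(-1.0, 1.0))
        big = select_sensitive(v, ThresholdPair(-2.5, 2.5))
        assert set(big.tolist()) <= set(small.tolist())


class TestClassify:
    def test_exhaustive_membership_patterns(self):
        """All 8 task-membership patterns map to their label."""
        patterns = list(itertools.product([False, True], repeat=3))
        flags = {t: np.array([p[i] for p in patterns]) for i, t in enumerate(TASKS)}
        cls = classify(flags)
        for k, p in enumerate(patterns):
            n = sum(p)
            expect = {0: "none", 1: "P_single", 2: "P_mix", 3: "P_all"}[n]
            assert cls.labels[k] == expect

    def test_task_order_invariance(self):
        rng = np.random.default_rng(1)
        flags = {t: rng.random(50) < 0.4 for t in TASKS}
        a = classify(flags)
        b = classify({t: flags[t] for t in reversed(TASKS)})
        assert np.array_equal(a.labels, b.labels)

    def test_partition_sums(self):
        rng = np.random.default_rng(2)
        flags = {t: rng.random(200) < 0.3 for t in TASKS}
        cls = classify(flags)
        counts = {lab: int((cls.labels == lab).sum()) for lab in ("none", "P_single", "P_mix", "P_all")}
        assert sum(counts.values()) == 200
        assert counts["P_single"] + counts["P_mix"] + counts["P_all"] == int(cls.sensitive.sum())

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            classify({"WM": np.zeros(5, bool), "STOP": np.zeros(6, bool)})


class TestSharedness:
    def _cls(self, flags_by_group):
        return {g: classify(f, group=g) for g, f in flags_by_group.items()}

    def test_identical_groups_fully_shared(self):
        rng = np.random.default_rng(0)
        flags = {t: rng.random(100) < 0.3 for t in TASKS}
        sh = sharedness(self._cls({g: flags for g in ("a", "b", "c")}))
        for g in ("a", "b", "c"):
            assert sh["metrics"]["unique_pct"][g]["sensitive"] == 0.0
            assert not sh["unique"][g]["sensitive"].any()

    def test_class_percentage_arithmetic(self):
        n = 300
        flags = {t: np.zeros(n, bool) for t in TASKS}
        for t in TASKS:
            flags[t][:14] = True  # 14 P_all
        flags["WM"][14:100] = True  # 86 P_single -> 100 sensitive
        sh = sharedness(self._cls({"a": flags, "b": {t: np.zeros(n, bool) for t in TASKS}}))
        assert sh["metrics"]["class_pct"]["a"]["P_all"] == pytest.approx(14.0)

    def test_disjoint_groups_fully_unique(self):
        n = 60
        fa = {t: np.zeros(n, bool) for t in TASKS}
        fb = {t: np.zeros(n, bool) for t in TASKS}
        for t in TASKS:
            fa[t][:10] = True
            fb[t][20:30] = True
        sh = sharedness(self._cls({"a": fa, "b": fb}))
        assert sh["metrics"]["unique_pct"]["a"]["P_all"] == 100.0
        assert sh["metrics"]["unique_pct"]["b"]["P_all"] == 100.0

    def test_same_class_vs_any_sensitive_rule(self):
        """An edge P_all in one group but P_single in the other is unique
        under the same-class rule yet shared under any-sensitive."""
        n = 30
        fa = {t: np.zeros(n, bool) for t in TASKS}
        fb = {t: np.zeros(n, bool) for t in TASKS}
        for t in TASKS:
            fa[t][0] = True  # P_all in a
        fb["WM"][0] = True  # P_single in b
        cls = self._cls({"a": fa, "b": fb})
        same = sharedness(cls, rule="same-class")
        any_ = sharedness(cls, rule="any-sensitive")
        assert same["metrics"]["unique_pct"]["a"]["P_all"] == 100.0
        assert any_["metrics"]["unique_pct"]["a"]["P_all"] == 0.0

    def test_master_union_and_sensitive_pct(self):
        n = 50
        fa = {t: np.zeros(n, bool) for t in TASKS}
        fb = {t: np.zeros(n, bool) for t in TASKS}
        fa["WM"][:20] = True
        fb["WM"][10:30] = True
        sh = sharedness(self._cls({"a": fa, "b": fb}))
        assert sh["master"].size == 30
        assert sh["metrics"]["sensitive_pct"]["a"] == pytest.approx(100 * 20 / 30)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            sharedness({}, rule="nonsense")
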