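"""Subsample-and-relabel bootstrap: resampling mechanics, empirical
p-values, FDR control and the full inference loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from taskpotency.bootstrap import (
    BootstrapConfig,
    empirical_pvalue,
    fdr_correct,
    relabel,
    run,
    subsample_indices,
)
from taskpotency.potency import PotencyCohort

TASKS = ("WM", "REWARD", "STOP")


def make_pc(n_per_group=8, n_edges=105, seed=0, missing=0.2, groups=("control", "sibling", "proband")):
    """Synthetic potency cohort with standard-normal edge values."""
    rng = np.random.default_rng(seed)
    n = n_per_group * len(groups)
    labels = np.repeat(groups, n_per_group)
    arrays = {}
    for t in TASKS:
        a = rng.normal(0, np.sqrt(2), (n, n_edges))
        gone = rng.random(n) < missing
        a[gone] = np.nan
        arrays[t] = a
    n_regions = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    return PotencyCohort(
        subject_ids=tuple(f"s{i}" for i in range(n)),
        groups=labels,
        tasks=TASKS,
        n_regions=n_regions,
        arrays=arrays,
    )


class TestSubsample:
    def test_fraction_one_is_identity(self):
        g = np.repeat(["a", "b"], 10)
        idx = subsample_indices(g, 1.0, np.random.default_rng(0))
        assert np.array_equal(idx, np.arange(20))

    def test_floor_rounding(self):
        g = np.repeat(["a"], 10)
        idx = subsample_indices(g, 0.8, np.random.default_rng(0))
        assert idx.size == 8

    def test_minimum_two_kept(self):
        g = np.repeat(["a"], 3)
        idx = subsample_indices(g, 0.4, np.random.default_rng(0))
        assert idx.size == 2

    def test_stratification_preserved(self):
        g = np.repeat(["a", "b", "c"], (10, 20, 30))
        idx = subsample_indices(g, 0.8, np.random.default_rng(1))
        kept = g[idx]
        assert [(kept == x).sum() for x in "abc"] == [8, 16, 24]

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            subsample_indices(np.array(["a", "b", "b"]), 0.8, np.random.default_rng(0))

    def test_union_covers_all_subjects(self):
        g = np.repeat(["a", "b"], 15)
        rng = np.random.default_rng(2)
        seen = set()
        for _ in range(60):
            seen |= set(subsample_indices(g, 0.8, rng).tolist())
        assert seen == set(range(30))


class TestRelabel:
    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=2, max_size=60))
    def test_group_sizes_invariant(self, labels):
        labels = np.array(labels)
        out = relabel(labels, np.random.default_rng(0))
        for g in np.unique(labels):
            assert (out == g).sum() == (labels == g).sum()

    def test_single_group_is_identity(self):
        labels = np.repeat(["a"], 10)
        assert np.array_equal(relabel(labels, np.random.default_rng(0)), labels)


class TestEmpiricalPvalue:
    def test_observed_at_median_is_one(self):
        null = np.arange(201.0)
        assert empirical_pvalue(100.0, null) == 1.0

    def test_floor_when_beyond_all_nulls(self):
        null = np.random.default_rng(0).normal(size=200)
        assert empirical_pvalue(50.0, null) == pytest.approx(2 / 201)

    def test_matches_explicit_rank_computation(self):
        rng = np.random.default_rng(1)
        null = rng.normal(size=151)
        for obs in (-2.0, -0.3, 0.0, 0.8, 3.0):
            lo = (null <= obs).sum() + 1
            hi = (null >= obs).sum() + 1
            expect = min(1.0, 2 * min(lo, hi) / 152)
            assert empirical_pvalue(obs, null) == pytest.approx(expect)

    def test_too_few_nulls_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            empirical_pvalue(0.0, np.zeros(10))


class TestFdrCorrect:
    def test_all_tiny_p_significant(self):
        flags = fdr_correct({"g": {f"m{i}": 0.001 for i in range(5)}}, q=0.05)
        assert all(flags["g"].values())

    def test_single_marginal_p_not_significant(self):
        flags = fdr_correct({"g": {"m": 0.06}}, q=0.05)
        assert not flags["g"]["m"]

    def test_step_up_on_worked_list(self):
        pvals = {"m1": 0.01, "m2": 0.02, "m3": 0.04, "m4": 0.30}
        flags = fdr_correct({"g": pvals}, q=0.05)
        # step-up: largest k with p_(k) <= k*q/m is k=2 (0.02 <= 0.025;
        # 0.04 > 0.0375), so exactly the two smallest pass
        expect, *_ = multipletests(list(pvals.values()), alpha=0.05, method="fdr_bh")
        assert [flags["g"][k] for k in pvals] == expect.tolist()
        assert flags["g"]["m1"] and flags["g"]["m2"]
        assert not flags["g"]["m3"] and not flags["g"]["m4"]

    def test_groups_corrected_independently(self):
        others = {f"m{i}": 0.9 for i in range(9)}
        flags = fdr_correct(
            {"g1": {"m": 0.04}, "g2": {"m": 0.04, **others}}, q=0.05
        )
        assert flags["g1"]["m"]  # alone in its family, 0.04 passes
        assert not flags["g2"]["m"]  # in a 10-way family it does not

    def test_nan_pvalues_excluded(self):
        flags = fdr_correct({"g": {"m1": float("nan"), "m2": 0.01}}, q=0.05)
        assert not flags["g"]["m1"]
        assert flags["g"]["m2"]


class TestRun:
    def test_deterministic_given_seed(self):
        pc = make_pc(seed=3)
        cfg = BootstrapConfig(n_iterations=100, seed=42, metrics=("percentage",))
        a, b = run(pc, cfg), run(pc, cfg)
        for g in a.groups:
            for m in a.observed[g]:
                assert np.array_equal(a.observed[g][m], b.observed[g][m], equal_nan=True)
                assert np.array_equal(a.null[g][m], b.null[g][m], equal_nan=True)
            for row in a.selection_stacks[g]:
                assert np.array_equal(a.selection_stacks[g][row], b.selection_stacks[g][row])

    def test_null_and_observed_coincide_without_group_effects(self):
        """Marginally over cohorts generated with identical group
        processes, the observed and relabeled metric streams follow the
        same distribution. (Within a single cohort the observed stream is
        conditioned on the realized group assignment, so the comparison
        must pool across cohorts.)"""
        from scipy.stats import ks_2samp

        obs_pool, null_pool = [], []
        for seed in range(12):
            pc = make_pc(seed=400 + seed, n_per_group=10)
            res = run(
                pc, BootstrapConfig(n_iterations=100, seed=500 + seed, metrics=("percentage",))
            )
            obs_pool.append(res.observed["control"]["sensitive_pct"])
            null_pool.append(res.null["control"]["sensitive_pct"])
        p = ks_2samp(np.concatenate(obs_pool), np.concatenate(null_pool)).pvalue
        assert p > 0.001

    def test_missing_amplitude_recorded_not_zero(self):
        """Draws where a class stratum is empty yield NaN samples."""
        pc = make_pc(seed=5)
        res = run(pc, BootstrapConfig(n_iterations=100, seed=1))
        summary = res.summary()
        amp = summary[summary.metric.str.startswith("amp_")]
        assert (amp.n_missing_observed > 0).any()
        assert not (np.nan_to_num(amp.observed_mean.to_numpy()) == 0).all()

    def test_summary_shape_and_pvalues(self):
        pc = make_pc(seed=6)
        res = run(pc, BootstrapConfig(n_iterations=100, seed=2, metrics=("percentage",)))
        s = res.summary()
        assert set(s.group) == {"control", "sibling", "proband"}
        assert set(s.metric) == {"sensitive_pct", "pall_pct", "pmix_pct", "psingle_pct"}
        ok = s.p.dropna()
        assert ((ok > 0) & (ok <= 1)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_iterations=50)
        with pytest.raises(ValueError):
            BootstrapConfig(subsample_fraction=1.2)
        with pytest.raises(ValueError):
            BootstrapConfig(metrics=("nonsense",))
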