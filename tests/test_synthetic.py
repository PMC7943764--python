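"""Synthetic cohort generator: baseline architecture, planted modulations
and scan-availability balancing."""

import numpy as np
import pytest

from taskpotency._edges import matrix_to_edges, n_edges
from taskpotency.selection import classify
from taskpotency.synthetic import (
    CohortSpec,
    generate_cohort,
    make_baseline_model,
    plant_modulations,
)

GROUPS = ("control", "sibling", "proband")


def spec_of(**kw):
    base = dict(
        n_regions=15,
        n_timepoints=100,
        group_sizes={g: 10 for g in GROUPS},
        scan_availability=1.0,
        seed=0,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_regions": 5},
            {"group_sizes": {"control": 1}},
            {"scan_availability": 0.0},
            {"scan_availability": 1.5},
            {"ar_coeff": 1.0},
        ],
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            spec_of(**kw)


class TestBaselineModel:
    def test_seeded_determinism(self):
        s = spec_of(seed=1)
        a, b = make_baseline_model(s), make_baseline_model(s)
        assert np.array_equal(a.baseline_precision, b.baseline_precision)
        assert a.jitter_seeds == b.jitter_seeds
        pa = plant_modulations(s, a, {"control": {"P_all": (5, 3.0)}})
        pb = plant_modulations(s, b, {"control": {"P_all": (5, 3.0)}})
        assert pa.calibration == pb.calibration
        assert [
            (e.i, e.j, e.tasks, e.delta) for e in pa.planted["control"]["P_all"]
        ] == [(e.i, e.j, e.tasks, e.delta) for e in pb.planted["control"]["P_all"]]

    def test_baseline_positive_definite(self):
        truth = make_baseline_model(spec_of(n_regions=10))
        assert np.linalg.eigvalsh(truth.baseline_precision).min() > 0
        assert np.allclose(truth.baseline_precision, truth.baseline_precision.T)

    def test_no_modulation_means_identical_task_and_rest_model(self):
        s = spec_of()
        truth = make_baseline_model(s)
        for g in GROUPS:
            for t in s.tasks:
                assert np.all(truth.delta_matrix(g, t) == 0)
                assert np.all(truth.expected_potency(g, t) == 0)


class TestPlanting:
    def test_pall_edges_modulate_every_task(self):
        s = spec_of()
        truth = plant_modulations(s, make_baseline_model(s), {"control": {"P_all": (20, 3.0)}})
        edges = truth.planted["control"]["P_all"]
        assert len(edges) == 20
        assert all(set(e.tasks) == set(s.tasks) for e in edges)

    def test_class_task_counts(self):
        s = spec_of()
        plan = {"control": {"P_all": (4, 3.0), "P_mix": (4, 3.0), "P_single": (4, 3.0)}}
        truth = plant_modulations(s, make_baseline_model(s), plan)
        assert all(len(e.tasks) == 3 for e in truth.planted["control"]["P_all"])
        assert all(len(e.tasks) == 2 for e in truth.planted["control"]["P_mix"])
        assert all(len(e.tasks) == 1 for e in truth.planted["control"]["P_single"])

    def test_classes_disjoint_within_group(self):
        s = spec_of()
        plan = {
            "shared": {"P_all": (5, 3.0)},
            "control": {"P_mix": (10, 3.0), "P_single": (10, 3.0)},
        }
        truth = plant_modulations(s, make_baseline_model(s), plan)
        ids = [
            e.edge_id(s.n_regions)
            for cls in truth.planted["control"].values()
            for e in cls
        ]
        assert len(ids) == len(set(ids))

    def test_budget_exceeded_rejected(self):
        s = spec_of(n_regions=10)
        with pytest.raises(ValueError, match="edges"):
            plant_modulations(
                s, make_baseline_model(s), {"control": {"P_all": (n_edges(10) + 1, 3.0)}}
            )

    def test_unknown_group_rejected(self):
        s = spec_of()
        with pytest.raises(ValueError, match="unknown group"):
            plant_modulations(s, make_baseline_model(s), {"martians": {"P_all": (2, 3.0)}})

    def test_shared_edges_identical_across_groups(self):
        s = spec_of()
        truth = plant_modulations(s, make_baseline_model(s), {"shared": {"P_all": (6, 3.0)}})
        ref = [(e.i, e.j, e.tasks, e.signs) for e in truth.planted["control"]["P_all"]]
        for g in ("sibling", "proband"):
            assert [(e.i, e.j, e.tasks, e.signs) for e in truth.planted[g]["P_all"]] == ref

    def test_noiseless_potency_recovers_planted_labels_exactly(self):
        """Thresholding the model-implied (noise-free) potency matrices
        reproduces the planted classification, edge for edge."""
        s = spec_of(n_regions=20)
        plan = {"control": {"P_all": (6, 3.0), "P_mix": (6, 3.0), "P_single": (6, 3.0)}}
        truth = plant_modulations(s, make_baseline_model(s), plan)
        pots = {t: matrix_to_edges(truth.expected_potency("control", t)) for t in s.tasks}
        planted_min = min(
            abs(v)
            for t, vec in pots.items()
            for v in vec[vec != 0]
        )
        eps = planted_min / 2
        cls = classify({t: np.abs(v) > eps for t, v in pots.items()}, group="control")
        for label in ("P_all", "P_mix", "P_single"):
            expect = truth.planted_edge_ids("control", label, s.n_regions)
            got = cls.class_edges(label)
            assert np.array_equal(got, expect)


class TestGenerateCohort:
    def test_full_availability_gives_all_scans(self):
        s = spec_of()
        cohort = generate_cohort(s, make_baseline_model(s))
        assert cohort.participants[list(("rest",) + s.tasks)].all().all()
        assert len(cohort.timeseries) == 30 * 4

    def test_seeded_reproducibility(self):
        s = spec_of(seed=3)
        truth = make_baseline_model(s)
        a, b = generate_cohort(s, truth), generate_cohort(s, truth)
        assert a.participants.equals(b.participants)
        for k in a.timeseries:
            assert np.array_equal(a.timeseries[k], b.timeseries[k])

    def test_long_rest_scan_approaches_model_covariance(self):
        s = spec_of(
            n_regions=10,
            n_timepoints=10_000,
            group_sizes={"control": 2},
            noise_sd=0.0,
            jitter_sd=0.0,
            seed=4,
        )
        truth = make_baseline_model(s)
        cohort = generate_cohort(s, truth)
        target = np.linalg.inv(truth.baseline_precision)
        sid = cohort.participants["subject_id"].iloc[0]
        sample = np.cov(cohort.timeseries[(sid, "rest")])
        assert np.abs(sample - target).max() < 0.08

    def test_multi_task_coverage_balanced_across_groups(self):
        s = spec_of(
            group_sizes={g: 20 for g in GROUPS},
            scan_availability=0.6,
            seed=6,
        )
        cohort = generate_cohort(s, make_baseline_model(s))
        fracs = []
        for g in GROUPS:
            sub = cohort.participants[cohort.participants["group"] == g]
            fracs.append((sub[list(s.tasks)].sum(axis=1) >= 2).mean())
        assert max(fracs) - min(fracs) <= 0.05 + 1e-9

    def test_identical_plans_give_exchangeable_group_means(self):
        """Two groups planted with the same design differ only by noise."""
        from scipy.stats import ttest_ind

        diffs_a, diffs_b = [], []
        for seed in range(10):
            s = CohortSpec(
                n_regions=15,
                n_timepoints=100,
                group_sizes={"control": 6, "proband": 6},
                scan_availability=1.0,
                seed=200 + seed,
            )
            plan = {"shared": {"P_all": (5, 3.0)}}
            truth = plant_modulations(s, make_baseline_model(s), plan)
            cohort = generate_cohort(s, truth)
            from taskpotency.model import TaskPotencyModel

            pc = TaskPotencyModel.from_cohort(cohort).potency_cohort()
            planted = truth.planted_edge_ids("control", "P_all", 15)
            for gi, (g, acc) in enumerate((("control", diffs_a), ("proband", diffs_b))):
                rows = np.flatnonzero(pc.groups == g)
                acc.append(np.abs(pc.group_mean("WM", rows)[planted]).mean())
        _, p = ttest_ind(diffs_a, diffs_b)
        assert p > 0.01
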