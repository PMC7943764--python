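"""Shared fixtures: small synthetic cohorts and the two flagship
experiment fixtures (ADHD-like contrast cohort, group-specific-core
cohort) reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from taskpotency.bootstrap import BootstrapConfig
from taskpotency.model import TaskPotencyModel
from taskpotency.synthetic import (
    CohortSpec,
    generate_cohort,
    make_baseline_model,
    plant_modulations,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="mixture EM did not converge")
warnings.filterwarnings("ignore", message=".*scan null fit.*")

GROUPS = ("control", "sibling", "proband")


def desk_spec(n_regions=15, n_timepoints=100, n_per_group=10, availability=0.7, seed=0, groups=GROUPS):
    return CohortSpec(
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        group_sizes={g: n_per_group for g in groups},
        scan_availability=availability,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Unmodulated 15-region cohort for plumbing tests."""
    spec = desk_spec(seed=101)
    return generate_cohort(spec, make_baseline_model(spec))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Desk-scale cohort (60 regions, 30 subjects/group, full coverage)
    with P_all / P_mix / P_single planted at amplitude 3 null SDs."""
    spec = CohortSpec(
        n_regions=60,
        n_timepoints=200,
        group_sizes={g: 30 for g in GROUPS},
        scan_availability=1.0,
        seed=5,
    )
    plan = {g: {"P_all": (20, 3.0), "P_mix": (8, 3.0), "P_single": (20, 3.0)} for g in GROUPS}
    truth = plant_modulations(spec, make_baseline_model(spec), plan)
    return generate_cohort(spec, truth)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    model = TaskPotencyModel.from_cohort(recovery_cohort)
    return model.fit()


@pytest.fixture(scope="session")
def adhd_like_results():
    """Cohort emulating the study's group pattern: a proband group with
    reduced P_all structure but more, stronger task-specific modulations;
    siblings intermediate. Returns (truth, fitted results, bootstrap)."""
    spec = CohortSpec(
        n_regions=60,
        n_timepoints=200,
        group_sizes={g: 30 for g in GROUPS},
        scan_availability=0.75,
        seed=11,
    )
    plan = {
        "shared": {"P_all": (6, 4.5)},
        "control+sibling": {"P_all": (16, 4.5)},
        "control": {"P_all": (6, 4.5), "P_mix": (6, 4.5), "P_single": (6, 4.5)},
        "sibling": {"P_all": (3, 4.5), "P_mix": (6, 4.5), "P_single": (10, 4.5)},
        "proband": {"P_mix": (4, 4.5), "P_single": (24, 5.5)},
    }
    truth = plant_modulations(spec, make_baseline_model(spec), plan)
    cohort = generate_cohort(spec, truth)
    res = TaskPotencyModel.from_cohort(cohort).fit()
    boot = res.bootstrap(BootstrapConfig(n_iterations=300, seed=7))
    return truth, res, boot


@pytest.fixture(scope="session")
def groupspec_results():
    """Cohort with a shared task-generic core plus disjoint group-specific
    P_all edges, for selection-stability checks. Returns (truth, bootstrap)."""
    spec = CohortSpec(
        n_regions=60,
        n_timepoints=200,
        group_sizes={g: 30 for g in GROUPS},
        scan_availability=0.75,
        seed=21,
    )
    plan = {"shared": {"P_all": (6, 4.5)}}
    plan.update({g: {"P_all": (12, 5.0)} for g in GROUPS})
    truth = plant_modulations(spec, make_baseline_model(spec), plan)
    cohort = generate_cohort(spec, truth)
    res = TaskPotencyModel.from_cohort(cohort).fit()
    boot = res.bootstrap(BootstrapConfig(n_iterations=200, seed=13, metrics=("percentage",)))
    return truth, boot
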