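"""Task potency: task-minus-rest connectivity deviations.

A subject's task potency is the signed elementwise difference between the
normalized connectome of a task scan and the normalized connectome of that
same subject's resting-state scan. The sign is retained at this stage;
amplitude metrics take the absolute value, disregarding the up- versus
down-modulation distinction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ._edges import matrix_to_edges, n_edges
from .connectome import ConnectivityMatrix

__all__ = [
    "PotencyMatrix",
    "GroupPotency",
    "PotencyCohort",
    "subject_potency",
    "group_mean_potency",
    "amplitude",
]


@dataclass
class PotencyMatrix:
    """Signed task-minus-rest deviation matrix for one subject and task."""

    values: np.ndarray
    subject_id: str
    task: str
    group: str

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        return matrix_to_edges(self.values)


@dataclass
class GroupPotency:
    """Elementwise mean of subject potency matrices for one group and task."""

    mean_values: np.ndarray
    task: str
    group: str
    n_subjects: int

    def edge_values(self) -> np.ndarray:
        return matrix_to_edges(self.mean_values)


def subject_potency(
    task_matrix: ConnectivityMatrix,
    rest_matrix: ConnectivityMatrix,
    subject_id: str = "",
    task: str = "",
    group: str = "",
) -> PotencyMatrix:
    """Task potency of one subject: task z* minus rest z*, signed."""
    if task_matrix.values.shape != rest_matrix.values.shape:
        raise ValueError(
            f"task matrix shape {task_matrix.values.shape} does not match "
            f"rest matrix shape {rest_matrix.values.shape}"
        )
    values = task_matrix.values - rest_matrix.values
    np.fill_diagonal(values, 0.0)
    return PotencyMatrix(values=values, subject_id=subject_id, task=task, group=group)


def group_mean_potency(potencies: list[PotencyMatrix]) -> GroupPotency:
    """Group-level potency: elementwise mean across subjects of one group x task."""
    if not potencies:
        raise ValueError("cannot average an empty collection of potency matrices")
    groups = {p.group for p in potencies}
    tasks = {p.task for p in potencies}
    if len(groups) > 1 or len(tasks) > 1:
        raise ValueError(
            f"potency matrices mix groups {groups} or tasks {tasks}; "
            "group means are per group and task"
        )
    mean = np.mean([p.values for p in potencies], axis=0)
    return GroupPotency(
        mean_values=mean,
        task=potencies[0].task,
        group=potencies[0].group,
        n_subjects=len(potencies),
    )


def amplitude(potencies: list[PotencyMatrix], edges: np.ndarray) -> float:
    """Mean absolute potency over an edge set.

    Averaging order: for each subject, the mean |potency| over the listed
    edges and over all of that subject's matrices in the collection; then
    the mean across subjects. Each subject thus contributes equally
    regardless of how many task scans it has.

    Parameters
    ----------
    edges : int array
        Canonical edge ids (strict upper triangle, row-major).
    """
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        raise ValueError("amplitude requires a non-empty edge set")
    if not potencies:
        raise ValueError("amplitude requires at least one potency matrix")
    m = n_edges(potencies[0].n_regions)
    if edges.min() < 0 or edges.max() >= m:
        raise ValueError(f"edge index out of range [0, {m})")

    per_subject: dict[str, list[float]] = defaultdict(list)
    for p in potencies:
        per_subject[p.subject_id].append(float(np.abs(p.edge_values()[edges]).mean()))
    return float(np.mean([np.mean(v) for v in per_subject.values()]))


@dataclass
class PotencyCohort:
    """Subject-level potency vectors for a whole cohort, in array form.

    ``arrays[task]`` is (n_subjects, n_edges); rows of subjects lacking
    that task scan are NaN. This is the working representation consumed by
    the bootstrap, where group means, thresholds and classifications are
    recomputed thousands of times.
    """

    subject_ids: tuple[str, ...]
    groups: np.ndarray  # str array aligned with subject_ids
    tasks: tuple[str, ...]
    n_regions: int
    arrays: dict[str, np.ndarray]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    def group_mean(self, task: str, rows: np.ndarray) -> np.ndarray:
        """Mean potency edge vector over the given subject rows (NaN-aware)."""
        sub = self.arrays[task][rows]
        ok = ~np.isnan(sub[:, 0])
        if not ok.any():
            return np.full(self.n_edges, np.nan)
        return sub[ok].mean(axis=0)

    @classmethod
    def from_cohort(cls, cohort) -> "PotencyCohort":
        """Run the per-scan connectivity pipeline and subtract rest from tasks.

        The per-scan mixture normalizations are refit in one batched EM
        call across scans (each scan still gets its own, subject-specific
        null fit; batching only shares the loop).
        """
        from ._edges import matrix_to_edges
        from .connectome import fisher_z, partial_correlation
        from .mixture import fit_null_batch

        spec = cohort.spec
        ids = tuple(cohort.participants["subject_id"])
        groups = cohort.participants["group"].to_numpy()
        m = n_edges(spec.n_regions)

        scan_keys = []
        z_cols = []
        for row_i, sid in enumerate(ids):
            for scan in ("rest", *spec.tasks):
                ts = cohort.timeseries.get((sid, scan))
                if ts is None:
                    continue
                z_cols.append(fisher_z(matrix_to_edges(partial_correlation(ts))))
                scan_keys.append((row_i, scan))
        Z = np.column_stack(z_cols)  # (n_edges, n_scans)
        fit = fit_null_batch(Z)
        robust = ~fit.converged
        if robust.any():  # robust median/MAD fallback already applied in-fit
            import warnings

            warnings.warn(
                f"{int(robust.sum())} scan null fit(s) did not converge; "
                "robust fallback used",
                RuntimeWarning,
                stacklevel=2,
            )
        Zn = (Z - fit.mu) / fit.sigma  # per-scan normalization

        normalized: dict[tuple[int, str], np.ndarray] = {
            key: Zn[:, k] for k, key in enumerate(scan_keys)
        }
        arrays = {t: np.full((len(ids), m), np.nan) for t in spec.tasks}
        for row_i, sid in enumerate(ids):
            rest = normalized[(row_i, "rest")]
            for t in spec.tasks:
                task_edges = normalized.get((row_i, t))
                if task_edges is not None:
                    arrays[t][row_i] = task_edges - rest
        return cls(
            subject_ids=ids,
            groups=groups,
            tasks=tuple(spec.tasks),
            n_regions=spec.n_regions,
            arrays=arrays,
        )
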