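"""Model/Results facade over the task-potency pipeline.

`TaskPotencyModel` is built from per-subject scan timeseries plus a
participants table (or directly from a synthetic `Cohort`); `fit()`
estimates per-scan connectomes, subject potency matrices, group-level
mean potency, mixture thresholds with conservative cross-group limits,
and the P_single / P_mix / P_all classification with unique/shared
status. The returned `TaskPotencyResults` exposes summary tables and a
`bootstrap()` method for subsample-and-relabel inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._edges import edge_index, edges_to_matrix
from .bootstrap import BootstrapConfig, BootstrapResults, run as _run_bootstrap
from .potency import GroupPotency, PotencyCohort
from .selection import (
    GroupClassification,
    ThresholdPair,
    group_classification_from_potency,
    sharedness,
)

__all__ = ["TaskPotencyModel", "TaskPotencyResults"]


class TaskPotencyModel:
    """Task-potency analysis of a multi-task, multi-group cohort.

    Parameters
    ----------
    timeseries : dict
        ``(subject_id, scan)`` -> (n_regions, n_timepoints) array, with
        ``scan`` equal to ``"rest"`` or a task name.
    participants : DataFrame
        Columns ``subject_id``, ``group``, ``rest`` and one boolean column
        per task.
    tasks : tuple of str
        Task scan names, in canonical order.
    """

    def __init__(
        self,
        timeseries: dict[tuple[str, str], np.ndarray],
        participants: pd.DataFrame,
        tasks: tuple[str, ...],
        region_labels: list[str] | None = None,
    ):
        required = {"subject_id", "group", "rest", *tasks}
        missing = required - set(participants.columns)
        if missing:
            raise ValueError(f"participants table lacks column(s): {sorted(missing)}")
        keep = participants[participants["rest"].astype(bool)].reset_index(drop=True)
        self.participants = keep
        self.tasks = tuple(tasks)
        self.timeseries = timeseries
        self.region_labels = region_labels
        first = next(iter(timeseries.values()))
        self.n_regions = first.shape[0]
        self._pc: PotencyCohort | None = None

    @classmethod
    def from_cohort(cls, cohort) -> "TaskPotencyModel":
        """Build from a synthetic `Cohort` (keeps its ground truth reachable
        through ``cohort.truth`` for recovery checks)."""
        return cls(
            timeseries=cohort.timeseries,
            participants=cohort.participants,
            tasks=tuple(cohort.spec.tasks),
        )

    @classmethod
    def from_directory(cls, data_dir, tasks: tuple[str, ...] | None = None) -> "TaskPotencyModel":
        """Load a written cohort: ``participants.tsv``, ``atlas.tsv`` and
        ``timeseries/{subject}_{scan}.txt`` matrices."""
        from pathlib import Path

        from .pipeline import read_participants

        d = Path(data_dir)
        participants = read_participants(d / "participants.tsv", tasks=tasks)
        task_cols = [c for c in participants.columns if c not in ("subject_id", "group", "rest")]
        tasks = tuple(tasks or task_cols)
        labels = None
        atlas = d / "atlas.tsv"
        if atlas.exists():
            labels = pd.read_csv(atlas, sep="\t")["label"].tolist()
        timeseries = {}
        for _, row in participants.iterrows():
            sid = row["subject_id"]
            for scan in ("rest", *tasks):
                if row[scan]:
                    timeseries[(sid, scan)] = np.loadtxt(d / "timeseries" / f"{sid}_{scan}.txt")
        return cls(timeseries, participants, tasks, region_labels=labels)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.participants["group"]))

    def potency_cohort(self) -> PotencyCohort:
        """Per-subject potency vectors (computed once, then cached)."""
        if self._pc is None:
            self._pc = PotencyCohort.from_cohort(_Carrier(self))
        return self._pc

    def fit(self, uniqueness_rule: str = "same-class") -> "TaskPotencyResults":
        """Estimate group potency, thresholds and the edge classification."""
        pc = self.potency_cohort()
        group_potencies: dict[str, dict[str, GroupPotency]] = {}
        for g in self.groups:
            rows = np.flatnonzero(pc.groups == g)
            group_potencies[g] = {}
            for t in self.tasks:
                mean_edges = pc.group_mean(t, rows)
                n_sub = int((~np.isnan(pc.arrays[t][rows, 0])).sum())
                group_potencies[g][t] = GroupPotency(
                    mean_values=edges_to_matrix(mean_edges, self.n_regions),
                    task=t,
                    group=g,
                    n_subjects=n_sub,
                )

        classifications, limits = group_classification_from_potency(
            group_potencies, min_values=min(100, pc.n_edges)
        )
        shared = sharedness(classifications, rule=uniqueness_rule)
        return TaskPotencyResults(
            model=self,
            group_potencies=group_potencies,
            limits=limits,
            classifications=classifications,
            shared=shared,
        )


class _Carrier:
    """Adapter giving PotencyCohort.from_cohort the fields it expects."""

    def __init__(self, model: TaskPotencyModel):
        self.participants = model.participants
        self.timeseries = model.timeseries
        self.spec = _SpecView(model)


class _SpecView:
    def __init__(self, model: TaskPotencyModel):
        self.tasks = model.tasks
        self.n_regions = model.n_regions
        from ._edges import n_edges

        self.null_fit_floor = min(100, n_edges(model.n_regions))


@dataclass
class TaskPotencyResults:
    """Fitted task-potency classification for one cohort."""

    model: TaskPotencyModel
    group_potencies: dict[str, dict[str, GroupPotency]]
    limits: dict[str, ThresholdPair]
    classifications: dict[str, GroupClassification]
    shared: dict

    def summary(self) -> pd.DataFrame:
        """Per-group percentages: sensitive edges as % of the master union,
        each class as % of the group's sensitive edges, and the unique
        share within each row."""
        m = self.shared["metrics"]
        rows = []
        for g in self.model.groups:
            rows.append(
                {
                    "group": g,
                    "n_sensitive": int(self.classifications[g].sensitive.sum()),
                    "sensitive_pct": m["sensitive_pct"][g],
                    "pall_pct": m["class_pct"][g]["P_all"],
                    "pmix_pct": m["class_pct"][g]["P_mix"],
                    "psingle_pct": m["class_pct"][g]["P_single"],
                    "sensitive_unique_pct": m["unique_pct"][g]["sensitive"],
                    "pall_unique_pct": m["unique_pct"][g]["P_all"],
                    "pmix_unique_pct": m["unique_pct"][g]["P_mix"],
                    "psingle_unique_pct": m["unique_pct"][g]["P_single"],
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        """Long-form per-group edge report: per-task sensitivity flags,
        class label and unique/shared status of every sensitive edge."""
        i, j = edge_index(self.model.n_regions)
        labels = self.model.region_labels
        frames = []
        for g in self.model.groups:
            cls = self.classifications[g]
            sens = np.flatnonzero(cls.sensitive)
            uniq_mask = self.shared["unique"][g]["sensitive"]
            data = {
                "group": g,
                "edge_id": sens,
                "region_i": i[sens],
                "region_j": j[sens],
                "class": cls.labels[sens],
                "unique": uniq_mask,
            }
            if labels is not None:
                data["label_i"] = np.asarray(labels, dtype=object)[i[sens]]
                data["label_j"] = np.asarray(labels, dtype=object)[j[sens]]
            for t in self.model.tasks:
                data[f"sensitive_{t}"] = cls.task_sensitive[t][sens]
            frames.append(pd.DataFrame(data))
        return pd.concat(frames, ignore_index=True)

    def bootstrap(self, config: BootstrapConfig | None = None, **kwargs) -> BootstrapResults:
        """Subsample-and-relabel inference on this cohort's metrics."""
        if config is None:
            config = BootstrapConfig(**kwargs)
        return _run_bootstrap(self.model.potency_cohort(), config)
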