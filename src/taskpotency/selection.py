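"""Sensitive-edge selection and task-class labelling.

Group-level potency matrices are thresholded with two-tailed cutoffs from
the central-Gaussian-plus-tails mixture fit: a cutoff sits where the
posterior probability of the null component drops below 0.5. The most
conservative (strictest) limit across diagnostic groups is applied per
task so that groups of unequal size are compared at the same level of
information. Sensitive edges are then classified by how many tasks
modulate them: exactly one (P_single), more than one but not all (P_mix),
or all tasks (P_all); and each labelled edge is flagged unique to its
group or shared with other groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._edges import matrix_to_edges
from .mixture import _BatchFit, fit_null_batch
from .potency import GroupPotency

__all__ = [
    "ThresholdPair",
    "GroupClassification",
    "CLASS_LABELS",
    "mixture_threshold",
    "conservative_limits",
    "select_sensitive",
    "classify",
    "sharedness",
]

CLASS_LABELS = ("none", "P_single", "P_mix", "P_all")

_GRID_COARSE = 97
_GRID_FINE = 65
_GRID_SPAN = 12.0  # in units of the fitted null SD
_FALLBACK_K = 2.0


@dataclass
class ThresholdPair:
    """Two-tailed sensitivity cutoffs for one group-by-task potency matrix."""

    neg_cut: float
    pos_cut: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.neg_cut < self.pos_cut:
            raise ValueError("neg_cut must lie below pos_cut")


@dataclass
class GroupClassification:
    """Per-edge task-sensitivity flags and class labels for one group."""

    group: str
    tasks: tuple[str, ...]
    task_sensitive: dict[str, np.ndarray]  # task -> bool edge vector
    labels: np.ndarray = field(init=False)  # str edge vector
    sensitive: np.ndarray = field(init=False)  # bool edge vector, any task

    def __post_init__(self) -> None:
        stack = np.vstack([self.task_sensitive[t] for t in self.tasks])
        counts = stack.sum(axis=0)
        self.sensitive = counts > 0
        labels = np.full(counts.shape, "none", dtype=object)
        labels[counts == 1] = "P_single"
        labels[(counts > 1) & (counts < len(self.tasks))] = "P_mix"
        labels[counts == len(self.tasks)] = "P_all"
        self.labels = labels

    def class_edges(self, label: str) -> np.ndarray:
        if label == "sensitive":
            return np.flatnonzero(self.sensitive)
        return np.flatnonzero(self.labels == label)


def _null_posterior_below_half(fit: _BatchFit, steps: np.ndarray, side: float) -> np.ndarray:
    """Boolean (n_steps, k): null posterior < 0.5 at mu + side*steps*sigma."""
    from .mixture import _gamma_pdf, _norm_pdf

    grid = fit.mu[None, :] + side * steps * fit.sigma[None, :]
    f0 = fit.weights[0][None, :] * _norm_pdf(grid, fit.mu, fit.sigma)
    f_neg = fit.weights[1][None, :] * _gamma_pdf(
        fit.anchor[None, :] - grid, fit.shape_neg, fit.scale_neg
    )
    f_pos = fit.weights[2][None, :] * _gamma_pdf(
        grid - fit.anchor[None, :], fit.shape_pos, fit.scale_pos
    )
    with np.errstate(invalid="ignore"):
        return f0 < f_neg + f_pos


def _batch_thresholds(fit: _BatchFit, fallback_k: float = _FALLBACK_K) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-0.5 crossings for every column of a batched mixture fit.

    Two-stage deterministic search per tail: a coarse scan over
    [0, 12] null SDs outward from the centre brackets the first point
    where the non-null posterior dominates, then a fine scan resolves it.
    Columns whose tail component is too weak to produce a crossing fall
    back to mu -/+ k*sigma.
    """
    cuts = []
    coarse = np.linspace(0.0, _GRID_SPAN, _GRID_COARSE)[:, None]
    dx = _GRID_SPAN / (_GRID_COARSE - 1)
    for side in (+1.0, -1.0):
        below = _null_posterior_below_half(fit, coarse, side)
        first = np.argmax(below, axis=0)  # 0 when no crossing
        has = below.any(axis=0) & (first > 0)
        lo = np.maximum(first - 1, 0) * dx
        fine_steps = lo[None, :] + np.linspace(0.0, dx, _GRID_FINE)[:, None]
        below_f = _null_posterior_below_half(fit, fine_steps, side)
        first_f = np.argmax(below_f, axis=0)
        step = np.take_along_axis(fine_steps, first_f[None, :], axis=0)[0]
        cut = np.where(
            has,
            fit.mu + side * step * fit.sigma,
            fit.mu + side * fallback_k * fit.sigma,
        )
        cuts.append(cut)
    pos_cuts, neg_cuts = cuts
    return neg_cuts, pos_cuts


def mixture_threshold(
    group_potency: GroupPotency | np.ndarray,
    min_values: int = 100,
    fallback_k: float = _FALLBACK_K,
) -> ThresholdPair:
    """Two-tailed mixture-model cutoffs for one group-level potency matrix.

    The mixture (central Gaussian + mirrored Gamma tails) is fitted to the
    edge-value distribution; each cutoff is the first point, moving outward
    from the centre, where the posterior probability of the null component
    drops below 0.5. Degenerate fits fall back to mu -/+ k*sigma with a
    warning. Deterministic.
    """
    if isinstance(group_potency, GroupPotency):
        values = group_potency.edge_values()
        source = f"{group_potency.group}:{group_potency.task}"
    else:
        values = np.asarray(group_potency, dtype=float).ravel()
        source = ""
    if values.size < min_values:
        raise ValueError(
            f"need at least {min_values} edges for a stable threshold fit, got {values.size}"
        )
    fit = fit_null_batch(values[:, None])
    if not fit.converged[0]:
        warnings.warn(
            "threshold mixture fit degenerate; using mu +/- k*sigma fallback",
            RuntimeWarning,
            stacklevel=2,
        )
    neg, pos = _batch_thresholds(fit, fallback_k=fallback_k)
    return ThresholdPair(neg_cut=float(neg[0]), pos_cut=float(pos[0]), source=source)


def conservative_limits(pairs: dict[str, ThresholdPair], task: str = "") -> ThresholdPair:
    """Strictest limit across groups: per tail, the largest-magnitude cutoff.

    With unequal group sizes the group with the loosest threshold would
    otherwise contribute more edges; taking the strictest limit in each
    tail compares all groups at the same level of information.
    """
    if not pairs:
        raise ValueError("no threshold pairs supplied")
    neg = min(p.neg_cut for p in pairs.values())
    pos = max(p.pos_cut for p in pairs.values())
    return ThresholdPair(neg_cut=neg, pos_cut=pos, source=f"conservative:{task}")


def select_sensitive(
    group_potency: GroupPotency | np.ndarray, limits: ThresholdPair
) -> np.ndarray:
    """Edges whose group-mean potency exceeds the two-tailed limits.

    Returns canonical edge ids (sorted, strict-upper-triangle order).
    """
    if isinstance(group_potency, GroupPotency):
        values = group_potency.edge_values()
    else:
        values = np.asarray(group_potency, dtype=float).ravel()
    mask = (values < limits.neg_cut) | (values > limits.pos_cut)
    return np.flatnonzero(mask)


def classify(task_sensitive: dict[str, np.ndarray], group: str = "") -> GroupClassification:
    """Label edges by task-membership pattern.

    ``task_sensitive`` maps each task name to a boolean edge vector. An
    edge flagged in exactly one task is P_single, in more than one but not
    all tasks P_mix, in every task P_all, otherwise none. The label is a
    pure function of the membership pattern and invariant to task order.
    """
    tasks = tuple(task_sensitive)
    if len(tasks) < 2:
        raise ValueError("classification needs at least 2 tasks")
    sizes = {np.asarray(v).shape[0] for v in task_sensitive.values()}
    if len(sizes) != 1:
        raise ValueError("per-task edge vectors must share one edge universe")
    flags = {t: np.asarray(v, dtype=bool) for t, v in task_sensitive.items()}
    return GroupClassification(group=group, tasks=tasks, task_sensitive=flags)


def sharedness(
    classifications: dict[str, GroupClassification],
    rule: str = "same-class",
) -> dict:
    """Unique/shared status across groups plus the summary percentages.

    For the overall sensitivity row an edge is unique to a group when no
    other group marks it sensitive in any task. For a class row (P_single,
    P_mix, P_all) the default ``rule="same-class"`` calls an edge unique
    when no other group gives it the *same* class label;
    ``rule="any-sensitive"`` relaxes this to any sensitivity in another
    group.

    Returns a dict with:

    - ``unique`` : {group: {row: bool edge mask over that group's row edges}}
    - ``metrics`` : three summary blocks —
      ``sensitive_pct`` (each group's sensitive count as % of the master
      union), ``class_pct`` (each class as % of the group's sensitive
      count) and ``unique_pct`` (% of the row's edges unique to the group).
    - ``master`` : sorted edge ids of the union of sensitive edges over
      groups and tasks.
    """
    if rule not in ("same-class", "any-sensitive"):
        raise ValueError(f"unknown uniqueness rule {rule!r}")
    groups = list(classifications)
    any_sensitive = {g: classifications[g].sensitive for g in groups}
    master = np.flatnonzero(np.any([any_sensitive[g] for g in groups], axis=0))

    rows = ("sensitive", "P_single", "P_mix", "P_all")
    unique: dict[str, dict[str, np.ndarray]] = {g: {} for g in groups}
    metrics: dict[str, dict] = {"sensitive_pct": {}, "class_pct": {}, "unique_pct": {}}

    for g in groups:
        cls = classifications[g]
        n_sens = int(cls.sensitive.sum())
        metrics["sensitive_pct"][g] = 100.0 * n_sens / max(master.size, 1)
        metrics["class_pct"][g] = {}
        metrics["unique_pct"][g] = {}
        for row in rows:
            if row == "sensitive":
                mask = cls.sensitive
                others = [any_sensitive[h] for h in groups if h != g]
            else:
                mask = cls.labels == row
                metrics["class_pct"][g][row] = 100.0 * int(mask.sum()) / max(n_sens, 1)
                if rule == "same-class":
                    others = [classifications[h].labels == row for h in groups if h != g]
                else:
                    others = [any_sensitive[h] for h in groups if h != g]
            other_any = np.any(others, axis=0) if others else np.zeros_like(mask)
            uniq = mask & ~other_any
            unique[g][row] = uniq[mask]
            n_row = int(mask.sum())
            metrics["unique_pct"][g][row] = (
                100.0 * int(uniq.sum()) / n_row if n_row else float("nan")
            )
    return {"unique": unique, "metrics": metrics, "master": master}


def group_classification_from_potency(
    group_potencies: dict[str, dict[str, GroupPotency]],
    min_values: int = 100,
) -> tuple[dict[str, GroupClassification], dict[str, ThresholdPair]]:
    """Threshold and classify a full {group: {task: GroupPotency}} table.

    Fits per group-by-task mixture thresholds, reduces them to per-task
    conservative limits, selects sensitive edges and classifies each
    group. Returns (classifications, per-task conservative limits).
    """
    groups = list(group_potencies)
    tasks = list(next(iter(group_potencies.values())))
    limits: dict[str, ThresholdPair] = {}
    for t in tasks:
        pairs = {g: mixture_threshold(group_potencies[g][t], min_values=min_values) for g in groups}
        limits[t] = conservative_limits(pairs, task=t)
    classifications = {}
    for g in groups:
        n_e = matrix_to_edges(group_potencies[g][tasks[0]].mean_values).size
        flags = {}
        for t in tasks:
            sel = select_sensitive(group_potencies[g][t], limits[t])
            v = np.zeros(n_e, dtype=bool)
            v[sel] = True
            flags[t] = v
        classifications[g] = classify(flags, group=g)
    return classifications, limits
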