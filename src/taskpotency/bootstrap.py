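"""Subsample-and-relabel bootstrap inference for group differences.

Every metric (percentages of sensitive / P_all / P_mix / P_single edges,
unique-vs-shared percentages, modulation amplitudes) is tested against a
group-specific empirical null: in each iteration an 80% stratified
subsample of the cohort is analysed with true group labels (observed
stream) while an independently drawn subsample is analysed after randomly
permuting group labels with group sizes preserved (null stream). The
observed mean across iterations is compared with the null distribution by
a two-tailed add-one empirical p-value, and significance is assessed with
Benjamini-Hochberg FDR control within each group's family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mixture import fit_null_batch
from .potency import PotencyCohort
from .selection import (
    ThresholdPair,
    _batch_thresholds,
    classify,
    sharedness,
)

__all__ = [
    "BootstrapConfig",
    "BootstrapResults",
    "subsample_indices",
    "relabel",
    "run",
    "empirical_pvalue",
    "fdr_correct",
]

CLASS_ROWS = ("sensitive", "P_all", "P_mix", "P_single")

_PCT_METRICS = {
    "sensitive": "sensitive_pct",
    "P_all": "pall_pct",
    "P_mix": "pmix_pct",
    "P_single": "psingle_pct",
}
_UNIQ_METRICS = {
    "sensitive": "sensitive_unique_pct",
    "P_all": "pall_unique_pct",
    "P_mix": "pmix_unique_pct",
    "P_single": "psingle_unique_pct",
}


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings. ``metrics`` selects the tested families:
    any subset of {"percentage", "uniqueness", "amplitude"}."""

    n_iterations: int = 500
    subsample_fraction: float = 0.8
    seed: int = 0
    q: float = 0.05
    metrics: tuple[str, ...] = ("percentage", "uniqueness", "amplitude")
    null_subsample: str = "independent"  # or "same"
    uniqueness_rule: str = "same-class"

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction < 1.0):
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")
        if self.null_subsample not in ("independent", "same"):
            raise ValueError("null_subsample must be 'independent' or 'same'")
        bad = set(self.metrics) - {"percentage", "uniqueness", "amplitude"}
        if bad:
            raise ValueError(f"unknown metric families: {sorted(bad)}")


def subsample_indices(
    groups: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified subsample without replacement: floor(fraction*n) per group,
    minimum 2, preserving relative group sizes. ``fraction=1.0`` is the
    identity (up to ordering)."""
    groups = np.asarray(groups)
    keep = []
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        if rows.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        k = max(2, int(np.floor(fraction * rows.size)))
        k = min(k, rows.size)
        keep.append(rng.choice(rows, size=k, replace=False))
    return np.sort(np.concatenate(keep))


def relabel(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute group labels uniformly across subjects, preserving each
    group's size. A subject keeps its scan set; only the label moves."""
    labels = np.asarray(labels)
    return labels[rng.permutation(labels.size)]


def empirical_pvalue(observed_mean: float, null_samples: np.ndarray) -> float:
    """Two-tailed add-one empirical p-value.

    p = 2 * min(#{null <= obs} + 1, #{null >= obs} + 1) / (N + 1), capped
    at 1. Never returns 0; the floor is 2 / (N + 1).
    """
    null_samples = np.asarray(null_samples, dtype=float)
    null_samples = null_samples[~np.isnan(null_samples)]
    n = null_samples.size
    if n < 100:
        raise ValueError(f"need at least 100 null samples, got {n}")
    lo = int(np.sum(null_samples <= observed_mean)) + 1
    hi = int(np.sum(null_samples >= observed_mean)) + 1
    return min(1.0, 2.0 * min(lo, hi) / (n + 1))


def fdr_correct(pvalues_by_group: dict[str, dict[str, float]], q: float = 0.05) -> dict[str, dict[str, bool]]:
    """Benjamini-Hochberg step-up within each group's test family.

    NaN p-values (metrics undefined in every draw) are excluded from the
    family and flagged non-significant.
    """
    flags: dict[str, dict[str, bool]] = {}
    for g, pvals in pvalues_by_group.items():
        names = [k for k, v in pvals.items() if not np.isnan(v)]
        flags[g] = {k: False for k in pvals}
        if not names:
            continue
        rej, *_ = multipletests([pvals[k] for k in names], alpha=q, method="fdr_bh")
        for k, r in zip(names, rej):
            flags[g][k] = bool(r)
    return flags


def _group_mean_columns(
    pc: PotencyCohort, rows: np.ndarray, labels: np.ndarray, group_order: tuple[str, ...]
) -> np.ndarray:
    """Group-by-task mean potency columns for one (subsample, labels) draw."""
    cols = []
    for g in group_order:
        g_rows = rows[labels == g]
        for t in pc.tasks:
            cols.append(pc.group_mean(t, g_rows))
    return np.column_stack(cols)  # (n_edges, G*T)


def _draw_stats(
    pc: PotencyCohort,
    rows: np.ndarray,
    labels: np.ndarray,
    config: BootstrapConfig,
    group_order: tuple[str, ...],
    precomputed: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
):
    """Full pipeline on one (subsample, labels) draw.

    ``precomputed`` optionally carries (X, invalid, neg, pos) from a
    batched mixture fit over many draws; otherwise the fit is done here.
    Returns (metrics {group: {name: value}}, class edge masks
    {group: {row: bool vector}}).
    """
    tasks = pc.tasks
    G, T = len(group_order), len(tasks)
    if precomputed is None:
        X = _group_mean_columns(pc, rows, labels, group_order)
        invalid = np.isnan(X[0])
        X = np.nan_to_num(X, nan=0.0)
        fit = fit_null_batch(X)
        neg, pos = _batch_thresholds(fit)
    else:
        X, invalid, neg, pos = precomputed
    neg = neg.reshape(G, T)
    pos = pos.reshape(G, T)
    limits = [
        ThresholdPair(neg_cut=float(neg[:, ti].min()), pos_cut=float(pos[:, ti].max()))
        for ti in range(T)
    ]

    classifications = {}
    for gi, g in enumerate(group_order):
        flags = {}
        for ti, t in enumerate(tasks):
            col = X[:, gi * T + ti]
            sel = (col < limits[ti].neg_cut) | (col > limits[ti].pos_cut)
            if invalid[gi * T + ti]:
                sel[:] = False
            flags[t] = sel
        classifications[g] = classify(flags, group=g)

    sh = sharedness(classifications, rule=config.uniqueness_rule)
    metrics: dict[str, dict[str, float]] = {g: {} for g in group_order}
    masks: dict[str, dict[str, np.ndarray]] = {g: {} for g in group_order}

    for g in group_order:
        cls = classifications[g]
        masks[g]["sensitive"] = cls.sensitive
        for row in ("P_all", "P_mix", "P_single"):
            masks[g][row] = cls.labels == row
        if "percentage" in config.metrics:
            metrics[g]["sensitive_pct"] = sh["metrics"]["sensitive_pct"][g]
            for row in ("P_all", "P_mix", "P_single"):
                metrics[g][_PCT_METRICS[row]] = sh["metrics"]["class_pct"][g][row]
        if "uniqueness" in config.metrics:
            for row in CLASS_ROWS:
                metrics[g][_UNIQ_METRICS[row]] = sh["metrics"]["unique_pct"][g][row]
        if "amplitude" in config.metrics:
            g_rows = rows[labels == g]
            for row in ("P_all", "P_mix", "P_single"):
                row_edges = np.flatnonzero(masks[g][row])
                uniq_flags = sh["unique"][g][row]
                for stratum in ("unique", "shared"):
                    key = f"amp_{row.lower().replace('_', '')}_{stratum}"
                    chosen = row_edges[uniq_flags] if stratum == "unique" else row_edges[~uniq_flags]
                    metrics[g][key] = _stratum_amplitude(pc, g_rows, chosen, classifications[g])
    return metrics, masks


def _stratum_amplitude(
    pc: PotencyCohort,
    g_rows: np.ndarray,
    edges: np.ndarray,
    cls,
) -> float:
    """Mean absolute potency over an edge stratum.

    Per subject, |potency| is averaged over the stratum's (edge, task)
    pairs restricted to the tasks in which the group flagged the edge;
    then averaged across subjects. Empty strata yield NaN (recorded as a
    missing draw, never zero)."""
    if edges.size == 0 or g_rows.size == 0:
        return float("nan")
    sums = np.zeros(g_rows.size)
    counts = np.zeros(g_rows.size)
    for t in pc.tasks:
        flagged = edges[cls.task_sensitive[t][edges]]
        if flagged.size == 0:
            continue
        vals = np.abs(pc.arrays[t][np.ix_(g_rows, flagged)])
        ok = ~np.isnan(vals)
        sums += np.where(ok, vals, 0.0).sum(axis=1)
        counts += ok.sum(axis=1)
    has = counts > 0
    if not has.any():
        return float("nan")
    return float(np.mean(sums[has] / counts[has]))


@dataclass
class BootstrapResults:
    """Observed and null metric streams plus per-iteration edge selections."""

    config: BootstrapConfig
    groups: tuple[str, ...]
    tasks: tuple[str, ...]
    n_regions: int
    observed: dict[str, dict[str, np.ndarray]]  # group -> metric -> (n_iter,)
    null: dict[str, dict[str, np.ndarray]]
    selection_stacks: dict[str, dict[str, np.ndarray]]  # group -> row -> (n_iter, n_edges) bool
    n_missing: dict[str, dict[str, int]] = field(default_factory=dict)

    def pvalues(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for g in self.groups:
            out[g] = {}
            for name, obs in self.observed[g].items():
                obs_ok = obs[~np.isnan(obs)]
                nul = self.null[g][name]
                nul_ok = nul[~np.isnan(nul)]
                if obs_ok.size == 0 or nul_ok.size < 100:
                    out[g][name] = float("nan")
                else:
                    out[g][name] = empirical_pvalue(float(obs_ok.mean()), nul_ok)
        return out

    def significance(self) -> dict[str, dict[str, bool]]:
        return fdr_correct(self.pvalues(), q=self.config.q)

    def summary(self) -> pd.DataFrame:
        """One row per group x metric: observed mean/SD, null mean/SD,
        empirical p and FDR flag."""
        p = self.pvalues()
        sig = self.significance()
        rows = []
        for g in self.groups:
            for name, obs in self.observed[g].items():
                nul = self.null[g][name]
                rows.append(
                    {
                        "group": g,
                        "metric": name,
                        "observed_mean": float(np.nanmean(obs)) if not np.all(np.isnan(obs)) else float("nan"),
                        "observed_sd": float(np.nanstd(obs)) if not np.all(np.isnan(obs)) else float("nan"),
                        "null_mean": float(np.nanmean(nul)) if not np.all(np.isnan(nul)) else float("nan"),
                        "null_sd": float(np.nanstd(nul)) if not np.all(np.isnan(nul)) else float("nan"),
                        "p": p[g][name],
                        "significant": sig[g][name],
                        "n_missing_observed": int(np.isnan(obs).sum()),
                        "n_missing_null": int(np.isnan(nul).sum()),
                    }
                )
        return pd.DataFrame(rows)


def run(pc: PotencyCohort, config: BootstrapConfig) -> BootstrapResults:
    """Run the full subsample-and-relabel bootstrap.

    Deterministic given the config seed: the observed and null streams use
    independent RNG streams derived from it.
    """
    groups = tuple(pd.unique(pc.groups))
    rng_obs = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    rng_null = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    n_it = config.n_iterations
    n_cells = 2 * len(groups) * len(pc.tasks)  # columns per iteration

    metric_names: list[str] | None = None
    observed: dict[str, dict[str, np.ndarray]] = {}
    null: dict[str, dict[str, np.ndarray]] = {}
    stacks = {
        g: {row: np.zeros((n_it, pc.n_edges), dtype=bool) for row in CLASS_ROWS}
        for g in groups
    }

    # iterations are processed in fixed-size blocks so the mixture refits
    # of all group-by-task cells in a block run as one batched EM call
    block = int(np.clip(2_000_000 // max(1, pc.n_edges * n_cells), 8, 256))
    for start in range(0, n_it, block):
        stop = min(start + block, n_it)
        draws = []
        for _ in range(start, stop):
            rows_obs = subsample_indices(pc.groups, config.subsample_fraction, rng_obs)
            if config.null_subsample == "independent":
                rows_null = subsample_indices(pc.groups, config.subsample_fraction, rng_null)
            else:
                rows_null = rows_obs
            perm = relabel(pc.groups[rows_null], rng_null)
            draws.append((rows_obs, pc.groups[rows_obs], rows_null, perm))

        X = np.concatenate(
            [
                np.concatenate(
                    (
                        _group_mean_columns(pc, ro, lo, groups),
                        _group_mean_columns(pc, rn, ln, groups),
                    ),
                    axis=1,
                )
                for ro, lo, rn, ln in draws
            ],
            axis=1,
        )
        invalid = np.isnan(X[0])
        X = np.nan_to_num(X, nan=0.0)
        fit = fit_null_batch(X)
        neg, pos = _batch_thresholds(fit)
        half = n_cells // 2

        for bi, (rows_obs, lab_obs, rows_null, perm) in enumerate(draws):
            it = start + bi
            lo_col = bi * n_cells
            sl_obs = slice(lo_col, lo_col + half)
            sl_null = slice(lo_col + half, lo_col + n_cells)
            m_obs, masks = _draw_stats(
                pc, rows_obs, lab_obs, config, groups,
                precomputed=(X[:, sl_obs], invalid[sl_obs], neg[sl_obs], pos[sl_obs]),
            )
            m_null, _ = _draw_stats(
                pc, rows_null, perm, config, groups,
                precomputed=(X[:, sl_null], invalid[sl_null], neg[sl_null], pos[sl_null]),
            )

            if metric_names is None:
                metric_names = list(m_obs[groups[0]])
                for g in groups:
                    observed[g] = {k: np.full(n_it, np.nan) for k in metric_names}
                    null[g] = {k: np.full(n_it, np.nan) for k in metric_names}
            for g in groups:
                for k in metric_names:
                    observed[g][k][it] = m_obs[g][k]
                    null[g][k][it] = m_null[g][k]
                for row in CLASS_ROWS:
                    stacks[g][row][it] = masks[g][row]

    return BootstrapResults(
        config=config,
        groups=groups,
        tasks=pc.tasks,
        n_regions=pc.n_regions,
        observed=observed,
        null=null,
        selection_stacks=stacks,
    )
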