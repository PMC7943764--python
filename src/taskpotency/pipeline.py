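"""File-based pipeline orchestration.

Each stage reads its inputs from files and writes plain-text outputs
(TSV / JSON / delimited matrices), so the stages compose through the
filesystem exactly as the CLI exposes them: simulate -> connectome ->
potency -> select -> bootstrap -> reproducibility -> report. `run_pipeline`
runs them in order and records a manifest of every artifact with content
hashes; deterministic stages reproduce identical hashes when re-run with
the same configuration.

One deviation from a strict stage-per-concept split: the per-iteration
edge-selection stacks produced by the bootstrap are reduced to per-edge
selection rates inside the bootstrap stage (which holds them in memory),
and the reproducibility stage consumes the rate tables. Writing raw
stacks to disk would serve no consumer and would dominate the output
size.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._edges import edges_to_matrix, matrix_to_edges, n_edges
from .bootstrap import BootstrapConfig, run as run_bootstrap
from .connectome import scan_connectivity
from .potency import GroupPotency, PotencyCohort, subject_potency
from .reproducibility import reproducible_edges, uniqueness_shareability
from .selection import (
    ThresholdPair,
    classify,
    conservative_limits,
    mixture_threshold,
    select_sensitive,
    sharedness,
)

__all__ = ["RunConfig", "read_participants", "run_pipeline"]

log = logging.getLogger("taskpotency")

DEFAULT_PLAN = {
    "shared": {"P_all": [10, 3.0]},
    "control": {"P_all": [8, 3.0], "P_mix": [8, 3.0], "P_single": [8, 3.0]},
    "sibling": {"P_all": [6, 3.0], "P_mix": [8, 3.0], "P_single": [10, 3.0]},
    "proband": {"P_all": [3, 3.0], "P_mix": [8, 3.0], "P_single": [14, 3.5]},
}


@dataclass
class RunConfig:
    """Pipeline configuration; every knob has its documented default.

    Stage seeds are derived deterministically from the master ``seed`` and
    the stage name, so stages are reproducible independently.
    """

    out_dir: str = "taskpotency_out"
    data_dir: str = ""  # defaults to <out_dir>/data
    tasks: list[str] = field(default_factory=lambda: ["WM", "REWARD", "STOP"])
    seed: int = 0
    log_level: str = "INFO"
    # simulate stage
    simulate: bool = True
    n_regions: int = 30
    n_timepoints: int = 150
    n_per_group: int = 12
    availability: float = 0.75
    noise_sd: float = 0.5
    plan: dict | None = None
    # selection stage
    uniqueness_rule: str = "same-class"
    # bootstrap stage
    n_iterations: int = 200
    subsample_fraction: float = 0.8
    q: float = 0.05
    metric_families: list[str] = field(default_factory=lambda: ["percentage", "uniqueness", "amplitude"])
    null_subsample: str = "independent"
    # reproducibility stage
    selection_floor: float = 0.5
    diff_band: float = 0.25
    require_both: bool = False

    def __post_init__(self) -> None:
        if not self.data_dir:
            self.data_dir = str(Path(self.out_dir) / "data")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def read_participants(path, tasks: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read and validate a participants table.

    Requires columns ``subject_id``, ``group`` and per-scan availability
    columns including ``rest``. Subjects without a rest scan are dropped
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group", "rest"):
        if col not in df.columns:
            raise ValueError(f"participants table is missing required column '{col}'")
    if tasks:
        missing = set(tasks) - set(df.columns)
        if missing:
            raise ValueError(f"participants table is missing task column(s): {sorted(missing)}")
    scan_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    df[scan_cols] = df[scan_cols].astype(bool)
    no_rest = ~df["rest"]
    if no_rest.any():
        for sid in df.loc[no_rest, "subject_id"]:
            log.warning("subject %s has no resting-state scan; dropped", sid)
        df = df[~no_rest].reset_index(drop=True)
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    def _default(x):
        if isinstance(x, (np.floating, np.integer)):
            return round(float(x), 10)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(type(x))

    def _round(x):
        if isinstance(x, float):
            return round(x, 10)
        if isinstance(x, dict):
            return {k: _round(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_round(v) for v in x]
        return x

    path.write_text(json.dumps(_round(obj), indent=1, sort_keys=True, default=_default) + "\n")


class _Manifest:
    def __init__(self):
        self.records: list[dict] = []

    def add(self, path: Path, stage: str, params: dict | None = None) -> None:
        self.records.append(
            {
                "path": str(path),
                "stage": stage,
                "sha256": _sha256(path),
                "params": params or {},
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.records, indent=1, sort_keys=True) + "\n")


def stage_simulate(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    from .synthetic import CohortSpec, generate_cohort, make_baseline_model, plant_modulations, write_cohort

    spec = CohortSpec(
        n_regions=cfg.n_regions,
        n_timepoints=cfg.n_timepoints,
        tasks=tuple(cfg.tasks),
        group_sizes={g: cfg.n_per_group for g in ("control", "sibling", "proband")},
        scan_availability=cfg.availability,
        noise_sd=cfg.noise_sd,
        seed=cfg.stage_seed("simulate"),
    )
    log.info("simulate: %s", spec)
    truth = make_baseline_model(spec)
    plan = cfg.plan if cfg.plan is not None else DEFAULT_PLAN
    plan = {g: {c: (int(v[0]), float(v[1])) for c, v in byc.items()} for g, byc in plan.items()}
    truth = plant_modulations(spec, truth, plan)
    cohort = generate_cohort(spec, truth)
    write_cohort(cohort, cfg.data_dir)
    if manifest is not None:
        for f in sorted(Path(cfg.data_dir).rglob("*")):
            if f.is_file():
                manifest.add(f, "simulate")


def stage_connectome(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    data = Path(cfg.data_dir)
    out = Path(cfg.out_dir) / "connectomes"
    out.mkdir(parents=True, exist_ok=True)
    participants = read_participants(data / "participants.tsv", tasks=tuple(cfg.tasks))
    floor = None
    for _, row in participants.iterrows():
        sid = row["subject_id"]
        for scan in ("rest", *cfg.tasks):
            if not row[scan]:
                continue
            ts = np.loadtxt(data / "timeseries" / f"{sid}_{scan}.txt")
            if floor is None:
                floor = min(100, n_edges(ts.shape[0]))
            cm = scan_connectivity(ts, min_values=floor)
            np.savetxt(out / f"{sid}_{scan}.txt", cm.values, fmt="%.8f")
            _json_dump(asdict(cm.normalization), out / f"{sid}_{scan}_null.json")
    log.info("connectome: wrote matrices for %d subjects", len(participants))
    if manifest is not None:
        for f in sorted(out.iterdir()):
            manifest.add(f, "connectome")


def stage_potency(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    data = Path(cfg.data_dir)
    conn = Path(cfg.out_dir) / "connectomes"
    out = Path(cfg.out_dir) / "potency"
    out.mkdir(parents=True, exist_ok=True)
    participants = read_participants(data / "participants.tsv", tasks=tuple(cfg.tasks))
    records = []
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for _, row in participants.iterrows():
        sid, g = row["subject_id"], row["group"]
        rest = np.loadtxt(conn / f"{sid}_rest.txt")
        for t in cfg.tasks:
            if not row[t]:
                continue
            task = np.loadtxt(conn / f"{sid}_{t}.txt")
            pot = task - rest
            np.fill_diagonal(pot, 0.0)
            fn = out / f"{sid}_{t}.txt"
            np.savetxt(fn, pot, fmt="%.8f")
            records.append({"file": fn.name, "subject_id": sid, "group": g, "task": t})
            groups.setdefault((g, t), []).append(pot)
    for (g, t), mats in groups.items():
        np.savetxt(out / f"groupmean_{g}_{t}.txt", np.mean(mats, axis=0), fmt="%.8f")
    pd.DataFrame(records).to_csv(out / "manifest.tsv", sep="\t", index=False)
    log.info("potency: %d subject matrices, %d group means", len(records), len(groups))
    if manifest is not None:
        for f in sorted(out.iterdir()):
            manifest.add(f, "potency")


def stage_select(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    pot = Path(cfg.out_dir) / "potency"
    out = Path(cfg.out_dir) / "selection"
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(pot / "manifest.tsv", sep="\t")
    group_names = list(pd.unique(meta["group"]))
    gp: dict[str, dict[str, GroupPotency]] = {}
    for g in group_names:
        gp[g] = {}
        for t in cfg.tasks:
            mat = np.loadtxt(pot / f"groupmean_{g}_{t}.txt")
            nsub = int(((meta["group"] == g) & (meta["task"] == t)).sum())
            gp[g][t] = GroupPotency(mean_values=mat, task=t, group=g, n_subjects=nsub)
    n_regions = next(iter(gp[group_names[0]].values())).mean_values.shape[0]
    floor = min(100, n_edges(n_regions))

    limits: dict[str, ThresholdPair] = {}
    for t in cfg.tasks:
        pairs = {g: mixture_threshold(gp[g][t], min_values=floor) for g in group_names}
        limits[t] = conservative_limits(pairs, task=t)
    classifications = {}
    for g in group_names:
        flags = {}
        for t in cfg.tasks:
            sel = select_sensitive(gp[g][t], limits[t])
            v = np.zeros(n_edges(n_regions), dtype=bool)
            v[sel] = True
            flags[t] = v
        classifications[g] = classify(flags, group=g)
    sh = sharedness(classifications, rule=cfg.uniqueness_rule)

    iu_i, iu_j = np.triu_indices(n_regions, k=1)
    frames = []
    for g in group_names:
        cls = classifications[g]
        sens = np.flatnonzero(cls.sensitive)
        data = {
            "group": g,
            "edge_id": sens,
            "region_i": iu_i[sens],
            "region_j": iu_j[sens],
            "class": cls.labels[sens],
            "unique": sh["unique"][g]["sensitive"],
        }
        for t in cfg.tasks:
            data[f"sensitive_{t}"] = cls.task_sensitive[t][sens]
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(out / "edge_table.tsv", sep="\t", index=False)
    _json_dump(
        {
            "limits": {t: {"neg_cut": limits[t].neg_cut, "pos_cut": limits[t].pos_cut} for t in cfg.tasks},
            "metrics": sh["metrics"],
            "n_master": int(sh["master"].size),
        },
        out / "metrics.json",
    )
    log.info("select: master union %d edges", sh["master"].size)
    if manifest is not None:
        for f in sorted(out.iterdir()):
            manifest.add(f, "select")


def _load_potency_cohort(cfg: RunConfig) -> PotencyCohort:
    data = Path(cfg.data_dir)
    pot = Path(cfg.out_dir) / "potency"
    participants = read_participants(data / "participants.tsv", tasks=tuple(cfg.tasks))
    ids = tuple(participants["subject_id"])
    groups = participants["group"].to_numpy()
    g0 = participants["group"].iloc[0]
    sample = np.loadtxt(pot / f"groupmean_{g0}_{cfg.tasks[0]}.txt")
    n_regions = sample.shape[0]
    m = n_edges(n_regions)
    arrays = {t: np.full((len(ids), m), np.nan) for t in cfg.tasks}
    for row_i, (_, row) in enumerate(participants.iterrows()):
        for t in cfg.tasks:
            f = pot / f"{row['subject_id']}_{t}.txt"
            if f.exists():
                arrays[t][row_i] = matrix_to_edges(np.loadtxt(f))
    return PotencyCohort(
        subject_ids=ids, groups=groups, tasks=tuple(cfg.tasks),
        n_regions=n_regions, arrays=arrays,
    )


def stage_bootstrap(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    out = Path(cfg.out_dir) / "bootstrap"
    out.mkdir(parents=True, exist_ok=True)
    pc = _load_potency_cohort(cfg)
    bconfig = BootstrapConfig(
        n_iterations=cfg.n_iterations,
        subsample_fraction=cfg.subsample_fraction,
        seed=cfg.stage_seed("bootstrap"),
        q=cfg.q,
        metrics=tuple(cfg.metric_families),
        null_subsample=cfg.null_subsample,
        uniqueness_rule=cfg.uniqueness_rule,
    )
    log.info("bootstrap: %s", bconfig)
    res = run_bootstrap(pc, bconfig)
    res.summary().to_csv(out / "summary.tsv", sep="\t", index=False)

    results = {
        g: {
            name: {
                "observed_mean": float(np.nanmean(res.observed[g][name])) if not np.all(np.isnan(res.observed[g][name])) else None,
                "null_mean": float(np.nanmean(res.null[g][name])) if not np.all(np.isnan(res.null[g][name])) else None,
                "null_sd": float(np.nanstd(res.null[g][name])) if not np.all(np.isnan(res.null[g][name])) else None,
                "p": None if np.isnan(res.pvalues()[g][name]) else res.pvalues()[g][name],
                "significant": bool(res.significance()[g][name]),
            }
            for name in res.observed[g]
        }
        for g in res.groups
    }
    _json_dump(results, out / "results.json")

    archive = []
    for g in res.groups:
        for name in res.observed[g]:
            for stream, arr in (("observed", res.observed[g][name]), ("null", res.null[g][name])):
                archive.append(
                    pd.DataFrame(
                        {"group": g, "metric": name, "stream": stream,
                         "iteration": np.arange(arr.size), "value": arr}
                    )
                )
    pd.concat(archive, ignore_index=True).to_csv(out / "distributions.tsv", sep="\t", index=False)

    # reduce selection stacks to per-edge rate tables (consumed by the
    # reproducibility stage)
    from .reproducibility import rate_table

    for row in ("sensitive", "P_all", "P_mix", "P_single"):
        rate_table(res.selection_stacks, pc.n_regions, row).to_csv(
            out / f"rates_{row}.tsv", sep="\t", index=False
        )
    if manifest is not None:
        for f in sorted(out.iterdir()):
            manifest.add(f, "bootstrap", {"n_iterations": cfg.n_iterations})


def stage_reproducibility(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    boot = Path(cfg.out_dir) / "bootstrap"
    out = Path(cfg.out_dir) / "reproducibility"
    out.mkdir(parents=True, exist_ok=True)
    report = {}
    for row in ("sensitive", "P_all", "P_mix", "P_single"):
        df = pd.read_csv(boot / f"rates_{row}.tsv", sep="\t")
        rate_cols = [c for c in df.columns if c.startswith("rate_")]
        groups = [c[len("rate_"):] for c in rate_cols]
        report[row] = {}
        for ai in range(len(groups)):
            for bi in range(ai + 1, len(groups)):
                ga, gb = groups[ai], groups[bi]
                xy = uniqueness_shareability(
                    df[f"rate_{ga}"].to_numpy(),
                    df[f"rate_{gb}"].to_numpy(),
                    df[f"shared_{ga}_{gb}"].to_numpy(),
                )
                rep = reproducible_edges(
                    df[f"rate_{ga}"].to_numpy(), df[f"rate_{gb}"].to_numpy(),
                    selection_floor=cfg.selection_floor, diff_band=cfg.diff_band,
                    require_both=cfg.require_both,
                )
                pd.DataFrame(
                    {"edge_id": df["edge_id"], "x": xy[:, 0], "y": xy[:, 1]}
                ).to_csv(out / f"coords_{row}_{ga}_{gb}.tsv", sep="\t", index=False)
                report[row][f"{ga}|{gb}"] = {
                    "shared_core": rep.shared_core.tolist(),
                    f"preferred_{ga}": rep.preferred_by_a.tolist(),
                    f"preferred_{gb}": rep.preferred_by_b.tolist(),
                }
    _json_dump(report, out / "reproducible_edges.json")
    log.info("reproducibility: report written")
    if manifest is not None:
        for f in sorted(out.iterdir()):
            manifest.add(f, "reproducibility")


def stage_report(cfg: RunConfig, manifest: _Manifest | None = None) -> None:
    out = Path(cfg.out_dir)
    combined = {
        "selection": json.loads((out / "selection" / "metrics.json").read_text()),
        "bootstrap": json.loads((out / "bootstrap" / "results.json").read_text()),
    }
    _json_dump(combined, out / "metrics.json")
    if manifest is not None:
        manifest.add(out / "metrics.json", "report")


_STAGES = (
    ("simulate", stage_simulate),
    ("connectome", stage_connectome),
    ("potency", stage_potency),
    ("select", stage_select),
    ("bootstrap", stage_bootstrap),
    ("reproducibility", stage_reproducibility),
    ("report", stage_report),
)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages in order; returns the output directory.

    Any stage failure aborts with a stage-tagged error. A manifest of
    every artifact (path, stage, sha256, parameters) is written to
    ``<out_dir>/manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    manifest = _Manifest()
    try:
        for name, fn in _STAGES:
            if name == "simulate" and not cfg.simulate:
                continue
            log.info("stage %s: start", name)
            try:
                fn(cfg, manifest)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        manifest.write(out / "manifest.json")
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
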