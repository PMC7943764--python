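"""Synthetic multi-subject, multi-task cohorts with planted modulation structure.

The generator emulates a three-group (control / sibling / proband) fMRI
design with one resting-state scan per subject and up to three task scans
(WM, REWARD, STOP) with incomplete, group-balanced task coverage. Rest
timeseries are drawn from a shared sparse positive-definite precision
("baseline architecture") with small subject-specific jitter; task
timeseries are drawn from the same subject precision additively perturbed
on planted edges, so the ground-truth task modulation lives in partial
correlation space — the quantity the pipeline estimates.

Planted edges carry a class (P_all: all tasks, P_mix: exactly two,
P_single: exactly one) and an amplitude expressed in units of the
empirical null SD of subject-level potency values. That unit is calibrated
once per baseline model by simulation, which makes planted amplitudes
portable across region counts, scan lengths and noise levels.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._edges import edge_id, edge_index, n_edges
from .connectome import scan_connectivity
from .potency import subject_potency

__all__ = [
    "CohortSpec",
    "PlantedEdge",
    "GroundTruth",
    "Cohort",
    "make_baseline_model",
    "plant_modulations",
    "generate_cohort",
    "write_cohort",
]

DEFAULT_TASKS = ("WM", "REWARD", "STOP")
DEFAULT_GROUPS = ("control", "sibling", "proband")

_PD_MARGIN = 0.05  # minimum eigenvalue enforced on every precision matrix


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults give a desk-scale version of a NeuroIMAGE-like design: three
    diagnostic groups, three tasks plus rest, and ~60% task coverage per
    group (each task is acquired for only part of each group, rest for
    everyone).
    """

    n_regions: int = 60
    n_timepoints: int = 200
    tasks: tuple[str, ...] = DEFAULT_TASKS
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: 30 for g in DEFAULT_GROUPS}
    )
    scan_availability: dict[tuple[str, str], float] | float = 0.6
    noise_sd: float = 0.5
    baseline_density: float = 0.10
    jitter_sd: float = 0.02
    ar_coeff: float = 0.0  # optional AR(1) temporal smoothing, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 10:
            raise ValueError("n_regions must be >= 10")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if len(self.tasks) < 1:
            raise ValueError("need at least one task")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")
        for g in self.group_sizes:
            for t in self.tasks:
                a = self.availability(g, t)
                if not (0.0 < a <= 1.0):
                    raise ValueError(f"availability for {g}x{t} must be in (0, 1], got {a}")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must be in [0, 1)")

    def availability(self, group: str, task: str) -> float:
        if isinstance(self.scan_availability, dict):
            return self.scan_availability.get((group, task), 1.0)
        return float(self.scan_availability)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    @property
    def null_fit_floor(self) -> int:
        # per-scan mixture fits need >= 100 values when available
        return min(100, self.n_edges)


@dataclass(frozen=True)
class PlantedEdge:
    """One ground-truth modulated connection."""

    i: int
    j: int
    cls: str  # P_all | P_mix | P_single
    tasks: tuple[str, ...]
    amplitude: float  # in units of the subject-level potency null SD
    signs: dict[str, int]  # task -> +1 / -1
    delta: float  # additive precision perturbation magnitude

    def edge_id(self, n_regions: int) -> int:
        return edge_id(self.i, self.j, n_regions)


@dataclass
class GroundTruth:
    """Baseline architecture, per-subject jitter and planted modulations."""

    baseline_precision: np.ndarray
    subject_ids: tuple[str, ...]
    subject_groups: dict[str, str]
    jitter_seeds: dict[str, int]
    calibration: dict[str, float]
    planted: dict[str, dict[str, list[PlantedEdge]]] = field(default_factory=dict)

    def planted_edge_ids(self, group: str, cls: str, n_regions: int) -> np.ndarray:
        edges = self.planted.get(group, {}).get(cls, [])
        return np.array(sorted(e.edge_id(n_regions) for e in edges), dtype=int)

    def delta_matrix(self, group: str, task: str) -> np.ndarray:
        """Additive precision perturbation for one group x task."""
        n = self.baseline_precision.shape[0]
        d = np.zeros((n, n))
        for edges in self.planted.get(group, {}).values():
            for e in edges:
                if task in e.tasks:
                    # sign is in potency direction; precision moves opposite
                    d[e.i, e.j] -= e.signs[task] * e.delta
                    d[e.j, e.i] -= e.signs[task] * e.delta
        return d

    def expected_potency(self, group: str, task: str) -> np.ndarray:
        """Noiseless potency: true task minus rest Fisher-Z partial correlation.

        Nonzero exactly on the planted edges of that group and task (up to
        tiny ridge side-effects when re-regularization was needed).
        """
        p_rest = _regularize(self.baseline_precision)
        p_task = _regularize(self.baseline_precision + self.delta_matrix(group, task))
        z0 = np.arctanh(np.clip(_precision_to_partial(p_rest), -0.999999, 0.999999))
        z1 = np.arctanh(np.clip(_precision_to_partial(p_task), -0.999999, 0.999999))
        out = z1 - z0
        np.fill_diagonal(out, 0.0)
        return out


@dataclass
class Cohort:
    """Generated cohort: participants table plus per-scan timeseries."""

    spec: CohortSpec
    truth: GroundTruth
    participants: pd.DataFrame  # subject_id, group, rest + one column per task
    timeseries: dict[tuple[str, str], np.ndarray]  # (subject_id, scan) -> regions x time

    def scans_of(self, subject_id: str) -> list[str]:
        row = self.participants.set_index("subject_id").loc[subject_id]
        return [s for s in ("rest", *self.spec.tasks) if row[s]]


def _precision_to_partial(prec: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def _regularize(prec: np.ndarray) -> np.ndarray:
    """Ridge a symmetric matrix up to the required eigenvalue margin."""
    lam = np.linalg.eigvalsh(prec)[0]
    if lam < _PD_MARGIN:
        prec = prec + (_PD_MARGIN - lam) * np.eye(prec.shape[0])
    return prec


def _subject_precision(truth: GroundTruth, spec: CohortSpec, sid: str) -> np.ndarray:
    """Baseline precision plus small subject-specific jitter on its support."""
    base = truth.baseline_precision
    rng = np.random.default_rng(truth.jitter_seeds[sid])
    n = base.shape[0]
    support = (base != 0) & ~np.eye(n, dtype=bool)
    jit = np.zeros_like(base)
    iu = np.triu_indices(n, k=1)
    mask = support[iu]
    vals = rng.normal(0.0, spec.jitter_sd, size=int(mask.sum()))
    jit[iu[0][mask], iu[1][mask]] = vals
    jit = jit + jit.T
    return _regularize(base + jit)


def _sample_scan(prec: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    cov = np.linalg.inv(prec)
    L = np.linalg.cholesky(cov)
    x = L @ rng.standard_normal((prec.shape[0], spec.n_timepoints))
    if spec.ar_coeff > 0:
        from scipy.signal import lfilter

        x = lfilter([1.0], [1.0, -spec.ar_coeff], x, axis=1)
        x *= np.sqrt(1.0 - spec.ar_coeff**2)  # restore unit innovation scale
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    return x


def _make_subjects(spec: CohortSpec, rng: np.random.Generator):
    ids, groups, seeds = [], {}, {}
    for g, size in spec.group_sizes.items():
        for k in range(size):
            sid = f"{g[:3]}{k:03d}"
            ids.append(sid)
            groups[sid] = g
            seeds[sid] = int(rng.integers(0, 2**31 - 1))
    return tuple(ids), groups, seeds


def _calibrate(spec: CohortSpec, baseline: np.ndarray, rng: np.random.Generator) -> dict[str, float]:
    """Measure the potency null SD and the precision-to-potency gain.

    Simulates a few calibration subjects through the full per-scan pipeline:
    a rest scan from the baseline and a probe "task" scan with a known
    additive precision perturbation on probe edges. Returns the robust SD
    of null potency values (``sigma_null``) and the mean normalized-potency
    shift per unit precision perturbation (``rho``).
    """
    n = spec.n_regions
    probe_delta = 0.3
    n_probe = max(5, min(40, spec.n_edges // 10))
    n_cal = 8
    iu = edge_index(n)
    order = rng.permutation(spec.n_edges)

    # degree-limited probe placement so the perturbed precision stays PD
    deg = np.zeros(n, dtype=int)
    probe, probe_signs = [], []
    for eid in order:
        i, j = int(iu[0][eid]), int(iu[1][eid])
        if deg[i] >= 2 or deg[j] >= 2:
            continue
        probe.append(eid)
        probe_signs.append(1 if len(probe) % 2 else -1)
        deg[i] += 1
        deg[j] += 1
        if len(probe) >= n_probe:
            break
    probe = np.array(probe)
    probe_signs = np.array(probe_signs, dtype=float)

    delta = np.zeros((n, n))
    delta[iu[0][probe], iu[1][probe]] = probe_signs * probe_delta
    delta = delta + delta.T

    floor = spec.null_fit_floor
    shifts, null_vals = [], []
    null_mask = np.ones(spec.n_edges, dtype=bool)
    null_mask[probe] = False
    for _ in range(n_cal):
        p_rest = _regularize(baseline)
        p_task = _regularize(baseline + delta)
        rest = scan_connectivity(_sample_scan(p_rest, spec, rng), min_values=floor)
        task = scan_connectivity(_sample_scan(p_task, spec, rng), min_values=floor)
        pot = subject_potency(task, rest).edge_values()
        shifts.append(pot[probe] * probe_signs)
        null_vals.append(pot[null_mask])
    null_vals = np.concatenate(null_vals)
    sigma_null = float(1.4826 * np.median(np.abs(null_vals - np.median(null_vals))))
    # a positive additive precision perturbation lowers the partial
    # correlation, so the gain is measured in the potency direction
    rho = float(-np.mean(np.concatenate(shifts)) / probe_delta)
    return {"sigma_null": sigma_null, "rho": rho, "probe_delta": probe_delta}


def make_baseline_model(spec: CohortSpec) -> GroundTruth:
    """Build the shared rest architecture and calibrate the amplitude unit.

    The baseline precision is a random sparse symmetric matrix with unit
    diagonal, scaled so its smallest eigenvalue stays safely positive; it
    is shared across subjects as the rest covariance skeleton. Per-subject
    jitter seeds and the amplitude calibration (see :func:`_calibrate`)
    are attached. Deterministic given the spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.n_regions
    iu = edge_index(n)
    present = rng.random(spec.n_edges) < spec.baseline_density
    weights = rng.uniform(0.05, 0.20, size=spec.n_edges) * rng.choice([-1.0, 1.0], size=spec.n_edges)
    S = np.zeros((n, n))
    S[iu[0][present], iu[1][present]] = weights[present]
    S = S + S.T
    norm = np.linalg.norm(S, ord=2)
    if norm > 0.7:
        S *= 0.7 / norm
    baseline = np.eye(n) + S
    if np.linalg.eigvalsh(baseline)[0] <= 0:
        raise RuntimeError("baseline precision construction failed to be positive-definite")

    ids, groups, seeds = _make_subjects(spec, rng)
    # amplitude calibration is only needed once modulations are planted;
    # it is filled in lazily by plant_modulations
    return GroundTruth(
        baseline_precision=baseline,
        subject_ids=ids,
        subject_groups=groups,
        jitter_seeds=seeds,
        calibration={},
    )


_CLS_N_TASKS = {"P_all": None, "P_mix": 2, "P_single": 1}


def plant_modulations(
    spec: CohortSpec,
    truth: GroundTruth,
    plan: dict[str, dict[str, tuple[int, float]]],
) -> GroundTruth:
    """Plant class-structured modulated edges according to a plan.

    ``plan`` maps group -> class -> (n_edges, amplitude). Besides single
    group names, a key may be the reserved name ``"shared"`` (plant one
    edge set identically in every group: same edges, tasks and signs — a
    task-generic core common to the whole cohort) or a ``"+"``-joined
    subset such as ``"control+sibling"`` (plant identically in those
    groups only). Within each group the edge sets of all classes
    (including shared ones) are disjoint. Amplitudes are in units of the
    calibrated potency null SD.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    n = spec.n_regions
    iu = edge_index(n)
    if not truth.calibration:
        cal_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 505]))
        truth = replace(
            truth, calibration=_calibrate(spec, truth.baseline_precision, cal_rng)
        )
    sigma, rho = truth.calibration["sigma_null"], truth.calibration["rho"]
    if rho <= 0:
        raise RuntimeError("amplitude calibration produced a non-positive gain")

    def key_groups(key: str) -> tuple[str, ...]:
        if key == "shared":
            return spec.groups
        parts = tuple(key.split("+"))
        bad = set(parts) - set(spec.groups)
        if bad:
            raise ValueError(f"plan names unknown group(s): {sorted(bad)}")
        return parts
    total = sum(ne for byclass in plan.values() for ne, _ in byclass.values())
    if total > spec.n_edges:
        raise ValueError(
            f"plan requests {total} edges but only {spec.n_edges} off-diagonal pairs exist"
        )

    order = rng.permutation(spec.n_edges)
    cursor = 0
    # per-group planted node degree: caps how many strong perturbations
    # can meet at one region, protecting positive-definiteness
    deg = {g: np.zeros(n, dtype=int) for g in spec.groups}
    pool: list[int] = []  # edges skipped by the degree cap, reusable later

    def accept(eid: int, target_groups: tuple[str, ...], force: bool = False) -> tuple[int, int] | None:
        i, j = int(iu[0][eid]), int(iu[1][eid])
        if not force and any(deg[g][i] >= 3 or deg[g][j] >= 3 for g in target_groups):
            return None
        for g in target_groups:
            deg[g][i] += 1
            deg[g][j] += 1
        return (i, j)

    def draw_edges(count: int, target_groups: tuple[str, ...]) -> list[tuple[int, int]]:
        nonlocal cursor
        out: list[tuple[int, int]] = []
        remaining: list[int] = []
        for eid in pool:  # try previously skipped edges first
            got = accept(eid, target_groups) if len(out) < count else None
            if got is None:
                remaining.append(eid)
            else:
                out.append(got)
        pool[:] = remaining
        while len(out) < count and cursor < order.size:
            eid = int(order[cursor])
            cursor += 1
            got = accept(eid, target_groups)
            if got is None:
                pool.append(eid)
            else:
                out.append(got)
        while len(out) < count and pool:  # cap exhausted: take anyway
            out.append(accept(pool.pop(0), target_groups, force=True))
        if len(out) < count:
            raise ValueError("edge budget exhausted while planting")
        return out

    def make_edges(cls: str, count: int, amp: float, target_groups: tuple[str, ...]) -> list[PlantedEdge]:
        k = _CLS_N_TASKS[cls] or len(spec.tasks)
        if _CLS_N_TASKS[cls] is not None and k >= len(spec.tasks) and cls == "P_mix":
            raise ValueError("P_mix requires at least 3 tasks in the spec")
        edges = []
        for i, j in draw_edges(count, target_groups):
            tasks = tuple(
                sorted(rng.choice(len(spec.tasks), size=k, replace=False).tolist())
            )
            tasks = tuple(spec.tasks[t] for t in tasks)
            signs = {t: int(rng.choice([-1, 1])) for t in tasks}
            edges.append(
                PlantedEdge(
                    i=i, j=j, cls=cls, tasks=tasks, amplitude=amp,
                    signs=signs, delta=amp * sigma / rho,
                )
            )
        return edges

    planted: dict[str, dict[str, list[PlantedEdge]]] = {g: {} for g in spec.groups}
    # multi-group keys first so widely shared structure claims edges before
    # group-specific extras
    for key in sorted(plan, key=lambda s: -len(key_groups(s))):
        targets = key_groups(key)
        for cls, (count, amp) in plan[key].items():
            edges = make_edges(cls, count, amp, targets)
            for g in targets:
                planted[g].setdefault(cls, []).extend(edges)

    for g, byclass in planted.items():
        seen: set[int] = set()
        for edges in byclass.values():
            ids = {e.edge_id(n) for e in edges}
            if ids & seen:
                raise RuntimeError("planted classes overlap within a group")
            seen |= ids

    return replace(truth, planted=planted)


def _assign_scans(spec: CohortSpec, truth: GroundTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Seeded scan-availability draws, balanced for multi-task overlap.

    Each group x task gets round(availability * n) subjects; the fraction
    of subjects holding two or more task scans is then greedily equalized
    across groups to within 5 percentage points, mirroring the design
    check that multi-acquisition percentages were equivalent between
    groups.
    """
    rows = []
    per_group: dict[str, np.ndarray] = {}
    for g in spec.groups:
        sids = [s for s in truth.subject_ids if truth.subject_groups[s] == g]
        ng = len(sids)
        have = np.zeros((ng, len(spec.tasks)), dtype=bool)
        for ti, t in enumerate(spec.tasks):
            k = max(2, int(round(spec.availability(g, t) * ng)))
            k = min(k, ng)
            have[rng.choice(ng, size=k, replace=False), ti] = True
        per_group[g] = have

    def multi_frac(have: np.ndarray) -> float:
        return float((have.sum(axis=1) >= 2).mean())

    for _ in range(200):
        fracs = {g: multi_frac(h) for g, h in per_group.items()}
        lo_g = min(fracs, key=fracs.get)
        hi_g = max(fracs, key=fracs.get)
        if fracs[hi_g] - fracs[lo_g] <= 0.05:
            break
        # raise the low group: move one task scan from a 3-task subject to
        # a 1-task subject (counts per task preserved)
        h = per_group[lo_g]
        counts = h.sum(axis=1)
        donors = np.flatnonzero(counts >= 3)
        receivers = np.flatnonzero(counts == 1)
        moved = False
        for d in donors:
            for r in receivers:
                movable = np.flatnonzero(h[d] & ~h[r])
                if movable.size:
                    ti = int(movable[0])
                    h[d, ti] = False
                    h[r, ti] = True
                    moved = True
                    break
            if moved:
                break
        if not moved:
            # lower the high group instead: consolidate scans onto fewer subjects
            h = per_group[hi_g]
            counts = h.sum(axis=1)
            two = np.flatnonzero(counts == 2)
            one = np.flatnonzero(counts == 1)
            moved2 = False
            for r in two:
                for d in one:
                    movable = np.flatnonzero(h[d] & ~h[r])
                    if movable.size:
                        ti = int(movable[0])
                        h[d, ti] = False
                        h[r, ti] = True
                        moved2 = True
                        break
                if moved2:
                    break
            if not moved2:
                break

    for g in spec.groups:
        sids = [s for s in truth.subject_ids if truth.subject_groups[s] == g]
        have = per_group[g]
        for si, sid in enumerate(sids):
            row = {"subject_id": sid, "group": g, "rest": True}
            for ti, t in enumerate(spec.tasks):
                row[t] = bool(have[si, ti])
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, truth: GroundTruth) -> Cohort:
    """Draw every subject's rest and available task scans.

    Rest scans come from the subject's jittered baseline precision; task
    scans from the same precision additively perturbed on that group's
    planted edges for that task (re-regularized to positive-definite),
    plus white observation noise. Deterministic given spec and truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    participants = _assign_scans(spec, truth, rng)
    timeseries: dict[tuple[str, str], np.ndarray] = {}
    for _, row in participants.iterrows():
        sid = row["subject_id"]
        g = row["group"]
        p_subj = _subject_precision(truth, spec, sid)
        scan_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 404, zlib.crc32(sid.encode())])
        )
        timeseries[(sid, "rest")] = _sample_scan(p_subj, spec, scan_rng)
        for t in spec.tasks:
            if not row[t]:
                continue
            p_task = _regularize(p_subj + truth.delta_matrix(g, t))
            timeseries[(sid, t)] = _sample_scan(p_task, spec, scan_rng)
    return Cohort(spec=spec, truth=truth, participants=participants, timeseries=timeseries)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write timeseries, participants, atlas and ground-truth JSON to disk."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for (sid, scan), ts in cohort.timeseries.items():
        np.savetxt(out / "timeseries" / f"{sid}_{scan}.txt", ts, fmt="%.6f")
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    atlas = pd.DataFrame(
        {"index": range(cohort.spec.n_regions),
         "label": [f"region{k:03d}" for k in range(cohort.spec.n_regions)]}
    )
    atlas.to_csv(out / "atlas.tsv", sep="\t", index=False)
    gt = {
        "calibration": cohort.truth.calibration,
        "planted": {
            g: {
                cls: [
                    {
                        "i": e.i, "j": e.j, "tasks": list(e.tasks),
                        "amplitude": e.amplitude, "delta": e.delta,
                        "signs": e.signs,
                    }
                    for e in edges
                ]
                for cls, edges in byclass.items()
            }
            for g, byclass in cohort.truth.planted.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
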