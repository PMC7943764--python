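"""Per-edge selection stability across bootstrap iterations.

Selection rates quantify how consistently an edge receives a label
(sensitive, P_all, P_mix or P_single) in a group across bootstrap
subsamples, and shared selection rates count the iterations in which two
groups label the edge simultaneously. The difference in selection rates
between two groups is an edge's *uniqueness* and its shared rate its
*shareability*; together they place every edge inside a triangle whose
apex is "always selected in both groups" and whose lower corners are
"always selected in one group only". A reproducible-edge report extracts
the shared core and the group-preferred edges with rate thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._edges import edge_index

__all__ = [
    "selection_rate",
    "shared_selection_rate",
    "uniqueness_shareability",
    "reproducible_edges",
    "rate_table",
]


def selection_rate(stack: np.ndarray) -> np.ndarray:
    """Fraction of bootstrap iterations in which each edge held the label.

    ``stack`` is a (n_iterations, n_edges) boolean array from the observed
    bootstrap stream; requires at least 100 iterations.
    """
    stack = np.asarray(stack, dtype=bool)
    if stack.ndim != 2 or stack.shape[0] < 100:
        raise ValueError("need a (>=100 iterations, n_edges) boolean stack")
    return stack.mean(axis=0)


def shared_selection_rate(stack_a: np.ndarray, stack_b: np.ndarray) -> np.ndarray:
    """Fraction of iterations in which both groups held the label
    simultaneously (within the same iteration, not a product of marginals)."""
    a = np.asarray(stack_a, dtype=bool)
    b = np.asarray(stack_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("selection stacks must share shape")
    return (a & b).mean(axis=0)


def uniqueness_shareability(
    rates_a: np.ndarray, rates_b: np.ndarray, shared_ab: np.ndarray
) -> np.ndarray:
    """Per-edge (x, y) triangle coordinates for one group pair.

    x = rate_A - rate_B (signed uniqueness), y = shared rate
    (shareability). Because the shared rate can never exceed either
    marginal rate, every edge satisfies y <= 1 - |x|.
    """
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    shared_ab = np.asarray(shared_ab, dtype=float)
    if not (rates_a.shape == rates_b.shape == shared_ab.shape):
        raise ValueError("rate vectors must share one edge universe")
    if np.any(shared_ab > np.minimum(rates_a, rates_b) + 1e-12):
        raise ValueError("shared rate exceeds a marginal selection rate")
    return np.column_stack([rates_a - rates_b, shared_ab])


@dataclass
class ReproducibleEdges:
    """Reproducibly selected edges for one group pair."""

    shared_core: np.ndarray  # edge ids
    preferred_by_a: np.ndarray
    preferred_by_b: np.ndarray
    selection_floor: float
    diff_band: float


def reproducible_edges(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    selection_floor: float = 0.5,
    diff_band: float = 0.25,
    require_both: bool = False,
) -> ReproducibleEdges:
    """Extract reproducibly used edges for a group pair.

    shared_core: selected in more than ``selection_floor`` of bootstraps
    (in at least one group by default, in both with ``require_both=True``)
    with an absolute rate difference below ``diff_band``. preferred_by_*:
    above the floor in that group with the signed rate difference
    exceeding ``diff_band`` toward it.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    diff = a - b
    if require_both:
        above = (a > selection_floor) & (b > selection_floor)
    else:
        above = np.maximum(a, b) > selection_floor
    core = above & (np.abs(diff) < diff_band)
    pref_a = (a > selection_floor) & (diff > diff_band)
    pref_b = (b > selection_floor) & (-diff > diff_band)
    return ReproducibleEdges(
        shared_core=np.flatnonzero(core),
        preferred_by_a=np.flatnonzero(pref_a),
        preferred_by_b=np.flatnonzero(pref_b),
        selection_floor=selection_floor,
        diff_band=diff_band,
    )


def rate_table(
    stacks: dict[str, dict[str, np.ndarray]],
    n_regions: int,
    row: str,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate per-edge rates for one label row across all groups and pairs.

    Columns: edge_id, region_i, region_j (+ labels), rate per group,
    shared rate and (x, y) coordinates per group pair.
    """
    groups = list(stacks)
    i, j = edge_index(n_regions)
    data: dict[str, np.ndarray] = {
        "edge_id": np.arange(i.size),
        "region_i": i,
        "region_j": j,
    }
    if region_labels is not None:
        data["label_i"] = np.asarray(region_labels, dtype=object)[i]
        data["label_j"] = np.asarray(region_labels, dtype=object)[j]
    rates = {g: selection_rate(stacks[g][row]) for g in groups}
    for g in groups:
        data[f"rate_{g}"] = rates[g]
    for ai in range(len(groups)):
        for bi in range(ai + 1, len(groups)):
            ga, gb = groups[ai], groups[bi]
            sh = shared_selection_rate(stacks[ga][row], stacks[gb][row])
            xy = uniqueness_shareability(rates[ga], rates[gb], sh)
            data[f"shared_{ga}_{gb}"] = sh
            data[f"x_{ga}_{gb}"] = xy[:, 0]
            data[f"y_{ga}_{gb}"] = xy[:, 1]
    return pd.DataFrame(data)
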