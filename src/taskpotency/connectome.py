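"""Per-scan connectivity estimation.

One scan's region-by-time matrix is converted into a normalized Fisher-Z
partial-correlation matrix in three steps:

1. partial correlation from a Ledoit-Wolf shrinkage-regularized precision
   matrix (well defined even when timepoints < regions),
2. Fisher-Z (atanh) variance stabilization,
3. normalization against a fitted central-Gaussian null: the mixture model
   in :mod:`taskpotency.mixture` fits the bulk of the edge distribution and
   the central component is used as the normal reference, absorbing
   residual autocorrelation into its scale.

Normalization is per scan and per subject; no information is shared across
subjects or conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from ._edges import matrix_to_edges
from .mixture import NullFit, fit_null

__all__ = [
    "ConnectivityMatrix",
    "partial_correlation",
    "fisher_z",
    "normalize",
    "scan_connectivity",
]


@dataclass
class ConnectivityMatrix:
    """Normalized Fisher-Z partial-correlation connectome of one scan.

    ``values`` is symmetric with zero diagonal; the diagonal carries no
    information and is excluded from every edge statistic. ``normalization``
    records the fitted null used as the normal reference.
    """

    values: np.ndarray
    normalization: NullFit | None = None

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        return matrix_to_edges(self.values)


def partial_correlation(timeseries: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of one scan.

    Parameters
    ----------
    timeseries : (n_regions, n_timepoints) array
        One scan's region-by-time data.

    Returns
    -------
    (n_regions, n_regions) array
        Symmetric partial correlations in [-1, 1], unit diagonal. The
        precision matrix is obtained from a Ledoit-Wolf shrunk covariance,
        then r_ij = -p_ij / sqrt(p_ii * p_jj).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (regions x timepoints)")
    n_regions, n_timepoints = ts.shape
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_timepoints < 2:
        raise ValueError("need more than one timepoint")
    if not np.all(np.isfinite(ts)):
        raise ValueError("timeseries contains non-finite values")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"region(s) {dead.tolist()} have zero variance (constant signal)"
        )

    lw = LedoitWolf(assume_centered=False).fit(ts.T)
    prec = lw.precision_
    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    r = 0.5 * (r + r.T)  # symmetrize away numerical asymmetry
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float, eps: float = 1e-7) -> np.ndarray | float:
    """Fisher-Z (atanh) transform, elementwise.

    Values with ``|r| >= 1`` are clipped to ``1 - eps`` (with a warning)
    so the transform stays finite; the diagonal of a correlation matrix
    should be excluded by the caller.
    """
    arr = np.asarray(r, dtype=float)
    clipped = np.abs(arr) >= 1.0
    if np.any(clipped):
        warnings.warn(
            f"{int(clipped.sum())} correlation value(s) with |r| >= 1 clipped to 1 - {eps}",
            RuntimeWarning,
            stacklevel=2,
        )
        arr = np.clip(arr, -1.0 + eps, 1.0 - eps)
    out = np.arctanh(arr)
    return out if isinstance(r, np.ndarray) else float(out)


def normalize(z_matrix: np.ndarray, fit: NullFit) -> ConnectivityMatrix:
    """Standardize a Fisher-Z matrix against its fitted null component.

    z*_ij = (z_ij - mu_null) / sigma_null elementwise off the diagonal;
    after this the null part of the distribution has mean 0 and SD 1 by
    construction.
    """
    if fit.sigma_null <= 0:
        raise ValueError("sigma_null must be positive")
    z = np.asarray(z_matrix, dtype=float)
    out = (z - fit.mu_null) / fit.sigma_null
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(values=out, normalization=fit)


def scan_connectivity(timeseries: np.ndarray, min_values: int = 100) -> ConnectivityMatrix:
    """Full per-scan pipeline: partial correlation -> Fisher-Z -> normalize."""
    r = partial_correlation(timeseries)
    z_edges = fisher_z(matrix_to_edges(r))
    fit = fit_null(z_edges, min_values=min_values)
    n = r.shape[0]
    z = np.zeros_like(r)
    i, j = np.triu_indices(n, k=1)
    z[i, j] = z_edges
    z[j, i] = z_edges
    return normalize(z, fit)
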