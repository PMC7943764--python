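"""Canonical edge indexing for region-by-region matrices.

Edges are the strict upper triangle in row-major order, 0-based. Every
edge-indexed collection in the package (selection flags, class labels,
bootstrap stacks, TSV reports) uses this ordering.
"""

from __future__ import annotations

import numpy as np


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, row-major."""
    return np.triu_indices(n_regions, k=1)


def matrix_to_edges(matrix: np.ndarray) -> np.ndarray:
    """Extract the canonical edge vector from a square symmetric matrix."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    i, j = edge_index(matrix.shape[0])
    return matrix[i, j]


def edges_to_matrix(values: np.ndarray, n_regions: int, diag: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix from a canonical edge vector."""
    values = np.asarray(values)
    if values.shape[0] != n_edges(n_regions):
        raise ValueError(
            f"edge vector length {values.shape[0]} does not match "
            f"{n_regions} regions ({n_edges(n_regions)} edges)"
        )
    out = np.full((n_regions, n_regions), diag, dtype=float)
    i, j = edge_index(n_regions)
    out[i, j] = values
    out[j, i] = values
    return out


def edge_id(i: int, j: int, n_regions: int) -> int:
    """Canonical id of the edge joining regions i < j."""
    if not (0 <= i < j < n_regions):
        raise ValueError(f"need 0 <= i < j < n_regions, got ({i}, {j})")
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)
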