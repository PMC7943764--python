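"""Gaussian-plus-tails mixture model for null calibration and thresholding.

Edge-value distributions (Fisher-Z partial correlations, or group-mean
potency values) are modelled as a central Gaussian carrying the null edges
plus two Gamma tails mirrored about the distribution centre carrying the
signal. The fitted central component provides the normal reference used to
normalize connectomes, and the point where the non-null posterior passes
0.5 provides two-tailed sensitivity cutoffs.

The EM fit is fully deterministic: it is initialized from robust moments
(median / scaled MAD) and uses no random numbers. Fitting is implemented
as a batched kernel over columns so the bootstrap can refit thresholds for
every group-by-task cell of every iteration at acceptable cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["NullFit", "fit_null", "fit_null_batch"]

_MAD_TO_SD = 1.4826  # consistency factor for a Gaussian

# Gamma shapes are kept > 1 so tail densities vanish at the anchor instead
# of diverging into the central component.
_SHAPE_MIN, _SHAPE_MAX = 1.01, 300.0


@dataclass
class NullFit:
    """Fitted parameters of the central-Gaussian null reference.

    Attributes
    ----------
    mu_null, sigma_null : float
        Location and scale of the central Gaussian.
    tail_weights : tuple of float
        Mixing proportions (null, negative tail, positive tail); sums to 1.
    converged : bool
        False when EM failed and the robust median/MAD fallback was used.
    n_iterations : int
        EM iterations actually run.
    """

    mu_null: float
    sigma_null: float
    tail_weights: tuple[float, float, float]
    converged: bool
    n_iterations: int
    anchor: float
    gamma_neg: tuple[float, float] = field(default=(2.0, 1.0))  # shape, scale
    gamma_pos: tuple[float, float] = field(default=(2.0, 1.0))

    def __post_init__(self) -> None:
        if self.sigma_null <= 0:
            raise ValueError("sigma_null must be positive")
        if abs(sum(self.tail_weights) - 1.0) > 1e-6:
            raise ValueError("mixing proportions must sum to 1")


def _robust_location_scale(x: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(x, axis=axis)
    mad = np.median(np.abs(x - med), axis=axis) * _MAD_TO_SD
    return med, np.maximum(mad, 1e-12)


def _gamma_pdf(y: np.ndarray, shape: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Gamma density, zero for y <= 0; vectorized over trailing axes."""
    pos = y > 0
    ym = np.where(pos, y, 1.0)
    with np.errstate(over="ignore"):
        logpdf = (
            (shape - 1.0) * np.log(ym)
            - ym / scale
            - gammaln(shape)
            - shape * np.log(scale)
        )
        out = np.where(pos, np.exp(np.minimum(logpdf, 700.0)), 0.0)
    return out


def _norm_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


class _BatchFit:
    """Raw parameter arrays for a batch of independent mixture fits."""

    __slots__ = (
        "anchor", "mu", "sigma", "weights",
        "shape_neg", "scale_neg", "shape_pos", "scale_pos",
        "converged", "n_iter",
    )

    def __init__(self, k: int):
        self.anchor = np.zeros(k)
        self.mu = np.zeros(k)
        self.sigma = np.ones(k)
        self.weights = np.zeros((3, k))  # rows: null, neg tail, pos tail
        self.shape_neg = np.full(k, 2.0)
        self.scale_neg = np.ones(k)
        self.shape_pos = np.full(k, 2.0)
        self.scale_pos = np.ones(k)
        self.converged = np.zeros(k, dtype=bool)
        self.n_iter = np.zeros(k, dtype=int)


def _em_batch(
    X: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> _BatchFit:
    """EM fit of (central Gaussian + mirrored Gamma tails) per column of X.

    The Gamma tails live on (x - anchor) and (anchor - x) with the anchor
    frozen at the per-column median, so the fit is location-equivariant and
    deterministic. Columns are dropped from the working set as they
    converge, which keeps large batches cheap.
    """
    n, k = X.shape
    fit = _BatchFit(k)
    med, mad = _robust_location_scale(X, axis=0)
    fit.anchor = med
    fit.mu = med.copy()
    fit.sigma = mad.copy()
    # moment-based deterministic init: tail weights from the robust
    # exceedance fractions beyond 2.5 robust SDs (floored so the tail
    # components stay alive), Gamma tails starting at shape 3, scale MAD
    frac_pos = np.maximum((X > med + 2.5 * mad).mean(axis=0), 0.005)
    frac_neg = np.maximum((X < med - 2.5 * mad).mean(axis=0), 0.005)
    fit.weights[0] = 1.0 - frac_pos - frac_neg
    fit.weights[1] = frac_neg
    fit.weights[2] = frac_pos
    fit.shape_neg[:] = fit.shape_pos[:] = 3.0
    fit.scale_neg = mad.copy()
    fit.scale_pos = mad.copy()

    sqrt2pi = np.sqrt(2.0 * np.pi)
    # active working set: compact views of the still-unconverged columns
    idx = np.arange(k)
    Xa = X
    y_pos = Xa - med
    y_neg = -y_pos
    pos_mask = y_pos > 0
    neg_mask = y_neg > 0
    log_y_pos = np.where(pos_mask, np.log(np.where(pos_mask, y_pos, 1.0)), 0.0)
    log_y_neg = np.where(neg_mask, np.log(np.where(neg_mask, y_neg, 1.0)), 0.0)
    mu, sigma = fit.mu.copy(), fit.sigma.copy()
    w = fit.weights.copy()
    a_n, b_n = fit.shape_neg.copy(), fit.scale_neg.copy()
    a_p, b_p = fit.shape_pos.copy(), fit.scale_pos.copy()
    prev_ll = np.full(k, -np.inf)

    for it in range(1, max_iter + 1):
        z = (Xa - mu) / sigma
        f0 = w[0] / (sigma * sqrt2pi) * np.exp(-0.5 * z * z)
        with np.errstate(over="ignore"):
            lp1 = (a_n - 1.0) * log_y_neg - y_neg / b_n - gammaln(a_n) - a_n * np.log(b_n)
            f1 = w[1] * np.where(neg_mask, np.exp(np.minimum(lp1, 700.0)), 0.0)
            lp2 = (a_p - 1.0) * log_y_pos - y_pos / b_p - gammaln(a_p) - a_p * np.log(b_p)
            f2 = w[2] * np.where(pos_mask, np.exp(np.minimum(lp2, 700.0)), 0.0)
        tot = f0 + f1 + f2 + 1e-300
        ll = np.log(tot).mean(axis=0)

        g0, g1, g2 = f0 / tot, f1 / tot, f2 / tot
        s0 = g0.sum(axis=0) + 1e-12
        s1 = g1.sum(axis=0)
        s2 = g2.sum(axis=0)
        w = np.vstack((s0 / n, s1 / n, s2 / n))
        mu = (g0 * Xa).sum(axis=0) / s0
        var0 = (g0 * (Xa - mu) ** 2).sum(axis=0) / s0
        sigma = np.sqrt(np.maximum(var0, 1e-20))
        for gam, sg, yv, which in ((g1, s1, y_neg, 0), (g2, s2, y_pos, 1)):
            ok = sg > 1e-8
            with np.errstate(invalid="ignore", divide="ignore"):
                m1 = (gam * yv).sum(axis=0) / np.maximum(sg, 1e-12)
                v = (gam * (yv - m1) ** 2).sum(axis=0) / np.maximum(sg, 1e-12)
                m1 = np.maximum(m1, 1e-12)
                v = np.maximum(v, 1e-12)
                shape = np.clip(m1 * m1 / v, _SHAPE_MIN, _SHAPE_MAX)
                scale = np.maximum(m1 / shape, 1e-12)
            if which == 0:
                a_n = np.where(ok, shape, a_n)
                b_n = np.where(ok, scale, b_n)
            else:
                a_p = np.where(ok, shape, a_p)
                b_p = np.where(ok, scale, b_p)

        done = np.abs(ll - prev_ll[idx]) < tol
        prev_ll[idx] = ll
        newly = done & ~fit.converged[idx]
        if newly.any():
            # freeze each column's parameters the moment it converges
            cols = idx[newly]
            fit.converged[cols] = True
            fit.n_iter[cols] = it
            fit.mu[cols], fit.sigma[cols] = mu[newly], sigma[newly]
            fit.weights[:, cols] = w[:, newly]
            fit.shape_neg[cols], fit.scale_neg[cols] = a_n[newly], b_n[newly]
            fit.shape_pos[cols], fit.scale_pos[cols] = a_p[newly], b_p[newly]
        still = ~fit.converged[idx]
        if not still.any():
            break
        # compact the working set only when enough columns retired, to
        # avoid re-slicing large arrays on every iteration
        if still.mean() < 0.75:
            keep = still
            idx = idx[keep]
            Xa = Xa[:, keep]
            y_pos, y_neg = y_pos[:, keep], y_neg[:, keep]
            pos_mask, neg_mask = pos_mask[:, keep], neg_mask[:, keep]
            log_y_pos, log_y_neg = log_y_pos[:, keep], log_y_neg[:, keep]
            mu, sigma = mu[keep], sigma[keep]
            w = w[:, keep]
            a_n, b_n = a_n[keep], b_n[keep]
            a_p, b_p = a_p[keep], b_p[keep]

    # Fallback: robust central fit for non-converged columns.
    bad = ~fit.converged
    if bad.any():
        fit.n_iter[bad] = max_iter
        fit.mu[bad] = med[bad]
        fit.sigma[bad] = mad[bad]
        fit.weights[0, bad] = 1.0
        fit.weights[1, bad] = 0.0
        fit.weights[2, bad] = 0.0
    return fit


def fit_null_batch(X: np.ndarray, max_iter: int = 500, tol: float = 1e-6) -> _BatchFit:
    """Fit the null mixture independently to every column of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("fit_null_batch expects a 2-D array (values x datasets)")
    return _em_batch(X, max_iter=max_iter, tol=tol)


def fit_null(
    values: np.ndarray,
    min_values: int = 100,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NullFit:
    """Fit the central-Gaussian null reference to a set of edge values.

    Parameters
    ----------
    values : array-like
        Edge statistics (e.g. Fisher-Z partial correlations of one scan).
    min_values : int
        Minimum number of values required for a stable fit.

    Returns
    -------
    NullFit
        Central component location/scale plus tail parameters. If EM does
        not converge within ``max_iter`` iterations the robust median/MAD
        fallback is returned with ``converged=False``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < min_values:
        raise ValueError(
            f"need at least {min_values} values for a stable null fit, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("null fit input contains non-finite values")
    fit = _em_batch(values[:, None], max_iter=max_iter, tol=tol)
    if not fit.converged[0]:
        warnings.warn(
            "mixture EM did not converge; falling back to robust median/MAD null fit",
            RuntimeWarning,
            stacklevel=2,
        )
    return NullFit(
        mu_null=float(fit.mu[0]),
        sigma_null=float(fit.sigma[0]),
        tail_weights=tuple(float(w) for w in fit.weights[:, 0]),
        converged=bool(fit.converged[0]),
        n_iterations=int(fit.n_iter[0]),
        anchor=float(fit.anchor[0]),
        gamma_neg=(float(fit.shape_neg[0]), float(fit.scale_neg[0])),
        gamma_pos=(float(fit.shape_pos[0]), float(fit.scale_pos[0])),
    )
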