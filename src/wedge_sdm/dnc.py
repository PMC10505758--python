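"""Distance to niche centroid (DNC) suitability.

The niche centroid is the mean environmental vector over presence cells;
suitability at a location is a decreasing function of the Mahalanobis
distance between its environment and that centroid, with the covariance
also estimated from the presence cells.  Smaller distance = closer to the
centre of the realized niche = higher suitability; the distance is rescaled
to [0, 1] as 1 - d/d_max over the projection area so that it is directly
comparable with (and oriented like) other suitability surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass
class DNCModel:
    centroid: np.ndarray        # per-predictor mean at presences
    cov: np.ndarray             # presence covariance (ddof=1), ridged if needed
    names: list[str]
    ridged: bool = False


def fit_dnc(presence_values: np.ndarray, names: list[str] | None = None,
            cond_max: float = 1e8, ridge_eps: float = 1e-6) -> DNCModel:
    """Centroid = column means; covariance = sample covariance (n-1).

    If the covariance is ill-conditioned (condition number > cond_max) a
    small ridge eps * diag(cov) is added so the Mahalanobis metric stays
    defined.
    """
    X = np.atleast_2d(np.asarray(presence_values, dtype=float))
    n, p = X.shape
    if names is None:
        names = [f"env{k + 1}" for k in range(p)]
    if n <= p:
        raise ValueError(
            f"{n} presence rows for {p} predictors: apply stronger predictor "
            "filtering (need more rows than predictors)")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    ridged = False
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > cond_max:
        d = np.diag(cov).copy()
        d[d == 0] = 1.0
        cov = cov + ridge_eps * np.diag(d)
        ridged = True
        if np.linalg.cond(cov) > 1e12:  # still degenerate; scale ridge up
            cov = cov + np.diag(d)
    return DNCModel(mu, cov, list(names), ridged)


def mahalanobis(model: DNCModel, env_values: np.ndarray) -> np.ndarray:
    """d(x) = sqrt((x-mu)' Sigma^-1 (x-mu)) per row, via Cholesky solve."""
    X = np.atleast_2d(np.asarray(env_values, dtype=float))
    diff = X - model.centroid
    c, low = cho_factor(model.cov)
    sol = cho_solve((c, low), diff.T)
    d2 = np.einsum("ij,ji->i", diff, sol)
    return np.sqrt(np.maximum(d2, 0.0))


def dnc_suitability(distances: np.ndarray) -> np.ndarray:
    """Rescale distances over the projection area to suitability 1 - d/d_max."""
    d = np.asarray(distances, dtype=float)
    d_max = d.max()
    if d_max == 0:
        warnings.warn("constant environment: all distances zero, suitability 1")
        return np.ones_like(d)
    return 1.0 - d / d_max
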