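"""Accessible-area delimitation by trend surface analysis (TSA).

Presence-only models are calibrated inside the region the species could
plausibly have reached, not the whole continent.  The delimitation here fits
a logistic regression of presence cells against all other grid cells on a
third-degree polynomial of the planar coordinates (y plays latitude, x
longitude), then keeps every cell whose fitted probability is at least the
minimum fitted probability over the presence cells — so the accessible area
always contains every presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .grids import Grid

#: term order of the cubic trend surface: lat, long, lat*long, long*lat^2,
#: long^2*lat, lat^2, long^2, lat^3, long^3  (lat = y, long = x)
TSA_TERM_NAMES = ["lat", "long", "lat*long", "long*lat^2", "long^2*lat",
                  "lat^2", "long^2", "lat^3", "long^3"]


def tsa_features(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raw 9-term cubic trend-surface design matrix, one row per point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("coordinates must be finite")
    lat, lon = y, x
    return np.column_stack([
        lat, lon, lat * lon, lon * lat ** 2, lon ** 2 * lat,
        lat ** 2, lon ** 2, lat ** 3, lon ** 3,
    ])


@dataclass
class TSAModel:
    coef: np.ndarray            # 9 coefficients on standardized terms
    intercept: float
    term_mean: np.ndarray
    term_sd: np.ndarray
    fitted: np.ndarray          # per-cell fitted probability, cell-id order

    def predict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        z = (tsa_features(x, y) - self.term_mean) / self.term_sd
        eta = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class MaskGrid:
    """Boolean accessible-area mask with the threshold that produced it."""

    grid: Grid
    inside: np.ndarray          # (n_rows, n_cols) bool
    threshold: float

    def cells(self) -> np.ndarray:
        return np.flatnonzero(self.inside.ravel())


def fit_tsa(presence_cells: np.ndarray, grid: Grid,
            ridge: float = 1e-4) -> TSAModel:
    """Logistic regression of presence (1) vs all other cells (0) on TSA terms.

    Terms are centered and scaled internally for conditioning only; fitted
    probabilities are what downstream thresholding uses.  A small ridge
    penalty keeps the fit defined under complete spatial separation.
    """
    presence_cells = np.asarray(presence_cells)
    if presence_cells.size == 0:
        raise ValueError("need at least one presence cell")
    if presence_cells.size >= grid.n_cells:
        # degenerate: everything is a presence; constant model
        warnings.warn("all cells are presences; accessible area is the whole grid")
        fitted = np.ones(grid.n_cells)
        return TSAModel(np.zeros(9), np.inf, np.zeros(9), np.ones(9), fitted)
    centers = grid.cell_centers()
    X = tsa_features(centers[:, 0], centers[:, 1])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    y = np.zeros(grid.n_cells, dtype=int)
    y[presence_cells] = 1
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    clf.fit(Z, y)
    fitted = clf.predict_proba(Z)[:, 1]
    return TSAModel(clf.coef_[0].copy(), float(clf.intercept_[0]), mean, sd,
                    fitted)


def delimit_area(model: TSAModel, grid: Grid,
                 presence_cells: np.ndarray) -> MaskGrid:
    """Keep cells whose fitted probability >= the minimum over presences.

    The comparison is closed (>=) so the presence achieving the minimum is
    itself retained; consequently the mask always contains every presence.
    """
    presence_cells = np.asarray(presence_cells)
    threshold = float(model.fitted[presence_cells].min())
    inside = (model.fitted >= threshold).reshape(grid.n_rows, grid.n_cols)
    return MaskGrid(grid, inside, threshold)
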