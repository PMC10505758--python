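"""Occurrence gridding and predictor collinearity reduction.

Two filters are applied before suitability modelling: a stepwise variance
inflation factor (VIF) filter computed on the accessible-area cells, and a
greedy Spearman-correlation filter computed on the presence cells (used by
the distance-to-niche-centroid model, which is especially sensitive to
redundant axes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .grids import Grid

log = logging.getLogger(__name__)


@dataclass
class PredictorSelection:
    """Outcome of a collinearity filter."""

    retained: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    # each dropped entry: (name, reason in {"vif", "correlation"}, statistic)

    def report(self) -> pd.DataFrame:
        rows = [{"name": n, "retained": True, "reason": "", "statistic": np.nan}
                for n in self.retained]
        rows += [{"name": n, "retained": False, "reason": r, "statistic": s}
                 for n, r, s in self.dropped]
        return pd.DataFrame(rows)


def gridify(points: pd.DataFrame, grid: Grid) -> tuple[pd.DataFrame, int]:
    """Map occurrence points to grid cells, one record per (species, cell).

    Points are columns (species, x, y); cells are half-open squares, so a
    point on a shared edge goes to the cell whose low corner it touches.
    Out-of-bounds points are skipped and counted.  Returns (table, n_skipped).
    """
    cell = grid.point_to_cell(points["x"].to_numpy(), points["y"].to_numpy())
    ok = cell >= 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.warning("gridify: skipped %d out-of-bounds point(s)", n_skipped)
    table = (pd.DataFrame({"species": points["species"].to_numpy()[ok],
                           "cell_id": cell[ok]})
             .drop_duplicates()
             .reset_index(drop=True))
    return table, n_skipped


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_k = 1/(1 - R^2_k), R^2 from regressing column k on the others."""
    n, p = X.shape
    Z = X - X.mean(axis=0)
    out = np.empty(p)
    for k in range(p):
        yk = Z[:, k]
        Xk = Z[:, [j for j in range(p) if j != k]]
        tss = float(yk @ yk)
        if tss == 0:
            out[k] = np.inf
            continue
        beta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        rss = float(((yk - Xk @ beta) ** 2).sum())
        r2 = 1.0 - rss / tss
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_step(values: pd.DataFrame, threshold: float = 10.0) -> PredictorSelection:
    """Stepwise VIF filter: drop the worst predictor until all VIF <= threshold.

    Perfectly collinear predictors have infinite VIF and are dropped first.
    Deterministic given column order (ties drop the later column).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if values.shape[0] < values.shape[1]:
        raise ValueError("need at least as many rows as predictors")
    names = list(values.columns)
    dropped: list[tuple[str, str, float]] = []
    while len(names) > 1:
        v = _vif(values[names].to_numpy(dtype=float))
        worst = int(np.flatnonzero(v == v.max())[-1])
        if v[worst] <= threshold:
            break
        dropped.append((names[worst], "vif", float(v[worst])))
        names.pop(worst)
    return PredictorSelection(names, dropped)


def correlation_filter(presence_values: pd.DataFrame,
                       rho_max: float = 0.8) -> PredictorSelection:
    """Greedy Spearman filter on presence-cell values.

    While any retained pair has |rho_S| > rho_max, the member of the worst
    pair with the larger mean absolute correlation against all other retained
    predictors is dropped (ties drop the later column).  Constant predictors
    have undefined rank correlation and are dropped up front as redundant.
    """
    names = list(presence_values.columns)
    dropped: list[tuple[str, str, float]] = []
    for n in list(names):
        col = presence_values[n].to_numpy(dtype=float)
        if np.all(col == col[0]):
            dropped.append((n, "correlation", np.nan))
            names.remove(n)
    while len(names) > 1:
        X = presence_values[names].to_numpy(dtype=float)
        rho = spearmanr(X).statistic
        if np.ndim(rho) == 0:  # two columns: scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
        np.fill_diagonal(rho, 0.0)
        a = np.abs(rho)
        worst = np.unravel_index(np.argmax(a), a.shape)
        if a[worst] <= rho_max:
            break
        i, j = sorted(worst)
        mean_i, mean_j = a[i].mean(), a[j].mean()
        drop = j if mean_j >= mean_i else i  # tie drops the later column
        dropped.append((names[drop], "correlation", float(a[worst[0], worst[1]])))
        names.pop(drop)
    if not names:
        raise ValueError("correlation filter removed every predictor")
    return PredictorSelection(names, dropped)
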