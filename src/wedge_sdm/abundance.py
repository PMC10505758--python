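"""Camera-trap capture rates and the suitability-abundance wedge analysis.

Capture rate (independent events per camera-day) is a relative abundance
index.  Because suitability bounds the maximum rather than the mean of
abundance (the "wedge" or triangular relationship), the relationship is
quantified with linear quantile regressions of capture rate on suitability
at high percentiles: the fitted line for quantile tau estimates the
conditional tau-quantile of abundance given suitability, and the upper
quantiles trace the wedge's ceiling.

The quantile regression program is solved exactly as a linear program
(pinball / check loss), and each fit records the goodness of fit

    R1(tau) = 1 - V_full(tau) / V_intercept_only(tau)

where V is the achieved pinball loss — the quantile-regression analogue of
R-squared against the intercept-only (marginal tau-quantile) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .synth import DetectionLog

DEFAULT_TAUS = (0.60, 0.70, 0.80, 0.85, 0.90, 0.91, 0.93, 0.95, 0.97, 0.99)


# ---------------------------------------------------------------------------
# independent events and capture rates

def filter_independent(log: DetectionLog | pd.DataFrame,
                       window_h: float = 24.0) -> pd.DataFrame:
    """Reduce raw detections to independent events.

    Scanning each (species, station) stream in time order, a detection is
    counted iff it falls at least ``window_h`` hours after the last counted
    detection, or it is a multi-animal photograph (n_individuals > 1), which
    is counted once regardless of timing.  Counted events (multi-animal ones
    included) reset the clock, which makes the filter idempotent.
    """
    records = log.records if isinstance(log, DetectionLog) else log
    if len(records) and (records["timestamp_h"] < 0).any():
        raise ValueError("timestamps must be non-negative")
    out = []
    cols = ["station_id", "cell_id", "species", "timestamp_h", "n_individuals"]
    for _, grp in records.groupby(["species", "station_id"], sort=True):
        grp = grp.sort_values("timestamp_h")
        last = -np.inf
        for row in grp.itertuples(index=False):
            if row.n_individuals > 1 or row.timestamp_h - last >= window_h:
                out.append(row)
                last = row.timestamp_h
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out, columns=records.columns)[cols].reset_index(drop=True)


def capture_rate(events: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Events per camera-day by cell: rate = n_events / camera_days.

    ``effort`` has columns (station_id, cell_id, effort_days); stations in
    the same cell pool both events and effort.  Cells with effort but no
    events get rate 0; cells with no effort are absent (not zero).
    """
    days = effort.groupby("cell_id")["effort_days"].sum()
    counts = (events.groupby("cell_id").size() if len(events)
              else pd.Series(dtype=int))
    missing = set(counts.index) - set(days.index)
    if missing:
        raise ValueError(f"events recorded in cells without effort: {sorted(missing)}")
    out = pd.DataFrame({"cell_id": days.index.astype(int),
                        "camera_days": days.to_numpy(dtype=float)})
    out["n_events"] = counts.reindex(days.index).fillna(0).astype(int).to_numpy()
    out["rate"] = out["n_events"] / out["camera_days"]
    return out[["cell_id", "n_events", "camera_days", "rate"]]


# ---------------------------------------------------------------------------
# quantile regression

@dataclass
class QuantileFit:
    tau: float
    slope: float
    intercept: float
    r1: float
    n: int
    loss: float                  # achieved pinball loss of the full model
    loss_null: float             # pinball loss of the intercept-only model
    n_below: int = 0             # points strictly below the fitted line
    n_above: int = 0

    def subgradient_ok(self) -> bool:
        """Optimality bounds: at most n*tau points strictly below the line
        and at most n*(1-tau) strictly above."""
        return (self.n_below <= self.tau * self.n + 1e-9
                and self.n_above <= (1 - self.tau) * self.n + 1e-9)


def pinball_loss(u: np.ndarray, tau: float) -> float:
    """rho_tau(u) = u * (tau - 1{u < 0}), summed."""
    u = np.asarray(u, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _qr_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact LP solution of min sum rho_tau(y - X beta); X includes intercept."""
    n, p = X.shape
    # variables: beta+ (p), beta- (p), u+ (n), u- (n)
    c = np.concatenate([np.zeros(2 * p), np.full(n, tau), np.full(n, 1 - tau)])
    eye = sp.eye(n, format="csc")
    A_eq = sp.hstack([sp.csc_matrix(X), -sp.csc_matrix(X), eye, -eye],
                     format="csc")
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p] - res.x[p:2 * p]


def quantile_fit(x: np.ndarray, y: np.ndarray, tau: float) -> QuantileFit:
    """Linear quantile regression of y on x at quantile tau (exact LP)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly between 0 and 1")
    if np.all(x == x[0]):
        raise ValueError("all x identical: slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    b0, b1 = _qr_lp(X, y, tau)
    resid = y - b0 - b1 * x
    loss = pinball_loss(resid, tau)
    c0 = _qr_lp(np.ones((x.size, 1)), y, tau)[0]
    loss_null = pinball_loss(y - c0, tau)
    r1 = 0.0 if loss_null == 0 else 1.0 - loss / loss_null
    tol = 1e-9 * max(1.0, float(np.abs(y).max()))
    return QuantileFit(tau, float(b1), float(b0), float(r1), int(x.size),
                       loss, loss_null,
                       n_below=int((resid < -tol).sum()),
                       n_above=int((resid > tol).sum()))


def wedge_profile(x: np.ndarray, y: np.ndarray,
                  taus: tuple[float, ...] = DEFAULT_TAUS) -> list[QuantileFit]:
    """One quantile fit per tau on the same data."""
    return [quantile_fit(x, y, t) for t in taus]


@dataclass
class QuantileSelection:
    selected: QuantileFit
    positive_wedge: bool
    table: pd.DataFrame = field(repr=False)


def select_quantile(fits: list[QuantileFit],
                    r1_tie: float = 0.005) -> QuantileSelection:
    """Pick the quantile giving the best upper bound of the response.

    Among fits with positive slope, rank by R1 (descending); fits within
    ``r1_tie`` of the best R1 are tie-broken by larger slope, then smaller
    |intercept|.  If no fit has positive slope, the max-R1 fit is returned
    flagged as "no positive wedge".
    """
    if not fits:
        raise ValueError("no fits to select from")
    table = pd.DataFrame([{
        "tau": f.tau, "r1": f.r1, "slope": f.slope, "intercept": f.intercept,
        "n": f.n} for f in fits])
    pos = [f for f in fits if f.slope > 0]
    if not pos:
        best = max(fits, key=lambda f: f.r1)
        return QuantileSelection(best, False, table)
    best_r1 = max(f.r1 for f in pos)
    contenders = [f for f in pos if best_r1 - f.r1 < r1_tie]
    best_slope = max(f.slope for f in contenders)
    contenders = [f for f in contenders if f.slope == best_slope]
    best = min(contenders, key=lambda f: abs(f.intercept))
    return QuantileSelection(best, True, table)
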