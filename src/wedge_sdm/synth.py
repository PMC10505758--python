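"""Synthetic virtual-species studies with known ground truth.

This module generates everything a presence-only suitability study needs —
smooth, partially collinear environmental layers; a virtual species whose
true suitability is a known function of those layers; spatially biased
occurrence sampling; abundance that is wedge-constrained by suitability; and
camera-trap detection streams whose rate is proportional to local abundance
— so that every downstream stage (accessible area, predictor filters,
suitability models, validation, wedge regression) can be tested against a
ground truth that real studies never have.

Smooth fields are white noise convolved with an isotropic Gaussian kernel;
collinear layer pairs are built by mixing a shared field with independent
noise.  Abundance follows the multiplicative-uniform wedge: each cell's
abundance is Uniform(0,1) times a linear ceiling ``a + b * suitability``, so
suitability bounds the maximum, not the mean, of abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import EnvStack, Grid

__all__ = [
    "LandscapeConfig",
    "VirtualSpeciesTruth",
    "DetectionLog",
    "generate_env_stack",
    "generate_bias_layer",
    "make_truth",
    "sample_occurrences",
    "simulate_abundance",
    "simulate_cameras",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    smoothness is the spatial correlation length in cells (Gaussian kernel
    sigma); collinearity is the target pairwise correlation induced between
    each designated layer pair.
    """

    n_rows: int = 100
    n_cols: int = 100
    n_layers: int = 5
    smoothness: float = 3.0
    collinearity: float = 0.0
    collinear_pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("grid dimensions must be >= 10")
        if self.n_layers < 3:
            raise ValueError("need at least 3 predictor layers")
        if not 0.0 <= self.collinearity < 1.0:
            raise ValueError("collinearity must lie in [0, 1)")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        for i, j in self.collinear_pairs:
            if not (0 <= i < self.n_layers and 0 <= j < self.n_layers) or i == j:
                raise ValueError(f"invalid collinear pair ({i}, {j})")


@dataclass
class VirtualSpeciesTruth:
    """Known niche and wedge parameters of the simulated species."""

    env: EnvStack
    niche_center: np.ndarray
    niche_widths: np.ndarray
    true_suitability: np.ndarray  # (n_rows, n_cols), values in [0, 1]
    wedge_intercept: float = 0.0
    wedge_slope: float = 1.0

    def suitability_flat(self) -> np.ndarray:
        return self.true_suitability.ravel()


@dataclass
class DetectionLog:
    """Raw camera-trap detections plus per-station effort.

    records: DataFrame (station_id, cell_id, species, timestamp_h,
    n_individuals); effort: DataFrame (station_id, cell_id, effort_days).
    """

    records: pd.DataFrame
    effort: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.records) and (self.records["timestamp_h"] < 0).any():
            raise ValueError("timestamps must be non-negative")
        if (self.effort["effort_days"] <= 0).any():
            raise ValueError("effort_days must be positive")


def _smooth_field(shape: tuple[int, int], sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_env_stack(config: LandscapeConfig) -> EnvStack:
    """Generate smooth, standardized predictor layers; deterministic per seed.

    Each designated pair (i, j) is made collinear by rewriting layer j as
    rho * layer_i + sqrt(1 - rho^2) * layer_j, which gives the pair a sample
    correlation close to rho (exactly rho in expectation for Gaussian
    fields).
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    layers = [_smooth_field(shape, config.smoothness, rng)
              for _ in range(config.n_layers)]
    rho = config.collinearity
    if rho > 0:
        for i, j in config.collinear_pairs:
            mixed = rho * layers[i] + np.sqrt(1 - rho ** 2) * layers[j]
            mixed -= mixed.mean()
            layers[j] = mixed / mixed.std()
    grid = Grid(config.n_rows, config.n_cols)
    names = [f"env{k + 1}" for k in range(config.n_layers)]
    return EnvStack(grid, names, np.stack(layers))


def generate_bias_layer(config: LandscapeConfig, strength: float = 1.0,
                        seed: int | None = None) -> np.ndarray:
    """Positive sampling-effort surface, exp(strength * smooth field).

    strength 0 gives a uniform layer.  Emulates an accessibility / human
    footprint surface used both to bias occurrence collection and to place
    background points.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    if strength == 0:
        return np.ones((config.n_rows, config.n_cols))
    z = _smooth_field((config.n_rows, config.n_cols), config.smoothness, rng)
    return np.exp(strength * z)


def make_truth(env: EnvStack, niche_center, niche_widths,
               a: float = 0.0, b: float = 1.0) -> VirtualSpeciesTruth:
    """Product-Gaussian niche: s(x) = exp(-sum_k ((x_k - c_k)/w_k)^2 / 2).

    Suitability is exactly 1 where all predictors sit at the niche center
    and decays monotonically with distance from it along each axis.
    """
    center = np.asarray(niche_center, dtype=float)
    widths = np.asarray(niche_widths, dtype=float)
    if center.shape != (env.n_layers,) or widths.shape != (env.n_layers,):
        raise ValueError("niche center/widths must have one entry per layer")
    if (widths <= 0).any():
        raise ValueError("niche widths must be positive")
    if b <= 0:
        raise ValueError("wedge slope b must be positive")
    z = (env.data - center[:, None, None]) / widths[:, None, None]
    s = np.exp(-0.5 * (z ** 2).sum(axis=0))
    return VirtualSpeciesTruth(env, center, widths, s, float(a), float(b))


def sample_occurrences(truth: VirtualSpeciesTruth, bias_layer: np.ndarray,
                       n: int, seed: int,
                       species: str = "virtual_felid") -> pd.DataFrame:
    """Draw n presence cells without replacement, P(cell) ∝ suitability × bias.

    Mirrors opportunistic occurrence collection: records accumulate where the
    species is (suitability) and where people look (bias), and are then
    deduplicated to one presence per grid cell.  Returns a DataFrame
    (species, x, y, cell_id) with cell-center coordinates.
    """
    bias = np.asarray(bias_layer, dtype=float).ravel()
    if (bias < 0).any() or bias.sum() == 0:
        raise ValueError("bias layer must be non-negative with positive mass")
    w = truth.suitability_flat() * bias
    positive = np.flatnonzero(w > 0)
    if n > positive.size:
        raise ValueError(
            f"cannot draw {n} cells: only {positive.size} have positive probability")
    rng = np.random.default_rng(seed)
    p = w[positive] / w[positive].sum()
    cells = rng.choice(positive, size=n, replace=False, p=p)
    xy = truth.env.grid.cell_centers(cells)
    return pd.DataFrame({"species": species, "x": xy[:, 0], "y": xy[:, 1],
                         "cell_id": cells})


def simulate_abundance(truth: VirtualSpeciesTruth, seed: int) -> np.ndarray:
    """Wedge-constrained abundance: N_i = U_i * (a + b * s_i), U ~ Unif(0,1).

    By construction no cell exceeds its ceiling a + b*s, and the conditional
    upper bound of abundance on suitability is exactly the line (a, b) —
    the triangular pattern the quantile-regression analysis targets.
    """
    rng = np.random.default_rng(seed)
    s = truth.true_suitability
    u = rng.uniform(size=s.shape)
    return u * (truth.wedge_intercept + truth.wedge_slope * s)


def simulate_cameras(abundance: np.ndarray, grid: Grid, n_stations: int,
                     effort_days: float, rate_scale: float, seed: int,
                     species: str = "virtual_felid",
                     multi_individual_prob: float = 0.05,
                     station_cells: np.ndarray | None = None) -> DetectionLog:
    """Simulate camera-trap detection streams at randomly placed stations.

    Each station sits on a distinct grid cell and records detections as a
    homogeneous Poisson process with rate ``rate_scale * abundance(cell)``
    per day over ``effort_days``; detection times are in hours since
    deployment.  A detection is a multi-animal photograph (n_individuals=2)
    with probability ``multi_individual_prob``.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be >= 0")
    if effort_days <= 0:
        raise ValueError("effort_days must be positive")
    rng = np.random.default_rng(seed)
    flat = np.asarray(abundance, dtype=float).ravel()
    if station_cells is None:
        if n_stations > grid.n_cells:
            raise ValueError("more stations than grid cells")
        station_cells = rng.choice(grid.n_cells, size=n_stations, replace=False)
    else:
        station_cells = np.asarray(station_cells)
        if len(np.unique(station_cells)) != len(station_cells):
            raise ValueError("stations must occupy distinct cells")
    rows = []
    for k, cell in enumerate(station_cells):
        lam = rate_scale * flat[cell] * effort_days
        n_det = rng.poisson(lam)
        if n_det == 0:
            continue
        times = np.sort(rng.uniform(0, effort_days * 24.0, size=n_det))
        n_ind = np.where(rng.uniform(size=n_det) < multi_individual_prob, 2, 1)
        for t, ni in zip(times, n_ind):
            rows.append((f"st{k:04d}", int(cell), species, float(t), int(ni)))
    records = pd.DataFrame(
        rows, columns=["station_id", "cell_id", "species", "timestamp_h",
                       "n_individuals"])
    effort = pd.DataFrame({
        "station_id": [f"st{k:04d}" for k in range(len(station_cells))],
        "cell_id": station_cells.astype(int),
        "effort_days": float(effort_days),
    })
    return DetectionLog(records, effort)
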