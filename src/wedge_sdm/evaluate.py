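"""Replicate validation (AUC) and between-algorithm agreement (weighted kappa).

AUC is the rank-based Mann-Whitney estimator: the probability that a random
presence scores above a random background point, counting ties as one half.
Agreement between two suitability surfaces is Cohen's weighted kappa on
quantile-based ordinal categories of each map, with disagreement weights
growing with the distance between categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, norm


# ---------------------------------------------------------------------------
# replicate splits

@dataclass(frozen=True)
class ReplicateSplit:
    replicate: int
    train: np.ndarray
    test: np.ndarray


def split_replicates(cells: np.ndarray, frac: float = 0.7, R: int = 10,
                     seed: int | np.random.Generator = 0) -> list[ReplicateSplit]:
    """R independent random train/test partitions at fraction frac.

    Train size is floor(frac * n); test gets the remainder.  Deterministic
    given the seed.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    cells = np.asarray(cells)
    if cells.size < 10:
        raise ValueError("need at least 10 presences to split")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(frac * cells.size))
    out = []
    for r in range(1, R + 1):
        perm = rng.permutation(cells)
        out.append(ReplicateSplit(r, np.sort(perm[:n_train]),
                                  np.sort(perm[n_train:])))
    return out


# ---------------------------------------------------------------------------
# AUC

def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """P(presence score > background score) + 0.5 P(tie); Mann-Whitney form."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (pos.size * neg.size)


# ---------------------------------------------------------------------------
# quantile categories and weighted kappa

def quantile_categorize(values: np.ndarray, k: int = 4) -> np.ndarray:
    """Ordinal categories 1..k from the map's own k-quantile breaks.

    A value equal to a break goes to the lower category.  A constant map
    yields all-1 with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    v = np.asarray(values, dtype=float)
    if np.all(v == v.ravel()[0]):
        warnings.warn("constant map: single category")
        return np.ones(v.shape, dtype=int)
    breaks = np.quantile(v, np.arange(1, k) / k)
    return 1 + (v[..., None] > breaks).sum(axis=-1)


@dataclass
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    k: int
    scheme: str
    se: float


def weighted_kappa(cat_a: np.ndarray, cat_b: np.ndarray, k: int | None = None,
                   scheme: str = "linear",
                   conf_level: float = 0.95) -> AgreementResult:
    """Cohen's weighted kappa for ordinal categories 1..k.

    kappa_w = 1 - sum(w * O) / sum(w * E) with disagreement weights
    w_ij = |i-j|/(k-1) (linear) or (|i-j|/(k-1))^2 (quadratic), O the
    observed and E the chance-expected (marginal-product) proportions.
    The CI uses the large-sample standard error of weighted kappa
    (Fleiss-Cohen-Everitt form).
    """
    a = np.asarray(cat_a).ravel()
    b = np.asarray(cat_b).ravel()
    if a.shape != b.shape:
        raise ValueError("category vectors must have equal length")
    kmax = int(max(a.max(), b.max()))
    if k is None:
        k = kmax
    elif kmax > k:
        raise ValueError(f"found category {kmax} > declared k={k}")
    if a.min() < 1 or b.min() < 1:
        raise ValueError("categories must be 1-based")
    n = a.size
    O = np.zeros((k, k))
    np.add.at(O, (a - 1, b - 1), 1.0)
    O /= n
    pa, pb = O.sum(axis=1), O.sum(axis=0)
    E = np.outer(pa, pb)
    ij = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    if scheme == "linear":
        w = ij
    elif scheme == "quadratic":
        w = ij ** 2
    else:
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    denom = float((w * E).sum())
    if denom == 0:
        # no chance-expected disagreement (all mass in one category)
        return AgreementResult(1.0, 1.0, 1.0, k, scheme, 0.0)
    kappa = 1.0 - float((w * O).sum()) / denom

    # large-sample SE in terms of agreement weights v = 1 - w
    v = 1.0 - w
    v_bar = float((v * O).sum())          # observed weighted agreement
    v_e = float((v * E).sum())            # expected weighted agreement
    vi = (v * pb[None, :]).sum(axis=1)    # row-wise expected agreement
    vj = (v * pa[:, None]).sum(axis=0)
    term = (v * (1 - v_e) - (vi[:, None] + vj[None, :]) * (1 - v_bar)) ** 2
    var = (float((O * term).sum()) - (v_bar * v_e - 2 * v_e + v_bar) ** 2) \
        / (n * (1 - v_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.5 + conf_level / 2)
    return AgreementResult(kappa, max(kappa - z * se, -1.0),
                           min(kappa + z * se, 1.0), k, scheme, se)
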