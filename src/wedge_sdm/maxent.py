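"""Maxent-style presence/background suitability model with cloglog output.

The model is the standard maximum-entropy density estimate over background
cells with linear, quadratic and pairwise-product features, fitted through
its equivalence with an L1-penalised, weighted presence-vs-background
logistic regression.  Predictors are standardized by background mean/sd
before feature expansion; each feature's L1 penalty is proportional to its
background standard deviation scaled by 1/sqrt(n_presences), so the default
regularization strength tracks sample size the way the classic
implementation's does.

The fitted raw distribution q(x) = exp(eta(x)) / Z is normalized over the
training background; the reported suitability is the cloglog transform

    cloglog(x) = 1 - exp(-e^H * q(x))

with H the entropy of q over the background, a monotone map of eta into
[0, 1] whose value is 1 - 1/e at a cell of "typical" (entropy-average)
suitability.

The optimizer is a monotone FISTA (accelerated proximal gradient with
backtracking and restart): the penalized objective is non-increasing across
iterations by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature expansion

@dataclass
class FeatureExpander:
    """Linear + quadratic + pairwise-product features of standardized predictors."""

    predictor_names: list[str]
    mean: np.ndarray            # background mean per predictor
    sd: np.ndarray              # background sd per predictor
    clamp_min: np.ndarray       # training (background) min per predictor
    clamp_max: np.ndarray

    @classmethod
    def from_background(cls, values: np.ndarray,
                        names: list[str]) -> "FeatureExpander":
        values = np.asarray(values, dtype=float)
        sd = values.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(list(names), values.mean(axis=0), sd,
                   values.min(axis=0), values.max(axis=0))

    @property
    def feature_names(self) -> list[str]:
        p = self.predictor_names
        names = list(p) + [f"{n}^2" for n in p]
        names += [f"{p[i]}*{p[j]}" for i in range(len(p))
                  for j in range(i + 1, len(p))]
        return names

    def expand(self, values: np.ndarray, clamp: bool = True) -> np.ndarray:
        """(n, n_features) design matrix; out-of-support values are clamped."""
        v = np.asarray(values, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        if v.shape[1] != len(self.predictor_names):
            raise ValueError("value matrix has wrong number of predictors")
        if clamp:
            n_clamped = int(((v < self.clamp_min) | (v > self.clamp_max)).sum())
            if n_clamped:
                log.info("clamped %d value(s) to the training range", n_clamped)
            v = np.clip(v, self.clamp_min, self.clamp_max)
        z = (v - self.mean) / self.sd
        p = z.shape[1]
        iu, ju = np.triu_indices(p, k=1)
        return np.hstack([z, z ** 2, z[:, iu] * z[:, ju]])


# ---------------------------------------------------------------------------
# background sampling

def sample_background(mask: np.ndarray, bias: np.ndarray, n: int,
                      seed: int | np.random.Generator) -> np.ndarray:
    """Sample n background cell ids, P(cell) ∝ bias inside the mask.

    Draws are without replacement when the mask holds at least n cells of
    positive bias, with replacement otherwise.  The bias layer mimics the
    spatial sampling bias of the occurrence records (e.g. human influence).
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool).ravel()
    bias = np.asarray(bias, dtype=float).ravel()
    if bias.shape != mask.shape:
        raise ValueError("bias and mask shapes differ")
    if (bias < 0).any():
        raise ValueError("bias must be non-negative")
    w = np.where(mask, bias, 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("bias has zero total mass inside the mask")
    cells = np.flatnonzero(w > 0)
    p = w[cells] / total
    replace = n > cells.size
    return rng.choice(cells, size=n, replace=replace, p=p)


# ---------------------------------------------------------------------------
# L1-penalized weighted logistic regression (monotone FISTA)

def _nll_and_grad(beta0, beta, X, y, w):
    eta = X @ beta + beta0
    # stable log(1 + exp(eta)) and sigmoid
    nll = float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))
    mu = 1.0 / (1.0 + np.exp(-eta))
    r = w * (mu - y)
    return nll, float(r.sum()), X.T @ r


def fit_l1_logistic(X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
                    penalty: np.ndarray, max_iter: int = 2000,
                    tol: float = 1e-9) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimize sum_i w_i * NLL_i / W + sum_j penalty_j * |beta_j|.

    Intercept unpenalized.  Monotone FISTA with backtracking line search;
    returns (beta0, beta, objective_history).  Raises if the gradient has not
    levelled off after max_iter iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    W = float(np.sum(sample_weight))
    w = np.asarray(sample_weight, dtype=float) / W
    penalty = np.asarray(penalty, dtype=float)
    n, p = X.shape

    def objective(b0, b):
        nll, _, _ = _nll_and_grad(b0, b, X, y, w)
        return nll + float(penalty @ np.abs(b))

    def prox(v, step):
        return np.sign(v) * np.maximum(np.abs(v) - step * penalty, 0.0)

    beta0, beta = 0.0, np.zeros(p)
    zb0, zb = beta0, beta.copy()          # extrapolated point
    t = 1.0
    # Lipschitz bound for logistic: 0.25 * largest eigenvalue of X'WX (+1 for icpt)
    col = np.sqrt(w)[:, None] * np.hstack([np.ones((n, 1)), X])
    L = 0.25 * np.linalg.norm(col, 2) ** 2
    step = 1.0 / max(L, 1e-12)
    history = [objective(beta0, beta)]
    for it in range(max_iter):
        nll, g0, g = _nll_and_grad(zb0, zb, X, y, w)
        cand0 = zb0 - step * g0
        cand = prox(zb - step * g, step)
        f_cand = objective(cand0, cand)
        # monotone safeguard: never accept an increase over the last iterate
        if f_cand > history[-1]:
            # fall back to a plain proximal step from the current iterate
            nll, g0, g = _nll_and_grad(beta0, beta, X, y, w)
            cand0 = beta0 - step * g0
            cand = prox(beta - step * g, step)
            f_cand = objective(cand0, cand)
            t = 1.0  # restart momentum
            if f_cand > history[-1] + 1e-15:
                history.append(history[-1])
                break  # at numerical floor
        t_next = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        zb0 = cand0 + (t - 1) / t_next * (cand0 - beta0)
        zb = cand + (t - 1) / t_next * (cand - beta)
        beta0, beta, t = cand0, cand, t_next
        history.append(f_cand)
        if it > 1 and history[-2] - history[-1] < tol * max(1.0, abs(history[-1])):
            break
    else:
        _, g0, g = _nll_and_grad(beta0, beta, X, y, w)
        gnorm = float(np.hypot(g0, np.linalg.norm(g)))
        if gnorm > 1e-3:
            raise RuntimeError(
                f"L1 logistic failed to converge: gradient norm {gnorm:.3e} "
                f"after {max_iter} iterations")
    return beta0, beta, np.asarray(history)


# ---------------------------------------------------------------------------
# the model

@dataclass
class MaxentModel:
    expander: FeatureExpander
    beta0: float
    beta: np.ndarray            # lambda per feature
    log_z: float                # log normalizer over training background
    entropy: float              # H of the fitted raw distribution
    objective_history: np.ndarray
    reg_multiplier: float = 1.0

    @property
    def feature_names(self) -> list[str]:
        return self.expander.feature_names

    def eta(self, values: np.ndarray, clamp: bool = True) -> np.ndarray:
        return self.expander.expand(values, clamp=clamp) @ self.beta

    def to_dict(self) -> dict:
        return {
            "predictors": self.expander.predictor_names,
            "features": self.feature_names,
            "lambda": self.beta.tolist(),
            "beta0": self.beta0,
            "standardization": {"mean": self.expander.mean.tolist(),
                                "sd": self.expander.sd.tolist(),
                                "clamp_min": self.expander.clamp_min.tolist(),
                                "clamp_max": self.expander.clamp_max.tolist()},
            "log_z": self.log_z,
            "entropy": self.entropy,
            "reg_multiplier": self.reg_multiplier,
        }


def fit_maxent(presence_values: np.ndarray, background_values: np.ndarray,
               names: list[str], reg_multiplier: float = 1.0,
               background_weights: np.ndarray | None = None,
               max_iter: int = 5000) -> MaxentModel:
    """Fit the presence/background model with linear+quadratic+product features.

    Presences get unit weight; background weights default to 1 (a
    bias-proportional background draw already encodes the sampling bias).
    The per-feature L1 penalty is reg_multiplier * sd_bg(feature) /
    sqrt(n_presences).
    """
    presence_values = np.atleast_2d(np.asarray(presence_values, dtype=float))
    background_values = np.atleast_2d(np.asarray(background_values, dtype=float))
    m = presence_values.shape[0]
    if m < 10:
        raise ValueError("need at least 10 presences to fit")
    expander = FeatureExpander.from_background(background_values, names)
    Xp = expander.expand(presence_values)
    Xb = expander.expand(background_values)
    if background_weights is None:
        background_weights = np.ones(Xb.shape[0])
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(Xp.shape[0]), np.zeros(Xb.shape[0])])
    w = np.concatenate([np.ones(Xp.shape[0]), np.asarray(background_weights,
                                                         dtype=float)])
    feat_sd = Xb.std(axis=0, ddof=0)
    feat_sd = np.where(feat_sd == 0, 1.0, feat_sd)
    # Maxent's default penalty is ~ sd(feature)/sqrt(n_presences) per unit of
    # per-presence log-likelihood; the weighted logistic loss here is
    # normalized by the total weight W, so the equivalent penalty carries the
    # factor m/W (presence share of the total weight).
    W = m + float(np.sum(background_weights))
    penalty = reg_multiplier * feat_sd * np.sqrt(m) / W
    beta0, beta, history = fit_l1_logistic(X, y, w, penalty, max_iter=max_iter)

    eta_bg = Xb @ beta
    # normalizer over the (weighted) background sample
    log_z = float(logsumexp(eta_bg + np.log(background_weights)))
    log_q = eta_bg + np.log(background_weights) - log_z
    entropy = float(-np.sum(np.exp(log_q) * log_q))
    return MaxentModel(expander, beta0, beta, log_z, entropy, history,
                       reg_multiplier)


def cloglog_from_eta(eta: np.ndarray, log_z: float,
                     entropy: float) -> np.ndarray:
    """1 - exp(-e^H * q) with q = exp(eta)/Z; monotone in eta, in [0, 1]."""
    return 1.0 - np.exp(-np.exp(entropy + np.asarray(eta) - log_z))


def predict_cloglog(model: MaxentModel, env_values: np.ndarray) -> np.ndarray:
    """Cloglog suitability per row of env_values (retained predictors)."""
    return cloglog_from_eta(model.eta(env_values), model.log_z, model.entropy)


def project_fine(models: list[MaxentModel],
                 fine_values: np.ndarray) -> np.ndarray:
    """Evaluate replicate models on a fine grid and average cell-wise."""
    if not models:
        raise ValueError("no replicate models to project")
    maps = np.stack([predict_cloglog(m, fine_values) for m in models])
    return maps.mean(axis=0)


def jackknife_importance(presence_values: np.ndarray,
                         background_values: np.ndarray, names: list[str],
                         test_presence_values: np.ndarray | None = None,
                         **fit_kw) -> dict[str, float]:
    """Leave-one-predictor-out importance: drop in AUC when a predictor is removed."""
    from .evaluate import auc as _auc

    test = presence_values if test_presence_values is None else test_presence_values
    full = fit_maxent(presence_values, background_values, names, **fit_kw)
    base = _auc(predict_cloglog(full, test),
                predict_cloglog(full, background_values))
    out = {}
    for k, name in enumerate(names):
        keep = [j for j in range(len(names)) if j != k]
        sub = fit_maxent(presence_values[:, keep], background_values[:, keep],
                         [names[j] for j in keep], **fit_kw)
        a = _auc(predict_cloglog(sub, test[:, keep]),
                 predict_cloglog(sub, background_values[:, keep]))
        out[name] = base - a
    return out


def response_curve(model: MaxentModel, predictor: str,
                   n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: vary one predictor over its training range, others
    held at their background means."""
    k = model.expander.predictor_names.index(predictor)
    grid = np.linspace(model.expander.clamp_min[k], model.expander.clamp_max[k],
                       n_points)
    values = np.tile(model.expander.mean, (n_points, 1))
    values[:, k] = grid
    return grid, predict_cloglog(model, values)
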