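"""Presence-only maximum-entropy niche model (Maxent-style), re-implemented.

The model places a Gibbs distribution over background cells,

    P(x) = exp(lambda . f(x)) / Z,   Z = sum_{x in background} exp(lambda . f(x)),

and chooses the feature weights ``lambda`` to maximise the L1-penalised
log-likelihood of the presence cells

    l(lambda) = mean_{i in train} lambda . f(x_i) - log Z - sum_j beta_j |lambda_j|.

This is the convex dual of the constrained maximum-entropy problem: the
solution is the distribution of maximum entropy whose feature expectations
match the presence means to within the per-feature tolerances ``beta_j``.

Features follow the conventional Maxent classes on a [0, 1] rescaling of
each layer: linear and quadratic terms always, plus hinge features at the
deciles of each layer when the training sample is large enough (>= 15 by
default) to support them.  Regularisation scales like
``beta_j = beta0 * s_j / sqrt(m)`` with ``s_j`` the background standard
deviation of feature j and ``m`` the number of presences, echoing Maxent's
sample-size-dependent defaults.

The model's output is the raw relative occurrence rate (ROR), normalised to
sum to one over the background; only its ordering matters downstream, where
the 10-percentile training-presence rule converts it to a binary
suitable/unsuitable map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .simulate import EnvLayerSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureExpansion",
    "MaxentModel",
    "SuitabilityMap",
    "build_features",
    "fit_maxent",
    "predict_suitability",
    "ten_percentile_threshold",
    "binarize",
    "omission_error",
]

HINGE_MIN_TRAIN = 15
HINGE_QUANTILES = np.arange(0.1, 1.0, 0.1)


@dataclass(frozen=True)
class Feature:
    kind: str  # "linear" | "quadratic" | "hinge"
    layer: str
    knot: float | None = None  # hinge knot on the [0,1] scale

    @property
    def name(self) -> str:
        if self.kind == "hinge":
            return f"hinge({self.layer}@{self.knot:.3f})"
        return f"{self.kind}({self.layer})"


@dataclass
class FeatureExpansion:
    """Feature definitions plus the per-layer [0, 1] scaling bounds.

    Scaling bounds are the background min/max of each layer; constant layers
    are dropped.  ``transform`` maps raw layer values to the design matrix.
    """

    features: list[Feature]
    scaling: dict[str, tuple[float, float]]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def layer_names(self) -> list[str]:
        return list(self.scaling)

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Design matrix (n, F) from raw layer values (n, len(scaling))."""
        names = self.layer_names
        scaled = {}
        for j, name in enumerate(names):
            lo, hi = self.scaling[name]
            scaled[name] = (values[:, j] - lo) / (hi - lo)
        cols = []
        for feat in self.features:
            z = scaled[feat.layer]
            if feat.kind == "linear":
                cols.append(z)
            elif feat.kind == "quadratic":
                cols.append(z**2)
            else:
                cols.append(np.clip((z - feat.knot) / (1.0 - feat.knot), 0.0, None))
        return np.column_stack(cols)


def build_features(
    env: EnvLayerSet,
    background_cells: np.ndarray,
    n_train: int,
    hinge: bool = True,
) -> FeatureExpansion:
    """Maxent-style auto features from the background sample.

    Linear and quadratic terms on every non-constant layer; hinge features
    at background deciles when ``n_train >= 15`` and ``hinge`` is enabled.
    """
    bg = env.values_at(background_cells)
    scaling: dict[str, tuple[float, float]] = {}
    feats: list[Feature] = []
    for j, name in enumerate(env.names):
        lo, hi = float(np.nanmin(bg[:, j])), float(np.nanmax(bg[:, j]))
        if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
            logger.info("dropping constant layer %s from features", name)
            continue
        scaling[name] = (lo, hi)
        feats.append(Feature("linear", name))
        feats.append(Feature("quadratic", name))
    if hinge and n_train >= HINGE_MIN_TRAIN:
        for j, name in enumerate(env.names):
            if name not in scaling:
                continue
            lo, hi = scaling[name]
            z = (bg[:, j] - lo) / (hi - lo)
            for q in HINGE_QUANTILES:
                knot = float(np.quantile(z, q))
                if 0.0 < knot < 1.0:
                    feats.append(Feature("hinge", name, knot))
    return FeatureExpansion(features=feats, scaling=scaling)


@dataclass
class MaxentModel:
    """A fitted per-species maximum-entropy niche model."""

    species_id: str
    expansion: FeatureExpansion
    weights: np.ndarray  # lambda, one per feature
    regularization: np.ndarray  # beta_j >= 0
    log_normalizer: float  # log Z over the background
    background_cells: np.ndarray
    train_cells: np.ndarray
    test_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    threshold: float | None = None  # tau, set by the 10-percentile rule


@dataclass
class SuitabilityMap:
    """Per-cell relative occurrence rate; NaN where layers are missing."""

    species_id: str
    values: np.ndarray  # (n_rows, n_cols), RORs


def _objective(env_design_bg: np.ndarray, p_mean: np.ndarray, beta: np.ndarray):
    """Penalised negative log-likelihood and gradient on the split parameters.

    lambda = u_plus - u_minus with u >= 0 makes the L1 term linear, so the
    problem stays smooth and convex under bound constraints.
    """
    F = env_design_bg.shape[1]

    def fun_grad(u: np.ndarray) -> tuple[float, np.ndarray]:
        lam = u[:F] - u[F:]
        scores = env_design_bg @ lam
        log_z = logsumexp(scores)
        w = np.exp(scores - log_z)
        e_bg = env_design_bg.T @ w
        nll = -(p_mean @ lam - log_z) + beta @ (u[:F] + u[F:])
        g_lam = -(p_mean - e_bg)
        grad = np.concatenate([g_lam + beta, -g_lam + beta])
        return nll, grad

    return fun_grad


def fit_maxent(
    train_cells: np.ndarray,
    background_cells: np.ndarray,
    env: EnvLayerSet,
    expansion: FeatureExpansion | None = None,
    beta0: float = 1.0,
    species_id: str = "species",
    gtol: float = 1e-6,
    maxiter: int = 10_000,
    hinge: bool = True,
) -> MaxentModel:
    """Fit the penalised maximum-entropy model for one species.

    Raises ``RuntimeError`` (carrying the final projected-gradient norm) if
    the optimiser fails to reach the gradient tolerance within ``maxiter``
    iterations.
    """
    train_cells = np.asarray(train_cells, dtype=int)
    background_cells = np.asarray(background_cells, dtype=int)
    if train_cells.size < 1:
        raise ValueError("at least one training cell is required")
    if np.setdiff1d(background_cells, train_cells).size == 0:
        raise ValueError("background must contain cells beyond the training set")
    if expansion is None:
        expansion = build_features(env, background_cells, train_cells.size, hinge=hinge)

    design_bg = expansion.transform(env.values_at(background_cells, expansion.layer_names))
    design_tr = expansion.transform(env.values_at(train_cells, expansion.layer_names))
    p_mean = design_tr.mean(axis=0)
    s_bg = design_bg.std(axis=0)
    beta = beta0 * s_bg / np.sqrt(train_cells.size)

    F = expansion.n_features
    fun_grad = _objective(design_bg, p_mean, beta)
    res = minimize(
        fun_grad,
        np.zeros(2 * F),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * F),
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
    )
    _, grad = fun_grad(res.x)
    # projected gradient: at an active lower bound only a negative gradient
    # component signals non-stationarity
    proj = np.where(res.x > 0, grad, np.minimum(grad, 0.0))
    pg_norm = float(np.max(np.abs(proj)))
    if pg_norm > 10 * gtol and not res.success:
        raise RuntimeError(
            f"maxent fit for {species_id} did not converge: "
            f"projected gradient norm {pg_norm:.3e} after {res.nit} iterations"
        )
    lam = res.x[:F] - res.x[F:]
    log_z = float(logsumexp(design_bg @ lam))
    return MaxentModel(
        species_id=species_id,
        expansion=expansion,
        weights=lam,
        regularization=beta,
        log_normalizer=log_z,
        background_cells=background_cells,
        train_cells=train_cells,
    )


def penalized_loglik(model: MaxentModel, env: EnvLayerSet,
                     weights: np.ndarray | None = None) -> float:
    """Penalised log-likelihood l(lambda) at the model's (or given) weights."""
    lam = model.weights if weights is None else weights
    design_bg = model.expansion.transform(
        env.values_at(model.background_cells, model.expansion.layer_names)
    )
    design_tr = model.expansion.transform(
        env.values_at(model.train_cells, model.expansion.layer_names)
    )
    log_z = logsumexp(design_bg @ lam)
    return float(
        design_tr.mean(axis=0) @ lam - log_z - model.regularization @ np.abs(lam)
    )


def predict_suitability(model: MaxentModel, env: EnvLayerSet) -> SuitabilityMap:
    """ROR over every cell with complete data: exp(lambda . f - log Z).

    Values sum to one over the background cells; cells with any missing
    layer are NaN.
    """
    missing = [n for n in model.expansion.layer_names if n not in env.layers]
    if missing:
        raise ValueError(f"environment lacks layers required by the model: {missing}")
    grid = env.grid
    values = env.matrix()[:, [env.names.index(n) for n in model.expansion.layer_names]]
    valid = np.all(np.isfinite(values), axis=1)
    ror = np.full(grid.n_cells, np.nan)
    design = model.expansion.transform(values[valid])
    ror[valid] = np.exp(design @ model.weights - model.log_normalizer)
    return SuitabilityMap(
        species_id=model.species_id, values=ror.reshape(grid.n_rows, grid.n_cols)
    )


def ten_percentile_threshold(train_suitabilities: np.ndarray,
                             percentile: float = 0.10) -> float:
    """The 10-percentile training-presence threshold tau.

    With the training suitabilities sorted ascending, tau is the value at
    0-based index ``floor(percentile * n)`` — the (floor(0.1 n)+1)-th
    smallest.  Cells strictly below tau are unsuitable, so training omission
    is floor(0.1 n)/n: at most 10%, and exactly 10% when n is a multiple of
    10 and the values are distinct.
    """
    vals = np.sort(np.asarray(train_suitabilities, dtype=float))
    if vals.size < 1:
        raise ValueError("at least one training suitability is required")
    return float(vals[int(np.floor(percentile * vals.size))])


def binarize(s: SuitabilityMap, tau: float) -> np.ndarray:
    """Boolean suitability map: suitable iff ROR >= tau; NaN cells unsuitable."""
    values = s.values
    n_na = int(np.isnan(values).sum())
    if n_na:
        logger.debug(
            "%s: %d NaN cells treated as unsuitable", s.species_id, n_na
        )
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(values), False, values >= tau)


def omission_error(binary: np.ndarray, presence_cells: np.ndarray) -> float:
    """Fraction of presence cells falling on unsuitable cells."""
    presence_cells = np.asarray(presence_cells, dtype=int)
    if presence_cells.size == 0:
        raise ValueError("no presence cells given")
    flat = binary.ravel()
    return float(np.mean(~flat[presence_cells]))
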