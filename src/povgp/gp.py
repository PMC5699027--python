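"""Gaussian-process regression with a product feature x spatial kernel.

The regression model for a commune-level target y_i (e.g. MPI) given a
feature vector x_i from one data source and spatial coordinates s_i of the
commune centre is

    y_i = beta^T x_i + f(x_i, s_i) + eps_i,     eps_i ~ N(0, sigma_n^2)

with a zero-mean GP prior on f whose covariance is the product of a squared
exponential over the features and a squared exponential over space:

    k((x, s), (x', s')) = sigma_f^2
        * exp(-||x - x'||^2 / (2 ell^2))
        * exp(-||s - s'||^2 / (2 ell_s^2))

The spatial factor makes the model a form of Kriging with an external
(linear) drift; the feature factor captures nonlinear source-feature
effects.  Hyperparameters (beta, ell, ell_s, sigma_f^2, sigma_n^2) are
estimated by maximising the marginal log likelihood penalised by an elastic
net on beta:

    J = log p(y | X) - (alpha * lam * ||beta||_2^2 + (1 - alpha) * lam * |beta|_1)

Posterior prediction at (x*, s*) conditions the joint Gaussian of training
targets and the test output, giving

    mean  = beta^T x* + k^T (K + sigma_n^2 I)^{-1} (y - X beta)
    var   = k* - k^T (K + sigma_n^2 I)^{-1} k + sigma_n^2

Note the residual y - X beta in the mean: conditioning is on the centred
process.  The predictive variance depends on the inputs only, never on the
observed targets.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "GPHyperParams",
    "TrainingSet",
    "FitConfig",
    "GPModelState",
    "kernel",
    "kernel_matrix",
    "marginal_log_likelihood",
    "penalized_objective",
    "fit",
    "predict",
    "feature_importance",
]

# Jitter schedule added to the diagonal when a Cholesky factorisation fails.
_JITTERS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)
_L1_SMOOTH_EPS = 1e-8


@dataclass
class GPHyperParams:
    """Hyperparameters of the penalised GP regression.

    beta is on the standardized-feature scale.  Positive quantities are
    optimised internally on the log scale; the dataclass stores them on the
    natural scale.
    """

    beta: np.ndarray
    ell: float
    ell_s: float
    sigma_f2: float
    sigma_n2: float
    alpha: float = 0.5
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.ell <= 0 or self.ell_s <= 0:
            raise ValueError("length-scales must be positive")
        if self.sigma_f2 < 0 or self.sigma_n2 < 0:
            raise ValueError("variances must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class TrainingSet:
    """Feature matrix, spatial coordinates and targets for one source.

    Features are standardized (zero mean, unit sd) at construction; the
    standardization parameters are retained so that test inputs can be
    mapped onto the training scale.  A single shared feature length-scale
    ell is only meaningful on standardized columns.
    """

    X: np.ndarray
    S: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray

    @classmethod
    def from_raw(
        cls,
        X: np.ndarray,
        S: np.ndarray,
        y: np.ndarray,
        feature_names: list[str] | None = None,
    ) -> "TrainingSet":
        X = np.asarray(X, dtype=float)
        S = np.asarray(S, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not (np.isfinite(X).all() and np.isfinite(S).all() and np.isfinite(y).all()):
            raise ValueError("training data contain non-finite values")
        if len(X) != len(S) or len(X) != len(y):
            raise ValueError("X, S and y must have matching lengths")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through centred
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        return cls((X - mean) / sd, S.copy(), y.copy(), list(names), mean, sd)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def standardize(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.d:
            raise ValueError(
                f"expected {self.d} feature columns, got {X_new.shape[1]}"
            )
        return (X_new - self.x_mean) / self.x_sd


@dataclass
class FitConfig:
    """Settings of the marginal-likelihood maximiser."""

    alpha: float = 0.5
    lam: float = 0.1
    n_restarts: int = 3
    max_iter: int = 150
    seed: int = 0
    select_lam: bool = False
    lam_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    select_folds: int = 5


@dataclass
class GPModelState:
    """A fitted model: hyperparameters plus cached training quantities."""

    params: GPHyperParams
    train: TrainingSet
    source: str = "cdr"
    converged: bool = True
    objective: float = float("nan")
    # cached at fit time for O(N^2) prediction
    _chol: tuple | None = None
    _resid_solve: np.ndarray | None = None

    def to_json(self, path: str) -> None:
        doc = {
            "source": self.source,
            "converged": self.converged,
            "objective": self.objective,
            "params": {
                "beta": self.params.beta.tolist(),
                "ell": self.params.ell,
                "ell_s": self.params.ell_s,
                "sigma_f2": self.params.sigma_f2,
                "sigma_n2": self.params.sigma_n2,
                "alpha": self.params.alpha,
                "lam": self.params.lam,
            },
            "train": {
                "X": self.train.X.tolist(),
                "S": self.train.S.tolist(),
                "y": self.train.y.tolist(),
                "feature_names": self.train.feature_names,
                "x_mean": self.train.x_mean.tolist(),
                "x_sd": self.train.x_sd.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "GPModelState":
        with open(path) as fh:
            doc = json.load(fh)
        p = doc["params"]
        params = GPHyperParams(
            beta=np.array(p["beta"]),
            ell=p["ell"],
            ell_s=p["ell_s"],
            sigma_f2=p["sigma_f2"],
            sigma_n2=p["sigma_n2"],
            alpha=p["alpha"],
            lam=p["lam"],
        )
        t = doc["train"]
        train = TrainingSet(
            X=np.array(t["X"]),
            S=np.array(t["S"]),
            y=np.array(t["y"]),
            feature_names=list(t["feature_names"]),
            x_mean=np.array(t["x_mean"]),
            x_sd=np.array(t["x_sd"]),
        )
        return cls(
            params=params,
            train=train,
            source=doc["source"],
            converged=doc["converged"],
            objective=doc["objective"],
        )


# ---------------------------------------------------------------------------
# kernel


def kernel(x, s, x2, s2, params: GPHyperParams) -> float:
    """Covariance between two (feature, space) input pairs."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    if x.shape != x2.shape or s.shape != s2.shape:
        raise ValueError("input dimensions do not match")
    if not (
        np.isfinite(x).all()
        and np.isfinite(x2).all()
        and np.isfinite(s).all()
        and np.isfinite(s2).all()
    ):
        raise ValueError("non-finite kernel inputs")
    dx2 = float(np.sum((x - x2) ** 2))
    ds2 = float(np.sum((s - s2) ** 2))
    return params.sigma_f2 * math.exp(
        -dx2 / (2.0 * params.ell**2) - ds2 / (2.0 * params.ell_s**2)
    )


def kernel_matrix(
    X1: np.ndarray,
    S1: np.ndarray,
    X2: np.ndarray,
    S2: np.ndarray,
    params: GPHyperParams,
) -> np.ndarray:
    """Cross-covariance matrix between two sets of (feature, space) inputs."""
    Dx = cdist(np.atleast_2d(X1), np.atleast_2d(X2), "sqeuclidean")
    Ds = cdist(np.atleast_2d(S1), np.atleast_2d(S2), "sqeuclidean")
    return params.sigma_f2 * np.exp(
        -Dx / (2.0 * params.ell**2) - Ds / (2.0 * params.ell_s**2)
    )


# ---------------------------------------------------------------------------
# likelihood and objective


def _chol_with_jitter(C: np.ndarray, context: str = ""):
    for j in _JITTERS:
        try:
            return cho_factor(C + j * np.eye(len(C)), lower=True), j
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"covariance not positive definite after max jitter {context}"
    )


def marginal_log_likelihood(train: TrainingSet, params: GPHyperParams) -> float:
    """Marginal log likelihood of the targets under the GP model.

    Computed via a Cholesky factorisation of K + sigma_n^2 I; no explicit
    inverse is ever formed.
    """
    K = kernel_matrix(train.X, train.S, train.X, train.S, params)
    C = K + params.sigma_n2 * np.eye(train.n)
    (L, lower), _ = _chol_with_jitter(
        C, f"(sigma_n2={params.sigma_n2:g}, sigma_f2={params.sigma_f2:g})"
    )
    r = train.y - train.X @ params.beta
    a = cho_solve((L, lower), r)
    return float(
        -0.5 * r @ a
        - np.log(np.diag(L)).sum()
        - 0.5 * train.n * math.log(2.0 * math.pi)
    )


def _penalty(beta: np.ndarray, alpha: float, lam: float, smooth: bool = False) -> float:
    l2 = float(beta @ beta)
    if smooth:
        l1 = float(np.sqrt(beta**2 + _L1_SMOOTH_EPS**2).sum())
    else:
        l1 = float(np.abs(beta).sum())
    return alpha * lam * l2 + (1.0 - alpha) * lam * l1


def penalized_objective(train: TrainingSet, params: GPHyperParams) -> float:
    """Marginal log likelihood minus the elastic-net penalty on beta."""
    return marginal_log_likelihood(train, params) - _penalty(
        params.beta, params.alpha, params.lam
    )


# ---------------------------------------------------------------------------
# fitting


def _objective_and_grad(theta, train, Dx, Ds, alpha, lam):
    """Negative penalised objective and its gradient.

    theta = [beta (d), log ell, log ell_s, log sigma_f2, log sigma_n2].
    The L1 term is smoothed as sqrt(beta^2 + eps^2) so the gradient exists
    everywhere.
    """
    d = train.d
    n = train.n
    beta = theta[:d]
    log_ell, log_ell_s, log_sf2, log_sn2 = theta[d:]
    ell = math.exp(log_ell)
    ell_s = math.exp(log_ell_s)
    sf2 = math.exp(log_sf2)
    sn2 = math.exp(log_sn2)

    K = sf2 * np.exp(-Dx / (2.0 * ell**2) - Ds / (2.0 * ell_s**2))
    C = K + sn2 * np.eye(n)
    try:
        (L, lower), _ = _chol_with_jitter(C)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)

    r = train.y - train.X @ beta
    a = cho_solve((L, lower), r)
    mll = -0.5 * r @ a - np.log(np.diag(L)).sum() - 0.5 * n * math.log(2.0 * math.pi)

    sm = np.sqrt(beta**2 + _L1_SMOOTH_EPS**2)
    pen = alpha * lam * beta @ beta + (1.0 - alpha) * lam * sm.sum()
    obj = -(mll - pen)

    # gradient
    Cinv = cho_solve((L, lower), np.eye(n))
    A = np.outer(a, a) - Cinv
    g_beta = train.X.T @ a - (2.0 * alpha * lam * beta + (1.0 - alpha) * lam * beta / sm)
    g_log_ell = 0.5 * np.sum(A * (K * Dx / ell**2))
    g_log_ell_s = 0.5 * np.sum(A * (K * Ds / ell_s**2))
    g_log_sf2 = 0.5 * np.sum(A * K)
    g_log_sn2 = 0.5 * sn2 * np.trace(A)
    grad = -np.concatenate([g_beta, [g_log_ell, g_log_ell_s, g_log_sf2, g_log_sn2]])
    return obj, grad


def _initial_points(train: TrainingSet, rng: np.random.Generator, n_restarts: int):
    """Data-driven initialisation plus seeded random restarts."""
    d = train.d
    var_y = max(float(np.var(train.y)), 1e-6)
    # ridge start for beta
    beta0 = np.linalg.solve(
        train.X.T @ train.X + 1e-2 * np.eye(d), train.X.T @ train.y
    )
    span = float(np.ptp(train.S, axis=0).max()) or 1.0
    base = np.concatenate(
        [
            beta0,
            [
                math.log(math.sqrt(d) if d > 0 else 1.0),
                math.log(span / 4.0),
                math.log(var_y / 2.0),
                math.log(var_y / 4.0),
            ],
        ]
    )
    points = [base]
    for _ in range(max(0, n_restarts - 1)):
        p = base.copy()
        p[:d] = beta0 * rng.uniform(0.5, 1.5, size=d)
        p[d] += rng.normal(0.0, 0.7)
        p[d + 1] = math.log(span) + rng.uniform(math.log(0.05), math.log(0.8))
        p[d + 2] += rng.normal(0.0, 0.7)
        p[d + 3] += rng.normal(0.0, 0.7)
        points.append(p)
    return points


def _fit_fixed_lam(train, alpha, lam, n_restarts, max_iter, rng):
    Dx = cdist(train.X, train.X, "sqeuclidean")
    Ds = cdist(train.S, train.S, "sqeuclidean")
    d = train.d
    bounds = [(None, None)] * d + [
        (math.log(1e-2), math.log(1e4)),
        (math.log(1e-1), math.log(1e5)),
        (math.log(1e-8), math.log(1e4)),
        (math.log(1e-8), math.log(1e4)),
    ]
    best_theta = None
    best_obj = np.inf
    converged = False
    for theta0 in _initial_points(train, rng, n_restarts):
        f0, _ = _objective_and_grad(theta0, train, Dx, Ds, alpha, lam)
        if f0 < best_obj:
            best_obj, best_theta = f0, theta0
        res = minimize(
            _objective_and_grad,
            theta0,
            args=(train, Dx, Ds, alpha, lam),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter},
        )
        if res.fun < best_obj:
            best_obj, best_theta = res.fun, res.x
            converged = bool(res.success)
    return best_theta, -best_obj, converged


def fit(train: TrainingSet, config: FitConfig | None = None, source: str = "cdr") -> GPModelState:
    """Maximise the penalised marginal likelihood over all hyperparameters.

    Runs a gradient-based (L-BFGS) maximiser from ``n_restarts`` seeded
    starting points; positive hyperparameters are optimised in log space.
    The best iterate never scores below the best initialisation.  When
    ``select_lam`` is set, the penalty strength is first chosen on a log
    grid by k-fold cross-validation within the training split.
    """
    config = config or FitConfig()
    if train.n < 10:
        raise ValueError("at least 10 training communes are required")
    rng = np.random.default_rng(config.seed)

    lam = config.lam
    if config.select_lam:
        lam = _select_lam(train, config, rng)

    theta, obj, converged = _fit_fixed_lam(
        train, config.alpha, lam, config.n_restarts, config.max_iter, rng
    )
    if not converged:
        warnings.warn(
            "hyperparameter optimisation did not report convergence; "
            "returning the best iterate",
            RuntimeWarning,
        )
    d = train.d
    params = GPHyperParams(
        beta=theta[:d],
        ell=math.exp(theta[d]),
        ell_s=math.exp(theta[d + 1]),
        sigma_f2=math.exp(theta[d + 2]),
        sigma_n2=math.exp(theta[d + 3]),
        alpha=config.alpha,
        lam=lam,
    )
    state = GPModelState(
        params=params, train=train, source=source, converged=converged, objective=obj
    )
    _cache_posterior(state)
    return state


def _select_lam(train: TrainingSet, config: FitConfig, rng: np.random.Generator) -> float:
    """Pick lam from the grid by inner k-fold CV RMSE."""
    idx = rng.permutation(train.n)
    folds = np.array_split(idx, config.select_folds)
    best_lam, best_rmse = config.lam, np.inf
    for lam in config.lam_grid:
        errs = []
        for f in folds:
            mask = np.ones(train.n, dtype=bool)
            mask[f] = False
            if mask.sum() < 10 or len(f) == 0:
                continue
            sub = TrainingSet(
                X=train.X[mask],
                S=train.S[mask],
                y=train.y[mask],
                feature_names=train.feature_names,
                x_mean=np.zeros(train.d),
                x_sd=np.ones(train.d),
            )
            theta, _, _ = _fit_fixed_lam(
                sub, config.alpha, lam, 1, config.max_iter, rng
            )
            params = GPHyperParams(
                beta=theta[: train.d],
                ell=math.exp(theta[train.d]),
                ell_s=math.exp(theta[train.d + 1]),
                sigma_f2=math.exp(theta[train.d + 2]),
                sigma_n2=math.exp(theta[train.d + 3]),
                alpha=config.alpha,
                lam=lam,
            )
            state = GPModelState(params=params, train=sub)
            _cache_posterior(state)
            mean, _ = _posterior(state, train.X[f], train.S[f])
            errs.append(np.mean((mean - train.y[f]) ** 2))
        if errs:
            rmse = float(np.sqrt(np.mean(errs)))
            if rmse < best_rmse:
                best_rmse, best_lam = rmse, lam
    return best_lam


# ---------------------------------------------------------------------------
# prediction


def _cache_posterior(state: GPModelState) -> None:
    train, params = state.train, state.params
    K = kernel_matrix(train.X, train.S, train.X, train.S, params)
    C = K + params.sigma_n2 * np.eye(train.n)
    chol, _ = _chol_with_jitter(C)
    r = train.y - train.X @ params.beta
    state._chol = chol
    state._resid_solve = cho_solve(chol, r)


def _posterior(state: GPModelState, Xs_std: np.ndarray, Ss: np.ndarray):
    train, params = state.train, state.params
    if state._chol is None:
        _cache_posterior(state)
    Kx = kernel_matrix(train.X, train.S, Xs_std, Ss, params)  # (n, m)
    mean = Xs_std @ params.beta + Kx.T @ state._resid_solve
    L, lower = state._chol
    V = solve_triangular(L, Kx, lower=lower)
    var = params.sigma_f2 - np.einsum("ij,ij->j", V, V) + params.sigma_n2
    return mean, np.maximum(var, 0.0)


def predict(
    state: GPModelState,
    X_star: np.ndarray,
    S_star: np.ndarray,
    commune_ids=None,
):
    """Posterior predictive mean and variance at new communes.

    Features are standardized with the training parameters before entering
    either the linear mean or the kernel.  Returns a pandas DataFrame with
    columns (commune_id, mean, variance, source).
    """
    import pandas as pd

    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    S_star = np.atleast_2d(np.asarray(S_star, dtype=float))
    Xs = state.train.standardize(X_star)
    mean, var = _posterior(state, Xs, S_star)
    if commune_ids is None:
        commune_ids = np.arange(len(mean))
    return pd.DataFrame(
        {
            "commune_id": commune_ids,
            "mean": mean,
            "variance": var,
            "source": state.source,
        }
    )


def feature_importance(state: GPModelState, prune_tol: float = 1e-3):
    """Features ranked by |beta| (standardized scale), descending.

    Coefficients with |beta| <= prune_tol are flagged as pruned by the
    elastic net.  Ranking is stable under permutation of the feature
    columns because ties are broken by feature name.
    """
    import pandas as pd

    beta = state.params.beta
    df = pd.DataFrame(
        {
            "feature": state.train.feature_names,
            "beta": beta,
            "abs_beta": np.abs(beta),
        }
    )
    df["pruned"] = df["abs_beta"] <= prune_tol
    df = df.sort_values(
        ["abs_beta", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
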