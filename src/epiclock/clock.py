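"""Penalized-regression age clocks (ridge and elastic net).

The fitted objective, for n samples and internally standardized predictors
(mean 0, population SD 1), is the glmnet-style elastic net

    (1/(2n)) * sum_i (y_i - b0 - x_i'b)^2
        + lam * [ alpha * ||b||_1 + ((1 - alpha)/2) * ||b||_2^2 ]

with an unpenalized intercept; coefficients are returned on the original
methylation scale. alpha = 0 is ridge (solved in closed form through an
eigendecomposition of the Gram matrix, exact for any n, p); alpha in (0, 1]
uses coordinate descent. The penalty lam is chosen by seeded internal k-fold
cross-validation over a log-spaced path from lam_max (the smallest penalty
that zeroes every coefficient; for ridge the conventional alpha = 0.001
surrogate defines it) down to a small fraction of lam_max (1e-4 when n > p,
1e-2 otherwise, the reference path convention), taking the
mean-squared-error minimizer ("lambda.min" rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, enet_path

from .io import training_hash

__all__ = [
    "ClockModel",
    "PenaltyPath",
    "PenalizedAgeClock",
    "fit_penalized",
    "select_lambda",
    "predict_age",
    "subset_conserved",
]

_RIDGE_ALPHA_SURROGATE = 1e-3  # defines lam_max when alpha == 0


@dataclass
class ClockModel:
    """A fitted clock: intercept plus per-site coefficients in months."""

    intercept: float
    coefficients: pd.Series      # indexed by site id, original scale
    alpha: float
    lam: float
    training_sites: list
    training_hash: str = ""

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients.to_numpy() != 0.0).sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ClockModel)
            and self.intercept == other.intercept
            and self.alpha == other.alpha
            and self.lam == other.lam
            and list(self.training_sites) == list(other.training_sites)
            and self.coefficients.equals(other.coefficients)
        )


@dataclass
class PenaltyPath:
    lambdas: np.ndarray          # descending grid
    cv_mse: np.ndarray           # pooled out-of-fold MSE per lambda
    lambda_min: float = field(init=False)

    def __post_init__(self):
        self.lambda_min = float(self.lambdas[int(np.argmin(self.cv_mse))])


# ---------------------------------------------------------------------------
# numerical core (standardized space)

def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, glmnet convention
    # constant columns leave rounding dust in sd; compare at relative scale
    zero_var = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    sd_safe = np.where(zero_var, 1.0, sd)
    S = (X - mu) / sd_safe
    return S, mu, sd_safe, zero_var


def _validate_xy(X: np.ndarray, y: np.ndarray):
    if np.isnan(X).any():
        raise ValueError("X contains NaN; impute before fitting")
    if np.isnan(y).any():
        raise ValueError("y contains NaN")
    if np.unique(y).size < 2:
        raise ValueError("y is constant; cannot fit an age clock")


def _ridge_solve(S: np.ndarray, r: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Exact ridge coefficients for every lam; returns (n_lams, p).

    Solves (S'S/n + lam I) b = S'r/n through the eigendecomposition of the
    smaller of the two Gram matrices, so p >> n costs O(n^2 p).
    """
    n, p = S.shape
    lams = np.atleast_1d(np.asarray(lams, dtype=float))
    if p <= n:
        C = (S.T @ S) / n
        rhs = S.T @ r / n
        w, V = np.linalg.eigh(C)
        proj = V.T @ rhs
        return np.stack([V @ (proj / (w + lam)) for lam in lams])
    G = (S @ S.T) / n
    w, Q = np.linalg.eigh(G)
    proj = Q.T @ r
    out = np.empty((len(lams), p))
    for i, lam in enumerate(lams):
        aa = Q @ (proj / (w + lam)) / n
        out[i] = S.T @ aa
    return out


def _enet_fit(S: np.ndarray, r: np.ndarray, alpha: float, lam: float) -> np.ndarray:
    """Coordinate-descent elastic net, warm-started down a short path.

    Solving directly at a small penalty converges slowly; walking a
    log-spaced path from lam_max to the target (the glmnet strategy) reaches
    the same optimum far faster.
    """
    lam_max = _lambda_max(S, r, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if lam >= lam_max:
            model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                               max_iter=100_000, tol=1e-6)
            model.fit(S, r)
            return model.coef_
        path = np.geomspace(lam_max, lam, 20)
        path[-1] = lam
        _, coefs, _ = enet_path(S, r, l1_ratio=alpha, alphas=path,
                                max_iter=100_000, tol=1e-6)
    return coefs[:, -1]


def _lambda_max(S: np.ndarray, r: np.ndarray, alpha: float) -> float:
    a = max(alpha, _RIDGE_ALPHA_SURROGATE)
    n = len(r)
    lm = float(np.max(np.abs(S.T @ r)) / (n * a))
    return lm if lm > 0 else 1.0


def _auto_min_ratio(n: int, p: int) -> float:
    # reference-implementation convention: shorter path when p exceeds n
    return 1e-4 if n > p else 1e-2


def _lambda_grid(lam_max: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


# ---------------------------------------------------------------------------
# public functional surface

def fit_penalized(X, y, alpha: float, lam: float) -> ClockModel:
    """Fit the elastic-net/ridge objective at a fixed penalty.

    X may be a DataFrame (site-id columns) or array; y is age in months.
    Zero-variance predictors receive coefficient 0 by convention.
    """
    Xa, sites = _as_array(X)
    y = np.asarray(y, dtype=float)
    _validate_xy(Xa, y)
    if lam < 0:
        raise ValueError("penalty lam must be >= 0")
    S, mu, sd, zero_var = _standardize(Xa)
    S = np.where(zero_var, 0.0, S)
    ybar = float(y.mean())
    r = y - ybar
    if alpha == 0.0:
        b_std = _ridge_solve(S, r, np.array([lam]))[0]
    else:
        b_std = _enet_fit(S, r, alpha, lam)
    b_std = np.where(zero_var, 0.0, b_std)
    b = b_std / sd
    intercept = ybar - float(b @ mu)
    coefs = pd.Series(b, index=sites, dtype=float)
    return ClockModel(
        intercept=intercept,
        coefficients=coefs,
        alpha=float(alpha),
        lam=float(lam),
        training_sites=list(sites),
    )


def select_lambda(
    X,
    y,
    alpha: float,
    n_folds: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 1,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> PenaltyPath:
    """Choose the penalty by seeded k-fold CV (lambda.min rule).

    The grid defaults to ``n_lambda`` log-spaced values from lam_max down to
    ``lambda_min_ratio * lam_max`` (1e-4 when n > p, else 1e-2, the
    reference path convention), computed on the full data; each fold is
    re-standardized on its own training part, as a fresh fit would be.
    """
    Xa, _ = _as_array(X)
    y = np.asarray(y, dtype=float)
    _validate_xy(Xa, y)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    if grid is None:
        if lambda_min_ratio is None:
            lambda_min_ratio = _auto_min_ratio(n, Xa.shape[1])
        S_full, _, _, zv = _standardize(Xa)
        S_full = np.where(zv, 0.0, S_full)
        lam_max = _lambda_max(S_full, y - y.mean(), alpha)
        grid = _lambda_grid(lam_max, n_lambda, lambda_min_ratio)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1].copy()

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds

    sse = np.zeros(len(grid))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        S_tr, mu, sd, zv = _standardize(Xa[train])
        S_tr = np.where(zv, 0.0, S_tr)
        ybar = y[train].mean()
        r_tr = y[train] - ybar
        S_te = (Xa[test] - mu) / sd
        S_te = np.where(zv, 0.0, S_te)
        if alpha == 0.0:
            # kernel form: predictions need only the train/test Gram blocks
            n_tr = len(r_tr)
            G = S_tr @ S_tr.T / n_tr
            w, Q = np.linalg.eigh(G)
            proj = Q.T @ r_tr
            dual = Q @ (proj[:, None] / (w[:, None] + grid[None, :])) / n_tr
            preds = ybar + (S_te @ S_tr.T / n_tr) @ dual  # (n_te, n_lam)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    S_tr, r_tr, l1_ratio=alpha, alphas=grid,
                    max_iter=20_000, tol=1e-4,
                )
            preds = ybar + S_te @ coefs                  # coefs is (p, n_lam)
        sse += ((preds - y[test][:, None]) ** 2).sum(axis=0)
    return PenaltyPath(lambdas=grid, cv_mse=sse / n)


def predict_age(model: ClockModel, X) -> pd.Series | np.ndarray:
    """Apply a fitted clock: yhat = b0 + x'b over the training sites."""
    if isinstance(X, pd.DataFrame):
        missing = [s for s in model.training_sites if s not in X.columns]
        if missing:
            shown = ", ".join(map(str, missing[:10]))
            raise ValueError(
                f"input lacks {len(missing)} training site(s): {shown}"
            )
        Xa = X[model.training_sites].to_numpy(dtype=float)
        yhat = model.intercept + Xa @ model.coefficients.to_numpy()
        return pd.Series(yhat, index=X.index, name="dnam_age")
    Xa = np.asarray(X, dtype=float)
    if Xa.shape[1] != len(model.training_sites):
        raise ValueError(
            f"expected {len(model.training_sites)} site columns, got {Xa.shape[1]}"
        )
    return model.intercept + Xa @ model.coefficients.to_numpy()


def subset_conserved(matrix: pd.DataFrame, site_list) -> pd.DataFrame:
    """Restrict a matrix to a conserved-CpG list (in list order).

    ``site_list`` holds site ids or (chrom, pos) keys; sites absent from the
    matrix are skipped with a warning, an empty intersection is an error.
    """
    wanted = []
    for s in site_list:
        if not isinstance(s, str):
            chrom, pos = s
            s = f"{chrom}:{int(pos)}"
        wanted.append(s)
    present = [s for s in wanted if s in matrix.columns]
    if not present:
        raise ValueError("conserved site list is disjoint from the matrix")
    if len(present) < len(wanted):
        warnings.warn(
            f"{len(wanted) - len(present)} of {len(wanted)} conserved sites "
            "absent from the matrix", stacklevel=2
        )
    return matrix[present]


# ---------------------------------------------------------------------------
# estimator

class PenalizedAgeClock(BaseEstimator, RegressorMixin):
    """Elastic-net / ridge DNA-methylation age estimator.

    Parameters
    ----------
    alpha : float, default=0.5
        Elastic-net mixing; 0 is ridge, 0.5 the conventional elastic net.
    lam : float or None, default=None
        Penalty strength. None selects it by internal cross-validation.
    n_folds : int, default=10
        Folds of the internal penalty-selection CV.
    n_lambda : int, default=100
        Length of the default penalty path.
    lambda_min_ratio : float or None, default=None
        Smallest path value relative to lam_max; None picks 1e-4 when
        n > p and 1e-2 otherwise.
    random_state : int, default=1
        Seed of the internal CV fold shuffle.

    Attributes
    ----------
    coef_ : ndarray of shape (n_sites,)
        Coefficients on the original methylation scale (months per unit).
    intercept_ : float
    lambda_ : float
        The penalty actually used.
    path_ : PenaltyPath or None
        Internal CV path when ``lam`` was selected automatically.
    model_ : ClockModel
        Serializable clock (site ids, coefficients, penalty).
    """

    def __init__(self, alpha: float = 0.5, lam: float | None = None,
                 n_folds: int = 10, n_lambda: int = 100,
                 lambda_min_ratio: float | None = None, random_state: int = 1):
        self.alpha = alpha
        self.lam = lam
        self.n_folds = n_folds
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.random_state = random_state

    def fit(self, X, y):
        if self.lam is None:
            self.path_ = select_lambda(
                X, y, self.alpha, n_folds=self.n_folds,
                seed=self.random_state, n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
            )
            lam = self.path_.lambda_min
        else:
            self.path_ = None
            lam = float(self.lam)
        self.model_ = fit_penalized(X, y, self.alpha, lam)
        if isinstance(X, pd.DataFrame):
            self.model_.training_hash = training_hash(X.index)
        self.coef_ = self.model_.coefficients.to_numpy()
        self.intercept_ = self.model_.intercept
        self.lambda_ = lam
        self.n_features_in_ = len(self.coef_)
        self.n_nonzero_ = self.model_.n_nonzero
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise AttributeError("PenalizedAgeClock is not fitted yet")
        return predict_age(self.model_, X)
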