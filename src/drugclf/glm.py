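"""Regularized generalized linear models: the engine shared by all analysis stages.

Two response families are supported. A *bernoulli* GLM (logistic inverse link)
models binary outcomes -- a cell being cancerous, a line being basal-like. A
*gaussian* GLM (identity link) models continuous outcomes -- chemosensitivity as
-log(GI50). Coefficients can be shrunk with an L1 penalty (sparse, performs gene
selection) or an L2 penalty (dense shrinkage); the intercept is never penalized.

The penalized objective minimized by :func:`fit_glm` is, with standardized
predictors ``x``, weights ``beta`` and intercept ``b``::

    bernoulli:  sum_i [ log(1 + exp(z_i)) - y_i * z_i ]  +  lam * P(beta)
    gaussian:   0.5 * sum_i (y_i - z_i)^2               +  lam * P(beta)

where ``z_i = x_i . beta + b`` and ``P`` is ``sum |beta_k|`` (L1) or
``sum beta_k^2`` (L2).

Predictors are z-scored on the training data by default; the centering/scaling
constants are stored in the model and re-applied at prediction time, so ranking
genes by coefficient magnitude compares them on a common scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import (
    ConfigurationError,
    DataQualityError,
    EmptyInputError,
    InvalidResponseError,
    SchemaError,
    StateError,
)

FAMILIES = ("bernoulli", "gaussian")
PENALTIES = ("l1", "l2", "none")

#: number of candidate penalty strengths in the default grid
N_LAMBDA = 50
#: smallest candidate relative to lambda_max
LAMBDA_RATIO = 1e-4

_PROB_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Samples x features predictor matrix with ordered identifiers.

    ``values`` holds expression levels (cells/lines x genes) or drug
    sensitivities (lines x drugs) as floats; no missing values are allowed --
    imputation/dropping happens upstream at load time.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("DesignMatrix values must be 2-dimensional")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if len(self.feature_ids) != p:
            raise SchemaError(
                f"{len(self.feature_ids)} feature ids for {p} columns"
            )
        if len(self.sample_ids) != n:
            raise SchemaError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.feature_ids)) != p:
            seen: set[str] = set()
            dup = next(f for f in self.feature_ids if f in seen or seen.add(f))
            raise SchemaError(f"duplicate feature id: {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataQualityError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df) -> "DesignMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns), list(df.index))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_features(self, ids: Sequence[str]) -> "DesignMatrix":
        pos = {f: k for k, f in enumerate(self.feature_ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as exc:
            raise SchemaError(f"unknown feature id: {exc.args[0]!r}") from None
        return DesignMatrix(self.values[:, idx], [self.feature_ids[k] for k in idx], self.sample_ids)

    def subset_samples(self, index: np.ndarray) -> "DesignMatrix":
        index = np.asarray(index)
        return DesignMatrix(
            self.values[index],
            self.feature_ids,
            [self.sample_ids[i] for i in np.arange(self.n_samples)[index]]
            if index.dtype == bool
            else [self.sample_ids[i] for i in index],
        )


@dataclass
class PenaltySpec:
    """Penalty kind ('l1', 'l2' or 'none') and nonnegative strength lambda."""

    kind: str = "none"
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PENALTIES:
            raise ConfigurationError(f"unknown penalty kind {self.kind!r}")
        if not np.isfinite(self.strength) or self.strength < 0:
            raise ConfigurationError("penalty strength must be finite and >= 0")


@dataclass
class GLMModel:
    """A fitted GLM: family, per-feature weights, intercept and penalty spec.

    Weights are on the standardized-predictor scale when ``standardization``
    holds per-feature (center, scale) arrays; prediction re-applies them.
    """

    family: str
    weights: np.ndarray | None
    intercept: float
    penalty: str
    penalty_strength: float
    feature_ids: list[str]
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.feature_ids),):
                raise SchemaError("weights length must equal feature_ids length")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        center, scale = (None, None)
        if self.standardization is not None:
            center = self.standardization[0].tolist()
            scale = self.standardization[1].tolist()
        return {
            "family": self.family,
            "penalty": self.penalty,
            "penalty_strength": float(self.penalty_strength),
            "feature_ids": list(self.feature_ids),
            "weights": None if self.weights is None else self.weights.tolist(),
            "intercept": float(self.intercept),
            "center": center,
            "scale": scale,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GLMModel":
        std = None
        if d.get("center") is not None:
            std = (np.asarray(d["center"], float), np.asarray(d["scale"], float))
        return cls(
            family=d["family"],
            weights=None if d["weights"] is None else np.asarray(d["weights"], float),
            intercept=d["intercept"],
            penalty=d["penalty"],
            penalty_strength=d["penalty_strength"],
            feature_ids=list(d["feature_ids"]),
            standardization=std,
        )

    @classmethod
    def from_json(cls, path) -> "GLMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _as_values(X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _constant_columns(X: np.ndarray) -> np.ndarray:
    return np.ptp(X, axis=0) == 0.0


def _standardize(X: np.ndarray):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(_constant_columns(X), 1.0, scale)
    return (X - center) / scale, center, scale


def _check_response(y, family: str, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != n:
        raise SchemaError(f"response length {y.shape[0]} != {n} samples")
    if not np.isfinite(y).all():
        raise DataQualityError("non-finite value in response")
    if family == "bernoulli" and not np.isin(y, (0.0, 1.0)).all():
        raise InvalidResponseError("bernoulli response must be coded 0/1")
    return y


def _nll(z: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "bernoulli":
        return float(np.logaddexp(0.0, z).sum() - y @ z)
    return float(0.5 * np.sum((y - z) ** 2))


def _penalty_value(w: np.ndarray, kind: str, lam: float) -> float:
    if kind == "l1":
        return lam * float(np.abs(w).sum())
    if kind == "l2":
        return lam * float(w @ w)
    return 0.0


def penalized_objective(model: GLMModel, X, y) -> float:
    """Penalized negative log-likelihood of ``model`` on (X, y).

    Evaluated on the model's own standardized predictor scale, i.e. exactly the
    objective :func:`fit_glm` minimizes.
    """
    Xv = _as_values(X)
    y = _check_response(y, model.family, Xv.shape[0])
    if model.standardization is not None:
        center, scale = model.standardization
        Xv = (Xv - center) / scale
    z = Xv @ model.weights + model.intercept
    return _nll(z, y, model.family) + _penalty_value(
        model.weights, model.penalty, model.penalty_strength
    )


def _logistic_newton(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    w0: np.ndarray | None = None,
    b0: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
):
    """Damped Newton minimization of the L2-penalized logistic objective.

    ``lam`` is the coefficient of ``sum beta^2`` (0 for the unpenalized fit, in
    which case iterations are bounded so separable data cannot hang).
    """
    n, p = X.shape
    w = np.zeros(p) if w0 is None else w0.copy()
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    b = float(logit(ybar)) if b0 is None else float(b0)

    def objective(w, b):
        z = X @ w + b
        return _nll(z, y, "bernoulli") + lam * (w @ w)

    f = objective(w, b)
    for _ in range(max_iter):
        z = X @ w + b
        pr = expit(z)
        r = pr - y
        g = np.empty(p + 1)
        g[:p] = X.T @ r + 2.0 * lam * w
        g[p] = r.sum()
        gnorm = np.max(np.abs(g))
        if gnorm < tol * max(1.0, n):
            break
        wt = pr * (1.0 - pr) + 1e-12
        Xw = X * wt[:, None]
        A = np.empty((p + 1, p + 1))
        A[:p, :p] = X.T @ Xw + 2.0 * lam * np.eye(p)
        A[:p, p] = Xw.sum(axis=0)
        A[p, :p] = A[:p, p]
        A[p, p] = wt.sum()
        A[np.diag_indices_from(A)] += 1e-10
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            step = g / max(A[np.diag_indices_from(A)].max(), 1.0)
        t = 1.0
        descent = float(g @ step)
        for _ in range(40):
            w2 = w - t * step[:p]
            b2 = b - t * step[p]
            f2 = objective(w2, b2)
            if f2 <= f - 1e-4 * t * descent:
                break
            t *= 0.5
        if f2 > f:  # no progress possible
            break
        improved = f - f2
        w, b, f = w2, b2, f2
        if improved < tol * (1.0 + abs(f)):
            break
    return w, b


def _logistic_l2_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray):
    """Warm-started Newton path over a descending lambda grid.

    Returns (len(lambdas) x p) weights and (len(lambdas),) intercepts.
    """
    n, p = X.shape
    W = np.empty((len(lambdas), p))
    B = np.empty(len(lambdas))
    w, b = None, None
    for k, lam in enumerate(lambdas):
        w, b = _logistic_newton(X, y, lam, w0=w, b0=b)
        W[k] = w
        B[k] = b
    return W, B


def _logistic_l1_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, seed: int):
    """L1-logistic path via a warm-started saga estimator (descending grid)."""
    n, p = X.shape
    W = np.empty((len(lambdas), p))
    B = np.empty(len(lambdas))
    est = LogisticRegression(
        l1_ratio=1.0,
        solver="saga",
        warm_start=True,
        max_iter=5000,
        tol=1e-8,
        random_state=int(seed) % (2**31),
    )
    for k, lam in enumerate(lambdas):
        est.C = 1.0 / max(lam, 1e-12)
        est.fit(X, y)
        W[k] = est.coef_[0]
        B[k] = est.intercept_[0]
    return W, B


def _fit_gaussian(Xs: np.ndarray, y: np.ndarray, kind: str, lam: float):
    n = Xs.shape[0]
    if kind == "l1" and lam > 0:
        est = Lasso(alpha=lam / n, fit_intercept=True, max_iter=100_000, tol=1e-10)
        est.fit(Xs, y)
        return est.coef_.copy(), float(est.intercept_)
    if kind == "l2" and lam > 0:
        # closed form with unpenalized intercept: solve on centered data
        xm = Xs.mean(axis=0)
        Xc = Xs - xm
        yc = y - y.mean()
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        d = s / (s**2 + 2.0 * lam)
        w = Vt.T @ (d * (U.T @ yc))
        return w, float(y.mean() - xm @ w)
    est = LinearRegression()
    est.fit(Xs, y)
    return est.coef_.copy(), float(est.intercept_)


def _l1_logistic_polish(X, y, lam, w, b, max_iter=50):
    """Active-set Newton polish of an L1-logistic solution.

    Within the orthant fixed by the signs of the nonzero coefficients the
    objective is smooth (NLL + lam * sign . w); Newton steps are taken on the
    active coordinates plus the intercept, zeroing any coefficient that tries
    to cross its orthant boundary.
    """
    w = w.copy()
    for _ in range(max_iter):
        active = np.flatnonzero(w != 0.0)
        signs = np.sign(w[active])
        Xa = X[:, active]
        wa, bn = w[active], b

        def objective(wa_, b_):
            z = Xa @ wa_ + b_
            return _nll(z, y, "bernoulli") + lam * float(np.abs(wa_).sum())

        f = objective(wa, bn)
        z = Xa @ wa + bn
        pr = expit(z)
        r = pr - y
        g = np.concatenate([Xa.T @ r + lam * signs, [r.sum()]])
        if np.max(np.abs(g)) < 1e-10 * max(1.0, len(y)):
            break
        wt = pr * (1 - pr) + 1e-12
        k = len(active)
        A = np.empty((k + 1, k + 1))
        Xw = Xa * wt[:, None]
        A[:k, :k] = Xa.T @ Xw
        A[:k, k] = Xw.sum(axis=0)
        A[k, :k] = A[:k, k]
        A[k, k] = wt.sum()
        A[np.diag_indices_from(A)] += 1e-10
        step = np.linalg.solve(A, g)
        t = 1.0
        for _ in range(30):
            wa2 = wa - t * step[:k]
            # clamp sign changes to the boundary (coefficient leaves the set)
            flipped = np.sign(wa2) * signs < 0
            wa2 = np.where(flipped, 0.0, wa2)
            b2 = bn - t * step[k]
            if objective(wa2, b2) <= f:
                break
            t *= 0.5
        if objective(wa2, b2) >= f - 1e-12 * (1 + abs(f)):
            w[active], b = wa2, b2
            break
        w[active], b = wa2, b2
    return w, b


def _fit_bernoulli(Xs: np.ndarray, y: np.ndarray, kind: str, lam: float, seed: int):
    if kind == "l1" and lam > 0:
        est = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / lam,
            solver="saga",
            max_iter=20_000,
            tol=1e-9,
            random_state=int(seed) % (2**31),
        )
        est.fit(Xs, y)
        return _l1_logistic_polish(Xs, y, lam, est.coef_[0].copy(), float(est.intercept_[0]))
    lam_eff = lam if kind == "l2" else 0.0
    w, b = _logistic_newton(Xs, y, lam_eff)
    return w, b


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_glm(
    X,
    y,
    family: str,
    penalty: PenaltySpec | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> GLMModel:
    """Fit a (possibly penalized) GLM of the given family.

    Parameters
    ----------
    X : DesignMatrix or array
        Samples x features predictors.
    y : array
        Response; {0,1} for bernoulli, real-valued for gaussian.
    family : {'bernoulli', 'gaussian'}
    penalty : PenaltySpec, optional
        Defaults to no penalty. With ``kind='none'`` the strength is ignored.
    seed : int
        Seeds stochastic solvers; the fit is deterministic given inputs + seed.
    standardize : bool
        Z-score predictors on this data before fitting (default). The
        constants are stored in the model and re-applied by :func:`predict`.
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    penalty = penalty or PenaltySpec()
    Xv = _as_values(X)
    if Xv.ndim != 2 or Xv.shape[0] == 0 or Xv.shape[1] == 0:
        raise EmptyInputError("design matrix must have >= 1 row and >= 1 feature")
    if Xv.shape[0] < 2:
        raise EmptyInputError("fitting requires at least 2 samples")
    if not np.isfinite(Xv).all():
        raise DataQualityError("non-finite value in design matrix")
    y = _check_response(y, family, Xv.shape[0])

    feature_ids = (
        list(X.feature_ids)
        if isinstance(X, DesignMatrix)
        else [f"x{k}" for k in range(Xv.shape[1])]
    )

    if standardize:
        Xs, center, scale = _standardize(Xv)
        std = (center, scale)
    else:
        Xs = Xv
        std = None

    kind = penalty.kind
    lam = float(penalty.strength)
    if kind == "none" or lam == 0.0:
        kind_eff, lam_eff = "none", 0.0
    else:
        kind_eff, lam_eff = kind, lam

    if family == "gaussian":
        w, b = _fit_gaussian(Xs, y, kind_eff, lam_eff)
    else:
        w, b = _fit_bernoulli(Xs, y, kind_eff, lam_eff, seed)

    # a zero-variance (constant) predictor carries no information and, once
    # standardized to all-zeros, must have exactly zero weight
    if standardize:
        w = np.where(_constant_columns(Xv), 0.0, w)

    return GLMModel(
        family=family,
        weights=w,
        intercept=float(b),
        penalty=penalty.kind,
        penalty_strength=lam,
        feature_ids=feature_ids,
        standardization=std,
    )


def predict(model: GLMModel, X) -> np.ndarray:
    """Model scores for X: probabilities in (0,1) for bernoulli, reals for gaussian.

    X may carry features in a different order; columns are re-aligned by id.
    """
    if model.weights is None:
        raise StateError("model has no fitted weights")
    if isinstance(X, DesignMatrix):
        if X.feature_ids != model.feature_ids:
            if set(X.feature_ids) != set(model.feature_ids):
                missing = sorted(set(model.feature_ids) - set(X.feature_ids))
                raise SchemaError(f"feature mismatch; missing {missing[:5]}")
            X = X.subset_features(model.feature_ids)
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[None, :]
    if Xv.shape[1] != len(model.feature_ids):
        raise SchemaError(
            f"{Xv.shape[1]} columns for a {len(model.feature_ids)}-feature model"
        )
    if model.standardization is not None:
        center, scale = model.standardization
        Xv = (Xv - center) / scale
    z = Xv @ model.weights + model.intercept
    if model.family == "bernoulli":
        return np.clip(expit(z), _PROB_EPS, 1.0 - _PROB_EPS)
    return z


def rank_features(model: GLMModel) -> list[str]:
    """Feature ids sorted by decreasing |weight|; ties keep input order.

    Zero-weight features necessarily sort last.
    """
    if model.weights is None:
        raise StateError("cannot rank features of an unfitted model")
    order = np.argsort(-np.abs(model.weights), kind="stable")
    return [model.feature_ids[k] for k in order]


def lambda_grid(X, y, n_lambda: int = N_LAMBDA, ratio: float = LAMBDA_RATIO) -> np.ndarray:
    """Descending logarithmic candidate grid for the penalty strength.

    Anchored at lambda_max = max_k |x_k . (y - mean(y))| on the standardized
    design: for L1 fits this is the smallest strength at which every weight is
    exactly zero; the same anchor is reused as a scale for L2 grids.
    """
    Xv = _as_values(X)
    y = np.asarray(y, dtype=float).ravel()
    Xs, _, _ = _standardize(Xv)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))))
    if not np.isfinite(lam_max) or lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _deviance_path_fold(Xtr, ytr, Xva, yva, family, kind, grid, seed):
    """Held-out deviance per candidate lambda for one CV fold."""
    Xs, center, scale = _standardize(Xtr)
    Xvs = (Xva - center) / scale
    if family == "bernoulli":
        if kind == "l2":
            W, B = _logistic_l2_path(Xs, ytr, grid)
        else:
            W, B = _logistic_l1_path(Xs, ytr, grid, seed)
        Z = Xvs @ W.T + B
        P = np.clip(expit(Z), _PROB_EPS, 1.0 - _PROB_EPS)
        yv = yva[:, None]
        dev = -2.0 * (yv * np.log(P) + (1.0 - yv) * np.log(1.0 - P)).sum(axis=0)
        return dev
    ybar = ytr.mean()
    yc = ytr - ybar
    if kind == "l1":
        n = Xs.shape[0]
        _, coefs, _ = lasso_path(Xs, yc, alphas=grid / n, max_iter=10_000, tol=1e-5)
        Zhat = Xvs @ coefs + ybar  # (n_val, n_lambda)
    else:
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        uty = U.T @ yc
        D = s[:, None] / (s[:, None] ** 2 + 2.0 * grid[None, :])
        Wl = Vt.T @ (D * uty[:, None])  # (p, n_lambda)
        Zhat = Xvs @ Wl + ybar
    return ((yva[:, None] - Zhat) ** 2).sum(axis=0)


def select_lambda_cv(
    X,
    y,
    family: str,
    penalty_kind: str,
    n_folds: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> float:
    """Choose the penalty strength by K-fold CV on held-out deviance.

    Folds are stratified by class for bernoulli responses and are a
    deterministic function of ``seed``. Among equal mean deviances the largest
    (most regularized) candidate wins.
    """
    if penalty_kind not in ("l1", "l2"):
        raise ConfigurationError("penalty_kind must be 'l1' or 'l2' for CV selection")
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    Xv = _as_values(X)
    y = _check_response(y, family, Xv.shape[0])
    if n_folds < 2:
        raise ConfigurationError("need at least 2 folds")
    rs = int(seed) % (2**31)
    if family == "bernoulli":
        n1 = int(y.sum())
        n0 = len(y) - n1
        if min(n0, n1) < n_folds:
            raise ConfigurationError(
                f"cannot build {n_folds} stratified folds with class counts ({n0}, {n1})"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        split_iter = splitter.split(Xv, y)
    else:
        if len(y) < n_folds:
            raise ConfigurationError(f"{len(y)} samples cannot fill {n_folds} folds")
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
        split_iter = splitter.split(Xv)

    if grid is None:
        grid = lambda_grid(Xv, y)
    grid = np.asarray(grid, dtype=float)

    total = np.zeros(len(grid))
    for tr, va in split_iter:
        total += _deviance_path_fold(
            Xv[tr], y[tr], Xv[va], y[va], family, penalty_kind, grid, seed
        )
    # grid is descending, argmin takes the first (largest lambda) among ties
    return float(grid[int(np.argmin(total))])
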