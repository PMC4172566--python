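"""GLM engine tests: penalized-objective oracles, prediction identities, ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from drugclf import (
    DesignMatrix,
    GLMModel,
    PenaltySpec,
    fit_glm,
    lambda_grid,
    penalized_objective,
    predict,
    rank_features,
    select_lambda_cv,
)
from drugclf.exceptions import (
    ConfigurationError,
    DataQualityError,
    EmptyInputError,
    InvalidResponseError,
    SchemaError,
    StateError,
)

from conftest import toy_design


# ---------------------------------------------------------------------------
# independent oracle: direct numerical minimization of the penalized objective
# ---------------------------------------------------------------------------


def reference_objective(params, X, y, family, kind, lam):
    w, b = params[:-1], params[-1]
    z = X @ w + b
    if family == "bernoulli":
        nll = np.sum(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y * z)
    else:
        nll = 0.5 * np.sum((y - z) ** 2)
    pen = lam * (np.abs(w).sum() if kind == "l1" else w @ w) if kind != "none" else 0.0
    return nll + pen


def oracle_minimum(X, y, family, kind, lam):
    """Coarse grid search then Nelder-Mead polish; independent of the package."""
    p = X.shape[1]
    grid = np.linspace(-4, 4, 9)
    best, best_val = None, np.inf
    mesh = np.meshgrid(*([grid] * (p + 1)))
    for params in zip(*(m.ravel() for m in mesh)):
        v = reference_objective(np.asarray(params), X, y, family, kind, lam)
        if v < best_val:
            best, best_val = np.asarray(params), v
    res = minimize(
        reference_objective,
        best,
        args=(X, y, family, kind, lam),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    return res.fun


@pytest.mark.parametrize("family", ["bernoulli", "gaussian"])
@pytest.mark.parametrize("kind,lam", [("l1", 0.7), ("l2", 0.5), ("none", 0.0)])
def test_fit_matches_direct_minimization(family, kind, lam):
    """Across 24 random small instances the fit's penalized objective matches a
    brute-force grid + simplex minimization of the same objective to 1e-3."""
    rng = np.random.default_rng(42)
    n_checked = 0
    for _ in range(8):
        n = int(rng.integers(4, 9))
        p = int(rng.integers(1, 3))
        X = rng.normal(size=(n, p))
        if family == "bernoulli":
            y = (rng.random(n) < 0.5).astype(float)
            if y.min() == y.max():
                y[0] = 1 - y[0]
        else:
            y = rng.normal(size=n)
        model = fit_glm(X, y, family, PenaltySpec(kind, lam), standardize=False)
        ours = penalized_objective(model, X, y)
        theirs = oracle_minimum(X, y, family, kind, lam)
        assert ours <= theirs + 1e-3
        n_checked += 1
    assert n_checked == 8


def test_l2_bernoulli_weights_match_grid_search_example():
    """6 samples x 2 features, L2 strength 0.5: weights agree with a dense grid
    search over (b1, b2, intercept) of the penalized log-likelihood to 1e-3."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(6, 2))
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    model = fit_glm(X, y, "bernoulli", PenaltySpec("l2", 0.5), standardize=False)
    res = minimize(
        reference_objective,
        np.zeros(3),
        args=(X, y, "bernoulli", "l2", 0.5),
        method="BFGS",
        options={"gtol": 1e-12},
    )
    assert np.allclose(model.weights, res.x[:2], atol=1e-3)
    assert np.isclose(model.intercept, res.x[2], atol=1e-3)


# ---------------------------------------------------------------------------
# fit_glm contracts
# ---------------------------------------------------------------------------


def test_constant_feature_gets_zero_weight():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 3))
    X[:, 1] = 4.2  # constant column
    y = (rng.random(20) < 0.5).astype(float)
    y[0] = 1 - y[0] if y.min() == y.max() else y[0]
    for kind in ("l1", "l2"):
        m = fit_glm(X, y, "bernoulli", PenaltySpec(kind, 1.0))
        assert m.weights[1] == 0.0


@pytest.mark.parametrize("family", ["bernoulli", "gaussian"])
def test_huge_l1_penalty_zeroes_weights_and_leaves_link_mean(family):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 4))
    y = (rng.random(30) < 0.4).astype(float) if family == "bernoulli" else rng.normal(2.0, 1.0, 30)
    m = fit_glm(X, y, family, PenaltySpec("l1", 1e9))
    assert np.all(m.weights == 0.0)
    expected = np.log(y.mean() / (1 - y.mean())) if family == "bernoulli" else y.mean()
    assert np.isclose(m.intercept, expected, atol=1e-4)


def test_penalized_objective_no_worse_than_zero_solution():
    """Optimizer sanity: the returned solution never loses to all-zero weights."""
    rng = np.random.default_rng(3)
    for kind, lam in [("l1", 0.3), ("l2", 1.2), ("none", 0.0)]:
        for family in ("bernoulli", "gaussian"):
            X = rng.normal(size=(25, 5))
            y = (rng.random(25) < 0.5).astype(float) if family == "bernoulli" else rng.normal(size=25)
            m = fit_glm(X, y, family, PenaltySpec(kind, lam))
            zero = GLMModel(
                family=family,
                weights=np.zeros(5),
                intercept=m.intercept,
                penalty=kind,
                penalty_strength=lam,
                feature_ids=m.feature_ids,
                standardization=m.standardization,
            )
            assert penalized_objective(m, X, y) <= penalized_objective(zero, X, y) + 1e-8


def test_unpenalized_fit_terminates_on_separable_data():
    X = np.linspace(-2, 2, 12)[:, None]
    y = (X[:, 0] > 0).astype(float)
    m = fit_glm(X, y, "bernoulli", PenaltySpec("none", 0.0))
    p = predict(m, X)
    assert np.all((p > 0) & (p < 1))
    assert np.all(p[y == 1] > 0.5) and np.all(p[y == 0] < 0.5)


def test_fit_errors():
    X = toy_design(6, 2)
    with pytest.raises(InvalidResponseError):
        fit_glm(X, np.array([0, 1, 2, 0, 1, 0]), "bernoulli")
    with pytest.raises(EmptyInputError):
        fit_glm(np.empty((0, 2)), np.empty(0), "gaussian")
    with pytest.raises(EmptyInputError):
        fit_glm(np.empty((5, 0)), np.zeros(5), "gaussian")
    bad = X.values.copy()
    bad[0, 0] = np.nan
    with pytest.raises(DataQualityError):
        fit_glm(bad, np.zeros(6), "gaussian")
    with pytest.raises(DataQualityError):
        fit_glm(X, np.array([0.0, 1, np.inf, 0, 1, 0]), "gaussian")


# ---------------------------------------------------------------------------
# predict
# ---------------------------------------------------------------------------


def test_zero_model_predicts_half():
    m = GLMModel("bernoulli", np.zeros(3), 0.0, "none", 0.0, ["a", "b", "c"])
    p = predict(m, np.zeros((4, 3)))
    assert np.all(p == 0.5)


def test_gaussian_identity_arithmetic():
    m = GLMModel("gaussian", np.array([2.0, -1.0]), 3.0, "none", 0.0, ["a", "b"])
    assert predict(m, np.array([[1.0, 1.0]]))[0] == pytest.approx(4.0)


def test_predictions_are_row_independent(small_cellset):
    y = small_cellset.labels.astype(float)
    m = fit_glm(small_cellset.expression, y, "bernoulli", PenaltySpec("l2", 1.0))
    X = small_cellset.expression.values[:5]
    batch = predict(m, X)
    singles = np.concatenate([predict(m, X[i : i + 1]) for i in range(5)])
    assert np.allclose(batch, singles, rtol=0, atol=1e-12)


def test_predict_realigns_features_by_id():
    rng = np.random.default_rng(5)
    X = DesignMatrix(rng.normal(size=(10, 3)), ["a", "b", "c"], [str(i) for i in range(10)])
    y = rng.normal(size=10)
    m = fit_glm(X, y, "gaussian")
    shuffled = X.subset_features(["c", "a", "b"])
    assert np.allclose(predict(m, X), predict(m, shuffled))
    with pytest.raises(SchemaError):
        predict(m, X.subset_features(["a", "b"]))


def test_rescaled_feature_leaves_predictions_unchanged():
    """Doubling a column's scale changes the stored standardization, not the
    predictions: coefficients live on the z-scored scale."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 3))
    y = rng.normal(size=30) + X[:, 0]
    m1 = fit_glm(X, y, "gaussian", PenaltySpec("l2", 0.5))
    X2 = X.copy()
    X2[:, 0] *= 2.0
    m2 = fit_glm(X2, y, "gaussian", PenaltySpec("l2", 0.5))
    assert np.allclose(predict(m1, X), predict(m2, X2), atol=1e-8)


# ---------------------------------------------------------------------------
# rank_features
# ---------------------------------------------------------------------------


def test_rank_by_magnitude_with_ties_and_zeros():
    m = GLMModel("gaussian", np.array([0.1, -3.0, 0.0]), 0.0, "none", 0.0, ["f1", "f2", "f3"])
    assert rank_features(m) == ["f2", "f1", "f3"]
    tied = GLMModel("gaussian", np.array([1.0, -1.0, 1.0]), 0.0, "none", 0.0, ["a", "b", "c"])
    assert rank_features(tied) == ["a", "b", "c"]


def test_rank_is_permutation_and_requires_fit():
    rng = np.random.default_rng(8)
    X = toy_design(12, 2, seed=9)
    m = fit_glm(X, rng.normal(size=12), "gaussian", PenaltySpec("l1", 0.1))
    assert sorted(rank_features(m)) == sorted(m.feature_ids)
    unfitted = GLMModel("gaussian", None, 0.0, "none", 0.0, ["a"])
    with pytest.raises(StateError):
        rank_features(unfitted)


# ---------------------------------------------------------------------------
# lambda selection
# ---------------------------------------------------------------------------


def test_lambda_grid_shape_and_l1_zeroing():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(30, 5))
    y = rng.normal(size=30)
    grid = lambda_grid(X, y)
    assert len(grid) == 50 and grid[0] > grid[-1]
    assert np.isclose(grid[-1], grid[0] * 1e-4)
    # at lambda_max every L1 weight is exactly zero
    m = fit_glm(X, y, "gaussian", PenaltySpec("l1", grid[0]))
    assert np.all(m.weights == 0.0)


def test_select_lambda_pure_noise_l1_shrinks_everything(nosignal_cellset):
    X = nosignal_cellset.expression
    y = nosignal_cellset.labels.astype(float)
    lam = select_lambda_cv(X, y, "bernoulli", "l1", n_folds=5, seed=0)
    m = fit_glm(X, y, "bernoulli", PenaltySpec("l1", lam), seed=0)
    assert np.count_nonzero(m.weights) <= 1


def test_select_lambda_keeps_signal(small_cellset):
    X = small_cellset.expression
    y = small_cellset.labels.astype(float)
    lam = select_lambda_cv(X, y, "bernoulli", "l1", n_folds=5, seed=0)
    m = fit_glm(X, y, "bernoulli", PenaltySpec("l1", lam), seed=0)
    assert np.count_nonzero(m.weights) >= 1


def test_select_lambda_deterministic(small_cellset):
    X = small_cellset.expression
    y = small_cellset.labels.astype(float)
    a = select_lambda_cv(X, y, "bernoulli", "l2", seed=33)
    b = select_lambda_cv(X, y, "bernoulli", "l2", seed=33)
    assert a == b


def test_select_lambda_fold_infeasibility():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(12, 3))
    y = np.array([1, 1, 1] + [0] * 9, dtype=float)  # only 3 positives
    with pytest.raises(ConfigurationError):
        select_lambda_cv(X, y, "bernoulli", "l2", n_folds=10)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(12)
    X = toy_design(15, 2, seed=13)
    m = fit_glm(X, rng.normal(size=15), "gaussian", PenaltySpec("l1", 0.2))
    path = tmp_path / "model.json"
    m.to_json(path)
    back = GLMModel.from_json(path)
    assert back.family == m.family and back.feature_ids == m.feature_ids
    assert np.allclose(back.weights, m.weights)
    assert np.allclose(predict(back, X), predict(m, X))
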