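"""Chemosensitivity modelling (Part II): drugs as classifiers of gene expression.

Each drug's sensitivity across a cell-line panel (-log(GI50); larger = the
line is killed at lower concentration) is modelled as a sparse linear function
of gene expression: a gaussian GLM with an L1 penalty, which performs gene
selection among hundreds-to-thousands of candidates. Out-of-sample accuracy is
measured by leave-one-out cross-validation R^2 (the penalty strength is
re-selected inside every training set, so the held-out line never influences
model selection). A two-gene sensitivity heatmap visualizes a drug's response
surface over its two most informative genes via scattered-data interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from . import glm
from .exceptions import (
    ConfigurationError,
    DrugLookupError,
    InterpolationError,
    SampleSizeError,
    SchemaError,
    UndefinedR2Error,
)
from .glm import DesignMatrix, GLMModel, PenaltySpec

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CellLinePanel:
    """Cell-line panel: expression, drug sensitivities and subtype labels.

    ``sensitivity`` is lines x drugs in -log(GI50) units; NaN marks a missing
    measurement (dropped per drug at fit time). ``subtype_labels`` is 1 for
    basal-like ("aggressive") and 0 for luminal lines.
    """

    expression: DesignMatrix
    sensitivity: np.ndarray
    drug_ids: list[str]
    subtype_labels: np.ndarray

    def __post_init__(self) -> None:
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.subtype_labels = np.asarray(self.subtype_labels, dtype=int).ravel()
        n = self.expression.n_samples
        if self.sensitivity.shape != (n, len(self.drug_ids)):
            raise SchemaError(
                f"sensitivity shape {self.sensitivity.shape} does not match "
                f"{n} lines x {len(self.drug_ids)} drugs"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise SchemaError("duplicate drug ids")
        if self.subtype_labels.shape[0] != n:
            raise SchemaError("subtype_labels length must equal line count")
        if not np.isin(self.subtype_labels, (0, 1)).all():
            raise SchemaError("subtype labels must be 0/1")

    @property
    def n_lines(self) -> int:
        return self.expression.n_samples

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(str(drug_id))
        except ValueError:
            raise DrugLookupError(f"unknown drug {drug_id!r}") from None

    def drug_column(self, drug_id: str) -> np.ndarray:
        return self.sensitivity[:, self.drug_index(drug_id)]


@dataclass
class DrugModel:
    """Fitted sensitivity model for one drug plus its cross-validated accuracy."""

    drug_id: str
    glm: GLMModel
    loocv_r2: float | None = None
    gene_curve: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.loocv_r2 is not None and self.loocv_r2 > 1.0:
            raise ConfigurationError("LOOCV R^2 cannot exceed 1")


@dataclass
class SensitivityHeatmap:
    """Drug sensitivity interpolated over the expression of two genes."""

    gene_x: str
    gene_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    heat: np.ndarray

    def __post_init__(self) -> None:
        if self.heat.shape != (len(self.grid_y), len(self.grid_x)):
            raise SchemaError("heat dimensions must match grid lengths")


# ---------------------------------------------------------------------------
# fitting and cross-validation
# ---------------------------------------------------------------------------

_MIN_LINES = 10


def _drug_data(panel: CellLinePanel, drug_id: str):
    """Expression rows and sensitivities for the lines measured for this drug."""
    y = panel.drug_column(drug_id)
    mask = np.isfinite(y)
    if int(mask.sum()) < _MIN_LINES:
        raise SampleSizeError(
            f"drug {drug_id!r} has {int(mask.sum())} measured lines; need >= {_MIN_LINES}"
        )
    X = panel.expression.values[mask]
    return X, y[mask], mask


def fit_drug_model(
    panel: CellLinePanel,
    drug_id: str,
    seed: int = 0,
    inner_folds: int = 10,
    compute_loocv: bool = True,
) -> DrugModel:
    """L1-penalized gaussian GLM for one drug's sensitivity vs expression.

    The penalty strength is chosen by ``inner_folds``-fold CV; lines missing
    this drug's measurement are dropped for this drug only. With
    ``compute_loocv`` the leave-one-out R^2 is attached (costlier: one full
    re-selection + fit per line).
    """
    X, y, _ = _drug_data(panel, drug_id)
    lam = glm.select_lambda_cv(X, y, "gaussian", "l1", n_folds=inner_folds, seed=seed)
    fids = panel.expression.feature_ids
    model = glm.fit_glm(
        DesignMatrix(X, fids, [f"line{i}" for i in range(len(y))]),
        y,
        "gaussian",
        PenaltySpec("l1", lam),
        seed=seed,
    )
    r2 = loocv_r2(panel, drug_id, seed=seed, inner_folds=inner_folds) if compute_loocv else None
    return DrugModel(drug_id=str(drug_id), glm=model, loocv_r2=r2)


def loocv_predictions(
    panel: CellLinePanel,
    drug_id: str,
    seed: int = 0,
    inner_folds: int = 10,
    feature_subset: list[str] | None = None,
):
    """Held-out prediction for every measured line (leave-one-out).

    Returns (y_observed, y_predicted) over the lines measured for this drug.
    The penalty strength is re-selected within each training set of n-1 lines.
    """
    X, y, _ = _drug_data(panel, drug_id)
    if feature_subset is not None:
        pos = {f: k for k, f in enumerate(panel.expression.feature_ids)}
        cols = np.asarray([pos[f] for f in feature_subset])
        X = X[:, cols]
    n = len(y)
    folds = min(inner_folds, n - 1)
    preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        lam = glm.select_lambda_cv(
            X[tr], y[tr], "gaussian", "l1", n_folds=folds, seed=seed
        )
        model = glm.fit_glm(X[tr], y[tr], "gaussian", PenaltySpec("l1", lam), seed=seed)
        preds[i] = glm.predict(model, X[i : i + 1])[0]
    return y, preds


def r_squared(y_obs, y_pred) -> float:
    """Definitional R^2 = 1 - SSE/SST (can be negative for held-out predictions)."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedR2Error("response has zero variance")
    sse = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - sse / sst


def loocv_r2(panel: CellLinePanel, drug_id: str, seed: int = 0, inner_folds: int = 10) -> float:
    """Leave-one-out cross-validated R^2 for one drug (may be negative)."""
    y, preds = loocv_predictions(panel, drug_id, seed=seed, inner_folds=inner_folds)
    return r_squared(y, preds)


def r2_vs_gene_count(
    panel: CellLinePanel,
    drug_id: str,
    max_genes: int,
    seed: int = 0,
    ks=None,
    inner_folds: int = 10,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """LOOCV R^2 as a function of the number of genes considered.

    Within each leave-one-out training set a full-gene model ranks the genes
    by |weight|; for each k the design is restricted to that training set's
    top k and the held-out line re-predicted (lambda re-selected on the
    restriction). The CI is a percentile bootstrap over per-line squared
    errors. k = 0 is rejected.
    """
    p = panel.expression.n_features
    if max_genes < 1 or max_genes > p:
        raise ConfigurationError(f"max_genes must be in [1, {p}]")
    ks = np.arange(1, max_genes + 1) if ks is None else np.asarray(sorted(ks), dtype=int)
    if ks[0] < 1 or ks[-1] > p:
        raise ConfigurationError("every k must satisfy 1 <= k <= gene count")

    X, y, _ = _drug_data(panel, drug_id)
    n = len(y)
    folds = min(inner_folds, n - 1)
    preds = np.full((len(ks), n), np.nan)
    for i in range(n):
        tr = np.arange(n) != i
        lam = glm.select_lambda_cv(X[tr], y[tr], "gaussian", "l1", n_folds=folds, seed=seed)
        full = glm.fit_glm(X[tr], y[tr], "gaussian", PenaltySpec("l1", lam), seed=seed)
        ranked_idx = np.argsort(-np.abs(full.weights), kind="stable")
        for j, k in enumerate(ks):
            cols = ranked_idx[: int(k)]
            lam_k = (
                lam
                if k == p
                else glm.select_lambda_cv(
                    X[tr][:, cols], y[tr], "gaussian", "l1", n_folds=folds, seed=seed
                )
            )
            m = glm.fit_glm(
                X[tr][:, cols], y[tr], "gaussian", PenaltySpec("l1", lam_k), seed=seed
            )
            preds[j, i] = glm.predict(m, X[i : i + 1, cols])[0]

    sst_terms = (y - y.mean()) ** 2
    rng = np.random.default_rng(int(seed) % (2**31))
    rows = []
    for j, k in enumerate(ks):
        err = (y - preds[j]) ** 2
        r2 = 1.0 - err.sum() / sst_terms.sum()
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            denom = sst_terms[idx].sum()
            if denom > 0:
                boots.append(1.0 - err[idx].sum() / denom)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"k": int(k), "r2": float(r2), "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# visualization
# ---------------------------------------------------------------------------


def two_gene_heatmap(
    panel: CellLinePanel,
    drug_id: str,
    resolution: int = 100,
    seed: int = 0,
    model: DrugModel | None = None,
) -> SensitivityHeatmap:
    """Observed sensitivity interpolated over the drug's two best genes.

    The two genes are the two largest |weights| of an all-data fit (a
    descriptive, not cross-validated, choice). Observed (x, y, sensitivity)
    triples are linearly interpolated onto a resolution x resolution grid over
    the observed expression range; grid cells outside the convex hull of the
    observations take their nearest observed value.
    """
    if resolution < 2:
        raise ConfigurationError("resolution must be >= 2")
    if model is None:
        model = fit_drug_model(panel, drug_id, seed=seed, compute_loocv=False)
    ranked = glm.rank_features(model.glm)
    gene_x, gene_y = ranked[0], ranked[1]
    _, y, mask = _drug_data(panel, drug_id)
    expr = panel.expression
    ix = expr.feature_ids.index(gene_x)
    iy = expr.feature_ids.index(gene_y)
    px = expr.values[mask, ix]
    py = expr.values[mask, iy]
    pts = np.column_stack([px, py])
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise InterpolationError("need >= 3 non-collinear observation points")
    gx = np.linspace(px.min(), px.max(), resolution)
    gy = np.linspace(py.min(), py.max(), resolution)
    GX, GY = np.meshgrid(gx, gy)
    heat = griddata(pts, y, (GX, GY), method="linear")
    outside = ~np.isfinite(heat)
    if outside.any():
        nearest = griddata(pts, y, (GX, GY), method="nearest")
        heat[outside] = nearest[outside]
    return SensitivityHeatmap(gene_x=gene_x, gene_y=gene_y, grid_x=gx, grid_y=gy, heat=heat)
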