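"""Single-cell cancer-vs-healthy classification (Part I of the pipeline).

A bernoulli GLM with L2 shrinkage scores each cell's probability of being
cancerous. Generalization is measured with nested 10-fold cross-validation:
inner folds pick the penalty strength on the training split only, outer folds
produce one strictly held-out score per cell. Discriminability is summarized
as the area under the ROC curve (AUC; 1 = perfect separation, 0.5 = chance).
Chance levels come from a shuffle control (label permutation), and the effect
of measuring more genes or more cells is traced with learning curves carrying
bootstrapped 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import glm
from .exceptions import (
    ConfigurationError,
    DataQualityError,
    EmptyInputError,
    StratificationError,
    UndefinedROCError,
)
from .glm import DesignMatrix, PenaltySpec

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LabeledCellSet:
    """Cells x genes expression with binary labels (0 = healthy, 1 = cancer)."""

    expression: DesignMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.shape[0] != self.expression.n_samples:
            raise ConfigurationError("labels length must equal cell count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ConfigurationError("labels must be 0/1")
        if len(np.unique(self.labels)) < 2:
            raise StratificationError("both classes must be present")

    @property
    def n_cells(self) -> int:
        return self.expression.n_samples


@dataclass
class ROCResult:
    """ROC curve (FPR/TPR over score thresholds) plus its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class LearningCurve:
    """Mean AUC with bootstrapped 95% CI and shuffle chance level vs x.

    ``x_values`` is the number of genes (gene-count curve) or of training
    cells (cell-count curve).
    """

    x_values: np.ndarray
    mean_auc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    chance_auc: np.ndarray


@dataclass
class ShuffleNullSummary:
    """Permutation-null AUC distribution summary from the shuffle control."""

    mean: float
    p2_5: float
    p97_5: float
    aucs: np.ndarray


# ---------------------------------------------------------------------------
# core scoring
# ---------------------------------------------------------------------------


def _spawn_ints(seed: int, n: int, key: tuple = ()) -> np.ndarray:
    """Deterministic child seeds below 2**31 from one root seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return (ss.generate_state(n, dtype=np.uint64) % (2**31)).astype(np.int64)


def _outer_folds(labels, n_folds, rs):
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if min(n0, n1) < n_folds:
        raise StratificationError(
            f"cannot stratify {n_folds} folds with class counts ({n0}, {n1})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rs))
    return list(skf.split(np.zeros(len(labels)), labels))


def _fit_scored_fold(X, y, tr, va, inner_folds, penalty_kind, seed):
    """Select lambda on the training split, fit, and score the held-out split."""
    lam = glm.select_lambda_cv(
        X[tr], y[tr], "bernoulli", penalty_kind, n_folds=inner_folds, seed=seed
    )
    model = glm.fit_glm(
        X[tr], y[tr], "bernoulli", PenaltySpec(penalty_kind, lam), seed=seed
    )
    return glm.predict(model, X[va]), model


def nested_cv_scores(
    data: LabeledCellSet,
    outer_folds: int = 10,
    inner_folds: int = 10,
    penalty_kind: str = "l2",
    seed: int = 0,
    return_folds: bool = False,
):
    """Out-of-fold probability scores from nested stratified cross-validation.

    Every cell is scored exactly once, by a model whose training split (and
    whose inner-CV penalty selection) never saw that cell.
    """
    X = data.expression.values
    y = data.labels.astype(float)
    seeds = _spawn_ints(seed, outer_folds + 1)
    folds = _outer_folds(data.labels, outer_folds, seeds[0])
    scores = np.full(len(y), np.nan)
    for k, (tr, va) in enumerate(folds):
        s, _ = _fit_scored_fold(X, y, tr, va, inner_folds, penalty_kind, seeds[k + 1])
        scores[va] = s
    if return_folds:
        return scores, folds
    return scores


def roc_and_auc(scores, labels) -> ROCResult:
    """ROC curve over the unique score thresholds plus its trapezoidal AUC.

    Higher scores must indicate the positive (cancer) class. Tied scores get
    half credit, so the AUC equals the Mann-Whitney U statistic / (n1*n0).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.shape != labels.shape:
        raise ConfigurationError("scores and labels must have equal length")
    if scores.size == 0:
        raise EmptyInputError("empty scores")
    if not np.isfinite(scores).all():
        raise DataQualityError("non-finite score")
    if len(np.unique(labels)) < 2:
        raise UndefinedROCError("ROC undefined with a single class")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def shuffle_control(
    data: LabeledCellSet,
    n_permutations: int = 100,
    seed: int = 0,
    outer_folds: int = 10,
    inner_folds: int = 10,
    penalty_kind: str = "l2",
) -> ShuffleNullSummary:
    """Chance-level AUC distribution: rerun the full nested CV on permuted labels.

    Permuting the healthy/cancer labels destroys any real association between
    expression and class, so the resulting AUCs sample the null distribution a
    random predictor would produce (centered on 0.5).
    """
    if n_permutations < 20:
        raise ConfigurationError("need at least 20 permutations for a usable null")
    aucs = np.empty(n_permutations)
    perm_seeds = _spawn_ints(seed, n_permutations, key=(1,))
    run_seeds = _spawn_ints(seed, n_permutations, key=(2,))
    for i in range(n_permutations):
        rng = np.random.default_rng(int(perm_seeds[i]))
        perm = rng.permutation(data.n_cells)
        shuffled = LabeledCellSet(data.expression, data.labels[perm])
        s = nested_cv_scores(
            shuffled, outer_folds, inner_folds, penalty_kind, seed=int(run_seeds[i])
        )
        aucs[i] = roc_and_auc(s, shuffled.labels).auc
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return ShuffleNullSummary(float(aucs.mean()), float(lo), float(hi), aucs)


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------


def bootstrap_ci(per_iteration_statistics, n_boot: int = 1000, seed: int = 0):
    """Percentile-bootstrap 95% interval for the mean of a statistic vector."""
    stats = np.asarray(per_iteration_statistics, dtype=float).ravel()
    if stats.size == 0:
        raise EmptyInputError("no statistics to bootstrap")
    if stats.size < 2:
        return float(stats[0]), float(stats[0])
    rng = np.random.default_rng(int(seed))
    idx = rng.integers(0, stats.size, size=(n_boot, stats.size))
    means = stats[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def _bootstrap_auc_ci(scores, labels, n_boot, rng):
    """Percentile bootstrap of the pooled AUC by resampling cells."""
    n = len(labels)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        aucs.append(roc_and_auc(scores[idx], lb).auc)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _score_permutation_chance(scores, labels, rng, n_perm: int = 100) -> float:
    """Mean AUC when labels are permuted against the fixed pooled scores."""
    vals = np.empty(n_perm)
    for i in range(n_perm):
        vals[i] = roc_and_auc(scores, labels[rng.permutation(len(labels))]).auc
    return float(vals.mean())


def gene_count_curve(
    data: LabeledCellSet,
    max_genes: int,
    seed: int = 0,
    ks=None,
    outer_folds: int = 10,
    inner_folds: int = 10,
    penalty_kind: str = "l2",
    n_boot: int = 1000,
) -> LearningCurve:
    """Nested-CV AUC as a function of the number of genes considered.

    Inside each outer training fold a full-gene model is fitted and its genes
    ranked by |weight|; the design is then restricted to the top k and the
    nested CV (including lambda re-selection) rerun on that restriction, so no
    information from the held-out cells enters the gene ranking.
    """
    p = data.expression.n_features
    if max_genes > p:
        raise ConfigurationError(f"max_genes {max_genes} exceeds {p} genes")
    if max_genes < 1:
        raise ConfigurationError("max_genes must be >= 1")
    ks = np.arange(1, max_genes + 1) if ks is None else np.asarray(sorted(ks), dtype=int)
    if ks[0] < 1 or ks[-1] > p:
        raise ConfigurationError("every k must satisfy 1 <= k <= gene count")

    X = data.expression
    y = data.labels.astype(float)
    seeds = _spawn_ints(seed, outer_folds + 1)
    folds = _outer_folds(data.labels, outer_folds, seeds[0])
    scores = np.full((len(ks), data.n_cells), np.nan)
    for f, (tr, va) in enumerate(folds):
        fold_seed = int(seeds[f + 1])
        _, full_model = _fit_scored_fold(
            X.values, y, tr, va, inner_folds, penalty_kind, fold_seed
        )
        ranked_idx = np.argsort(-np.abs(full_model.weights), kind="stable")
        for j, k in enumerate(ks):
            cols = ranked_idx[: int(k)]
            s, _ = _fit_scored_fold(
                X.values[:, cols], y, tr, va, inner_folds, penalty_kind, fold_seed
            )
            scores[j, va] = s

    rng = np.random.default_rng(int(_spawn_ints(seed, 1, key=(3,))[0]))
    mean_auc = np.empty(len(ks))
    lo = np.empty(len(ks))
    hi = np.empty(len(ks))
    chance = np.empty(len(ks))
    for j in range(len(ks)):
        mean_auc[j] = roc_and_auc(scores[j], data.labels).auc
        lo[j], hi[j] = _bootstrap_auc_ci(scores[j], data.labels, n_boot, rng)
        chance[j] = _score_permutation_chance(scores[j], data.labels, rng)
    return LearningCurve(ks, mean_auc, lo, hi, chance)


def _subset_lambda(X, y, inner_folds, seed):
    """Penalty strength for a training subset, falling back when CV is infeasible.

    With fewer than 2 cells per class no stratified CV exists (the smallest
    subsets trained here hold one cell per class); the fallback is the
    geometric middle of the candidate grid, lambda_max * 1e-2.
    """
    counts = np.bincount(y.astype(int), minlength=2)
    feasible = int(min(counts[0], counts[1]))
    if feasible >= 2:
        return glm.select_lambda_cv(
            X, y, "bernoulli", "l2", n_folds=min(inner_folds, feasible), seed=seed
        )
    grid = glm.lambda_grid(X, y)
    return float(grid[0] * 1e-2)


def cell_count_curve(
    data: LabeledCellSet,
    train_sizes,
    n_iterations: int = 100,
    ks=None,
    seed: int = 0,
    inner_folds: int = 10,
    penalty_kind: str = "l2",
    n_boot: int = 1000,
) -> dict[int, LearningCurve]:
    """AUC vs gene count for a range of training-set sizes (100 subsample draws).

    For each size, each iteration draws a class-balanced random training subset
    (size/2 healthy + size/2 cancer), trains, and measures AUC on the strictly
    held-out remaining cells. Returns one gene-count LearningCurve per size;
    CIs are a percentile bootstrap over the iteration AUCs.
    """
    if penalty_kind != "l2":
        raise ConfigurationError("cell_count_curve supports the Part-I l2 penalty")
    y = data.labels
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    p = data.expression.n_features
    ks = np.asarray([p] if ks is None else sorted(ks), dtype=int)
    if ks[0] < 1 or ks[-1] > p:
        raise ConfigurationError("every k must satisfy 1 <= k <= gene count")
    train_sizes = [int(s) for s in train_sizes]
    for s in train_sizes:
        if s < 2 or s % 2 != 0:
            raise ConfigurationError("train sizes must be even and >= 2 (balanced classes)")
        if s // 2 >= min(len(idx0), len(idx1)):
            raise ConfigurationError(
                f"train size {s} leaves no held-out cells in the smaller class"
            )

    X = data.expression.values
    yf = y.astype(float)
    out: dict[int, LearningCurve] = {}
    for si, size in enumerate(train_sizes):
        half = size // 2
        iter_aucs = np.full((len(ks), n_iterations), np.nan)
        draw_seeds = _spawn_ints(seed, n_iterations, key=(4, si))
        for it in range(n_iterations):
            rng = np.random.default_rng(int(draw_seeds[it]))
            tr = np.concatenate(
                [
                    rng.choice(idx0, size=half, replace=False),
                    rng.choice(idx1, size=half, replace=False),
                ]
            )
            mask = np.ones(len(y), dtype=bool)
            mask[tr] = False
            va = np.flatnonzero(mask)
            lam = _subset_lambda(X[tr], yf[tr], inner_folds, int(draw_seeds[it]))
            full = glm.fit_glm(
                X[tr], yf[tr], "bernoulli", PenaltySpec("l2", lam), seed=int(draw_seeds[it])
            )
            ranked_idx = np.argsort(-np.abs(full.weights), kind="stable")
            for j, k in enumerate(ks):
                cols = ranked_idx[: int(k)]
                if k == p:
                    model = full
                    Xva = X[va]
                else:
                    model = glm.fit_glm(
                        X[tr][:, cols],
                        yf[tr],
                        "bernoulli",
                        PenaltySpec("l2", lam),
                        seed=int(draw_seeds[it]),
                    )
                    Xva = X[va][:, cols]
                sc = glm.predict(model, Xva)
                iter_aucs[j, it] = roc_and_auc(sc, y[va]).auc
        rng = np.random.default_rng(int(_spawn_ints(seed, 1, key=(5, si))[0]))
        mean_auc = iter_aucs.mean(axis=1)
        lo = np.empty(len(ks))
        hi = np.empty(len(ks))
        for j in range(len(ks)):
            lo[j], hi[j] = bootstrap_ci(
                iter_aucs[j], n_boot=n_boot, seed=int(_spawn_ints(seed, 1, key=(6, si, j))[0])
            )
        out[size] = LearningCurve(
            ks, mean_auc, lo, hi, np.full(len(ks), 0.5)
        )
    return out
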