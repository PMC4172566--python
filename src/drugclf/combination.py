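"""Drug-pair compound classifiers (Part III).

Two drugs' sensitivities (-log(GI50)), measured or predicted from expression,
become the two features of an unregularized bernoulli GLM that discriminates
the aggressive (basal-like) from the less aggressive (luminal) population --
the boosting idea of combining weak classifiers. Each candidate pair is
scored by the mean held-out AUC over repeated 90/10 stratified subsampling
rounds, with a percentile-bootstrap CI over round AUCs and single-drug AUCs
computed on the identical splits for comparison. ``search_pairs`` evaluates
every unordered pair exhaustively.

With two features overfitting is unlikely, so no penalty is applied. By
default no multiple-comparison correction is made across the many pairs;
Benjamini-Hochberg annotation is available as an opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from . import glm
from .classification import bootstrap_ci, roc_and_auc
from .chemosensitivity import CellLinePanel, DrugModel
from .exceptions import (
    ConfigurationError,
    DataQualityError,
    DrugLookupError,
    StateError,
    StratificationError,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DrugFeatureVector:
    """One drug's per-line classifier feature: its chemosensitivity profile."""

    drug_id: str
    values: np.ndarray
    source: str  # 'measured' | 'predicted'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.source not in ("measured", "predicted"):
            raise ConfigurationError(f"unknown source {self.source!r}")
        if not np.isfinite(self.values).all():
            raise DataQualityError(
                f"drug feature {self.drug_id!r} has non-finite values"
            )


@dataclass
class PairSearchResult:
    """One drug pair's compound-classifier performance vs its single drugs."""

    drug_a: str
    drug_b: str
    pair_auc: float
    pair_ci: tuple[float, float]
    auc_a: float
    auc_b: float
    weights: np.ndarray
    n_rounds: int
    n_redraws: int = 0
    p_value: float | None = None
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pair_auc <= 1.0):
            raise ConfigurationError("pair_auc must lie in [0, 1]")
        if self.pair_ci[0] > self.pair_ci[1]:
            raise ConfigurationError("CI bounds out of order")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def drug_feature(
    panel: CellLinePanel,
    drug_id: str,
    source: str = "predicted",
    model: DrugModel | None = None,
) -> DrugFeatureVector:
    """The per-line feature vector for one drug.

    ``measured`` returns the sensitivity column verbatim (all lines must be
    measured); ``predicted`` applies the drug's Part-II expression model to the
    panel and requires that fitted model -- there is no silent fallback.
    """
    if source == "measured":
        col = panel.drug_column(drug_id)
        return DrugFeatureVector(str(drug_id), col, "measured")
    if source == "predicted":
        if model is None:
            raise StateError(
                f"predicted feature for {drug_id!r} requires a fitted DrugModel"
            )
        if model.drug_id != str(drug_id):
            raise DrugLookupError(
                f"model is for {model.drug_id!r}, not {drug_id!r}"
            )
        vals = glm.predict(model.glm, panel.expression)
        return DrugFeatureVector(str(drug_id), vals, "predicted")
    raise ConfigurationError(f"unknown source {source!r}")


# ---------------------------------------------------------------------------
# fast batched unpenalized logistic fits
# ---------------------------------------------------------------------------


def _batched_logistic(Xb: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-8):
    """Newton fits of B unpenalized logistic models sharing one response.

    ``Xb`` has shape (B, n, k); an intercept column is appended internally.
    Returns coefficients of shape (B, k+1), intercept last. Iterations are
    bounded so separable splits terminate with large-but-finite weights.
    """
    B, n, k = Xb.shape
    Z = np.concatenate([Xb, np.ones((B, n, 1))], axis=2)
    beta = np.zeros((B, k + 1))
    ybar = min(max(float(y.mean()), 1e-6), 1.0 - 1.0e-6)
    beta[:, k] = np.log(ybar / (1 - ybar))

    def objective(bet):
        zz = np.einsum("bnk,bk->bn", Z, bet)
        return np.logaddexp(0.0, zz).sum(axis=1) - zz @ y

    f = objective(beta)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        zz = np.einsum("bnk,bk->bn", Z, beta)
        pr = expit(zz)
        r = pr - y[None, :]
        g = np.einsum("bn,bnk->bk", r, Z)
        if not active.any():
            break
        wt = pr * (1.0 - pr) + 1e-12
        H = np.einsum("bni,bn,bnj->bij", Z, wt, Z)
        H[:, np.arange(k + 1), np.arange(k + 1)] += 1e-10
        step = np.linalg.solve(H, g[..., None])[..., 0]
        # vectorized backtracking: halve steps wherever the objective rose
        t = np.where(active, 1.0, 0.0)
        descent = np.einsum("bk,bk->b", g, step)
        for _ in range(30):
            cand = beta - t[:, None] * step
            fc = objective(cand)
            bad = active & (fc > f - 1e-4 * t * descent)
            if not bad.any():
                break
            t = np.where(bad, t * 0.5, t)
        newf = objective(beta - t[:, None] * step)
        improved = f - newf
        beta = beta - t[:, None] * step
        f = newf
        active = active & (improved > tol * (1.0 + np.abs(f)))
    return beta


def _stratified_round_splits(labels, n_rounds, train_fraction, rng, max_redraws=1000):
    """Per-round stratified train/test index pairs; degenerate tests redrawn."""
    labels = np.asarray(labels, dtype=int)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if len(idx0) < 2 or len(idx1) < 2:
        raise StratificationError("need >= 2 lines per class for subsampling")
    n_tr0 = max(1, int(round(train_fraction * len(idx0))))
    n_tr1 = max(1, int(round(train_fraction * len(idx1))))
    n_tr0 = min(n_tr0, len(idx0) - 1)
    n_tr1 = min(n_tr1, len(idx1) - 1)
    splits = []
    redraws = 0
    for _ in range(n_rounds):
        for attempt in range(max_redraws):
            tr = np.concatenate(
                [
                    rng.choice(idx0, size=n_tr0, replace=False),
                    rng.choice(idx1, size=n_tr1, replace=False),
                ]
            )
            mask = np.ones(len(labels), dtype=bool)
            mask[tr] = False
            te = np.flatnonzero(mask)
            if labels[te].min() != labels[te].max():
                break
            redraws += 1
        else:
            raise StratificationError("could not draw a two-class test split")
        splits.append((tr, te))
    return splits, redraws


def _batched_mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Tie-aware AUC per row of ``scores`` (B, n); identical to the trapezoidal
    ROC integral computed by roc_and_auc (a property the tests enforce)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores, axis=1)
    r1 = ranks[:, labels == 1].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _round_aucs_for_feature_sets(F, feature_sets, labels, splits):
    """AUC per round for each feature set (columns of F), batched per round.

    F is lines x drugs; feature_sets is a list of column-index tuples. Returns
    an array (len(feature_sets), n_rounds).
    """
    labels = np.asarray(labels, dtype=int)
    y = labels.astype(float)
    nset = len(feature_sets)
    out = np.empty((nset, len(splits)))
    # group by feature-set width so each batch has a homogeneous design shape
    for w in sorted({len(fs) for fs in feature_sets}):
        members = [i for i, fs in enumerate(feature_sets) if len(fs) == w]
        cols = np.asarray([feature_sets[i] for i in members])  # (B, w)
        for r, (tr, te) in enumerate(splits):
            Xtr = F[tr][:, cols].transpose(1, 0, 2)  # (B, n_tr, w)
            beta = _batched_logistic(Xtr, y[tr])
            Xte = F[te][:, cols].transpose(1, 0, 2)
            scores = np.einsum("bnk,bk->bn", Xte, beta[:, :w]) + beta[:, w][:, None]
            out[members, r] = _batched_mann_whitney_auc(scores, labels[te])
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def evaluate_pair(
    x_a: DrugFeatureVector,
    x_b: DrugFeatureVector,
    labels,
    n_rounds: int = 100,
    train_fraction: float = 0.9,
    seed: int = 0,
    n_null: int = 0,
    splits=None,
) -> PairSearchResult:
    """Subsampled AUC of the two-drug compound classifier vs each drug alone.

    Per round an unpenalized bernoulli GLM on (x_a, x_b) is fitted to a
    stratified ``train_fraction`` subset and scored by AUC on the held-out
    rest; ``pair_auc`` is the mean over rounds with a percentile-bootstrap CI.
    Single-drug AUCs use the identical splits. With ``n_null`` > 0 a
    label-permutation p-value for the pair AUC is attached.
    """
    if n_rounds < 1:
        raise ConfigurationError("n_rounds must be >= 1")
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=int).ravel()
    if len(labels) != len(x_a.values) or len(labels) != len(x_b.values):
        raise ConfigurationError("feature vectors and labels must align")
    F = np.column_stack([x_a.values, x_b.values])
    rng = np.random.default_rng(int(seed) % (2**31))
    redraws = 0
    if splits is None:
        splits, redraws = _stratified_round_splits(labels, n_rounds, train_fraction, rng)
    sets = [(0, 1), (0,), (1,)]
    aucs = _round_aucs_for_feature_sets(F, sets, labels, splits)
    pair_auc = float(aucs[0].mean())
    ci = bootstrap_ci(aucs[0], seed=int(rng.integers(2**31)))
    # reported weights: one unpenalized fit on all lines
    full = glm.fit_glm(
        F, labels.astype(float), "bernoulli", glm.PenaltySpec("none", 0.0), seed=seed
    )
    p_value = None
    if n_null > 0:
        null = np.empty(n_null)
        for i in range(n_null):
            perm = rng.permutation(len(labels))
            nsplits, _ = _stratified_round_splits(
                labels[perm], len(splits), train_fraction, rng
            )
            null[i] = _round_aucs_for_feature_sets(
                F, [(0, 1)], labels[perm], nsplits
            )[0].mean()
        p_value = float((1 + np.sum(null >= pair_auc)) / (1 + n_null))
    return PairSearchResult(
        drug_a=x_a.drug_id,
        drug_b=x_b.drug_id,
        pair_auc=pair_auc,
        pair_ci=ci,
        auc_a=float(aucs[1].mean()),
        auc_b=float(aucs[2].mean()),
        weights=full.weights,
        n_rounds=len(splits),
        n_redraws=redraws,
        p_value=p_value,
    )


def panel_features(
    panel: CellLinePanel,
    source: str = "predicted",
    models: dict[str, DrugModel] | None = None,
    seed: int = 0,
) -> list[DrugFeatureVector]:
    """One feature vector per drug; fits Part-II models on demand for 'predicted'."""
    feats = []
    for d in panel.drug_ids:
        model = None
        if source == "predicted":
            if models is not None and d in models:
                model = models[d]
            else:
                from .chemosensitivity import fit_drug_model

                model = fit_drug_model(panel, d, seed=seed, compute_loocv=False)
        feats.append(drug_feature(panel, d, source=source, model=model))
    return feats


def search_pairs(
    panel: CellLinePanel | None = None,
    source: str = "predicted",
    n_rounds: int = 100,
    seed: int = 0,
    train_fraction: float = 0.9,
    models: dict[str, DrugModel] | None = None,
    features: list[DrugFeatureVector] | None = None,
    labels=None,
) -> list[PairSearchResult]:
    """Exhaustive drug-pair search, ranked by compound-classifier AUC.

    Evaluates all D*(D-1)/2 unordered pairs on one shared set of subsample
    splits (drawn from ``seed``), which makes pair and single-drug AUCs
    directly comparable across the table and the search symmetric in (A, B).
    Returns the full ranked list, not only the winner.
    """
    if features is None:
        if panel is None:
            raise ConfigurationError("provide a panel or precomputed features")
        features = panel_features(panel, source=source, models=models, seed=seed)
    if labels is None:
        if panel is None:
            raise ConfigurationError("labels required when no panel is given")
        labels = panel.subtype_labels
    labels = np.asarray(labels, dtype=int).ravel()
    D = len(features)
    if D < 2:
        raise ConfigurationError("need at least 2 drugs to search pairs")
    F = np.column_stack([f.values for f in features])
    rng = np.random.default_rng(int(seed) % (2**31))
    splits, redraws = _stratified_round_splits(labels, n_rounds, train_fraction, rng)

    singles = _round_aucs_for_feature_sets(
        F, [(j,) for j in range(D)], labels, splits
    )
    pairs = [(a, b) for a in range(D) for b in range(a + 1, D)]
    pair_aucs = _round_aucs_for_feature_sets(F, pairs, labels, splits)

    y = labels.astype(float)
    results = []
    ci_seeds = np.random.SeedSequence(int(seed), spawn_key=(7,)).generate_state(
        len(pairs), dtype=np.uint64
    ) % (2**31)
    for idx, (a, b) in enumerate(pairs):
        full = glm.fit_glm(
            F[:, [a, b]], y, "bernoulli", glm.PenaltySpec("none", 0.0), seed=seed
        )
        results.append(
            PairSearchResult(
                drug_a=features[a].drug_id,
                drug_b=features[b].drug_id,
                pair_auc=float(pair_aucs[idx].mean()),
                pair_ci=bootstrap_ci(pair_aucs[idx], seed=int(ci_seeds[idx])),
                auc_a=float(singles[a].mean()),
                auc_b=float(singles[b].mean()),
                weights=full.weights,
                n_rounds=n_rounds,
                n_redraws=redraws,
            )
        )
    results.sort(key=lambda r: -r.pair_auc)
    return results


def max_pair_auc_null(
    features: list[DrugFeatureVector],
    labels,
    n_permutations: int = 20,
    n_rounds: int = 20,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null of the *maximum* pair AUC over the whole search.

    Exposes the selection effect: even with no signal, the best of many pairs
    systematically exceeds 0.5, which is why the best-pair AUC must not be
    read as an unbiased estimate.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    F = np.column_stack([f.values for f in features])
    D = F.shape[1]
    pairs = [(a, b) for a in range(D) for b in range(a + 1, D)]
    rng = np.random.default_rng(int(seed) % (2**31))
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(labels))
        yl = labels[perm]
        splits, _ = _stratified_round_splits(yl, n_rounds, train_fraction, rng)
        aucs = _round_aucs_for_feature_sets(F, pairs, yl, splits)
        out[i] = aucs.mean(axis=1).max()
    return out


def multiplicity_adjust(
    results: list[PairSearchResult], method: str = "none"
) -> list[PairSearchResult]:
    """Optionally annotate FDR q-values across the searched pairs.

    The default ``none`` returns the input unchanged (no correction across
    pairs); ``benjamini_hochberg`` requires permutation p-values on every
    result and attaches Benjamini-Hochberg q-values.
    """
    if method == "none":
        return results
    if method != "benjamini_hochberg":
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    if any(r.p_value is None for r in results):
        raise StateError(
            "benjamini_hochberg requires permutation p-values on every result"
        )
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray([r.p_value for r in results], dtype=float)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [replace(r, q_value=float(q)) for r, q in zip(results, qvals)]
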