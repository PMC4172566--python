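"""Synthetic datasets with the statistical structure the analyses assume.

Two generators mirror the shapes of the two study datasets:

* a two-population single-cell expression set (gaussian log-expression, a
  sparse subset of informative genes shifted between healthy and tumor cells
  by a chosen effect size in pooled-SD units, optional assay-floor dropout)
  at the ~45-gene / <200-cell scale of single-cell PCR panels;
* a cell-line panel (45 lines x 74 drugs by default) whose drug sensitivities
  are sparse linear functions of expression plus gaussian noise, with a latent
  subtype axis u (basal-like iff u > 0) that individual drugs capture only
  partially, and an optional *complementary pair* of drugs reading u+v and
  u-v of a two-factor latent structure -- jointly they recover u, so the pair
  discriminates the subtypes better than either drug alone by construction.

Every dataset is fully determined by its config's seed, and ships with a
GroundTruth record (planted genes, true drug weights, latent factors) for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemosensitivity import CellLinePanel
from .classification import LabeledCellSet
from .exceptions import ConfigurationError
from .glm import DesignMatrix

# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class SingleCellSimConfig:
    """Two-population single-cell expression simulation parameters.

    ``effect_size`` is the mean shift of each informative gene between the
    populations, in pooled-SD units (the pooled SD equals ``noise_sd``).
    ``dropout_rate`` is the probability that a value is replaced by the assay
    floor (0.0), mimicking expression below the detection limit.
    """

    n_healthy: int = 90
    n_tumor: int = 90
    n_genes: int = 45
    n_informative: int = 10
    effect_size: float = 1.5
    dropout_rate: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_tumor < 1:
            raise ConfigurationError("need >= 1 cell per population")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ConfigurationError("n_informative must be in [0, n_genes]")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")


@dataclass
class PanelSimConfig:
    """Cell-line panel simulation parameters.

    Each drug's sensitivity is a ``support_size``-sparse linear combination of
    gene expression plus N(0, noise_sd^2) noise. ``subtype_effect`` scales the
    loadings of the latent subtype factor u on its marker genes. Optional
    ``n_null_drugs`` drugs carry pure-noise sensitivity (empty support).
    ``complementary_pair`` plants two drugs at the given drug indices whose
    sensitivities read u+v and u-v; the subtype label is 1 iff u > 0.
    """

    n_lines: int = 45
    n_genes: int = 500
    n_drugs: int = 74
    support_size: int = 5
    noise_sd: float = 0.5
    subtype_effect: float = 1.0
    n_null_drugs: int = 0
    complementary_pair: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 4:
            raise ConfigurationError("need >= 4 lines")
        if not (0 <= self.support_size <= self.n_genes):
            raise ConfigurationError("support_size must be in [0, n_genes]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_null_drugs < 0 or self.n_null_drugs > self.n_drugs:
            raise ConfigurationError("n_null_drugs must be in [0, n_drugs]")
        if self.n_genes < 2:
            raise ConfigurationError("need >= 2 genes")
        if self.complementary_pair is not None:
            a, b = self.complementary_pair
            if a == b or not (0 <= a < self.n_drugs) or not (0 <= b < self.n_drugs):
                raise ConfigurationError("complementary_pair must be two distinct drug indices")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    informative_gene_ids: list[str] = field(default_factory=list)
    drug_true_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_u: np.ndarray | None = None
    latent_v: np.ndarray | None = None
    subtype_labels: np.ndarray | None = None
    complementary_drug_ids: tuple[str, str] | None = None


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

_ASSAY_FLOOR = 0.0


def generate_single_cell_dataset(config: SingleCellSimConfig):
    """Draw a LabeledCellSet of two overlapping cell populations.

    Non-informative genes are identically distributed in both populations;
    informative genes are shifted upward in tumor cells by
    ``effect_size * noise_sd`` on the log-expression scale.
    """
    rng = np.random.default_rng(int(config.seed))
    n = config.n_healthy + config.n_tumor
    base = rng.normal(5.0, 1.0, size=config.n_genes)
    expr = base + rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    labels = np.concatenate(
        [np.zeros(config.n_healthy, dtype=int), np.ones(config.n_tumor, dtype=int)]
    )
    informative = rng.choice(config.n_genes, size=config.n_informative, replace=False)
    shift = config.effect_size * config.noise_sd
    expr[np.ix_(labels == 1, informative)] += shift
    if config.dropout_rate > 0:
        mask = rng.random(expr.shape) < config.dropout_rate
        expr[mask] = _ASSAY_FLOOR
    gene_ids = [f"g{j:03d}" for j in range(config.n_genes)]
    cell_ids = [f"healthy_{i:03d}" for i in range(config.n_healthy)] + [
        f"tumor_{i:03d}" for i in range(config.n_tumor)
    ]
    data = LabeledCellSet(DesignMatrix(expr, gene_ids, cell_ids), labels)
    truth = GroundTruth(informative_gene_ids=[gene_ids[j] for j in sorted(informative)])
    return data, truth


def generate_cell_line_panel(config: PanelSimConfig):
    """Draw a CellLinePanel with sparse linear drug-response structure.

    Gene blocks: genes 0..19 load on the latent subtype factor u, genes 20..39
    on a second factor v (fewer when n_genes is small), the rest are pure
    noise. With ``complementary_pair`` set, genes 0 and 1 become clean readouts
    of u and v, and the two planted drugs read their sum and difference.
    """
    rng = np.random.default_rng(int(config.seed))
    nl, ng, nd = config.n_lines, config.n_genes, config.n_drugs
    u = rng.normal(0.0, 1.0, size=nl)
    v = rng.normal(0.0, 1.0, size=nl)

    n_u = min(20, ng // 2)
    n_v = min(20, ng - n_u)
    load_u = np.zeros(ng)
    load_v = np.zeros(ng)
    load_u[:n_u] = config.subtype_effect * rng.uniform(0.5, 1.0, size=n_u)
    load_v[n_u : n_u + n_v] = config.subtype_effect * rng.uniform(0.5, 1.0, size=n_v)

    base = rng.normal(7.0, 1.0, size=ng)
    idio = rng.normal(0.0, 1.0, size=(nl, ng))
    expr = base + np.outer(u, load_u) + np.outer(v, load_v) + idio

    gene_ids = [f"g{j:04d}" for j in range(ng)]
    line_ids = [f"line_{i:02d}" for i in range(nl)]
    drug_ids = [f"drug_{j:02d}" for j in range(nd)]

    if config.complementary_pair is not None:
        # genes 0/1 become near-noiseless readouts of the two latent factors
        expr[:, 0] = base[0] + u + rng.normal(0.0, 0.1, size=nl)
        expr[:, 1] = base[1] + v + rng.normal(0.0, 0.1, size=nl)

    null_drugs = set(range(nd - config.n_null_drugs, nd))
    comp = set(config.complementary_pair) if config.complementary_pair else set()

    sens = np.empty((nl, nd))
    true_w: dict[str, dict[str, float]] = {}
    for j in range(nd):
        if j in comp:
            a, b = config.complementary_pair
            sign = 1.0 if j == a else -1.0
            w = {gene_ids[0]: 1.0, gene_ids[1]: sign}
        elif j in null_drugs:
            w = {}
        else:
            support = rng.choice(ng, size=config.support_size, replace=False)
            coefs = rng.uniform(0.5, 1.5, size=config.support_size) * rng.choice(
                [-1.0, 1.0], size=config.support_size
            )
            w = {gene_ids[g]: float(c) for g, c in zip(support, coefs)}
        linear = np.zeros(nl)
        for gid, c in w.items():
            linear += c * expr[:, gene_ids.index(gid)]
        sens[:, j] = linear + rng.normal(0.0, config.noise_sd, size=nl)
        true_w[drug_ids[j]] = w

    subtype = (u > 0).astype(int)
    panel = CellLinePanel(
        expression=DesignMatrix(expr, gene_ids, line_ids),
        sensitivity=sens,
        drug_ids=drug_ids,
        subtype_labels=subtype,
    )
    truth = GroundTruth(
        drug_true_weights=true_w,
        latent_u=u,
        latent_v=v,
        subtype_labels=subtype,
        complementary_drug_ids=(
            None
            if config.complementary_pair is None
            else (drug_ids[config.complementary_pair[0]], drug_ids[config.complementary_pair[1]])
        ),
    )
    return panel, truth
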