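"""Synthetic scRNA-seq generators with known ground truth.

Droplet-style data are negative-binomial: per-gene mean abundances E are
log-normal (``ln E ~ N(mu, sigma^2)``, defaults mu=0, sigma=2) and counts
are drawn ``NB(mean=E_i, size=r)`` with a fixed dispersion r (the gamma
shape; variance ``E + E^2/r``), r in the 5-20 range typical of UMI data.
Full-length-style data add zero inflation: each count is zeroed with a
per-gene dropout probability ``P_i = sigm(-(g0 + g1 E_i))`` (g0 = -1.5,
g1 = 1/median(E)), decreasing in expression.

On top of a base population the module can

- inject differentially expressed genes into a shared subset of cells
  (fold changes log-normal; ground-truth labels follow the 1.5-fold rule
  on the *realized* population-mean ratio),
- build depth-scaled replicate pairs (replicate 2 means = delta x
  replicate 1 means, same dispersion), and
- compose multi-type mixtures where similar subtypes share most of their
  mean vector.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .entropy import CountMatrix, Platform

logger = logging.getLogger("rogue")

__all__ = [
    "SimSpec",
    "DepthPairSpec",
    "MultitypeScenario",
    "simulate_nb",
    "simulate_zinb",
    "inject_de_genes",
    "simulate_depth_pair",
    "simulate_multitype",
    "DE_FOLD_THRESHOLD",
]

#: realized mean-ratio threshold defining ground-truth DE genes
DE_FOLD_THRESHOLD = 1.5


@dataclass
class SimSpec:
    """Parameters of one synthetic count matrix.

    Defaults reproduce the standard benchmark condition: 20,000 genes x
    2,000 cells, log-normal means with mu=0 / sigma=2, NB dispersion r=10
    (midpoint of the 5-20 range used for UMI data), and for ZINB data a
    sigmoid dropout with gamma0=-1.5 and gamma1=1/median(E).
    """

    n_genes: int = 20_000
    n_cells: int = 2_000
    mu: float = 0.0
    sigma: float = 2.0
    dispersion_r: float = 10.0
    zinb: bool = False
    gamma0: float = -1.5
    gamma1: float | None = None  # default 1/median(E)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dispersion_r <= 0:
            raise ValueError("dispersion_r must be positive")
        if self.gamma1 is not None and self.gamma1 <= 0:
            raise ValueError("gamma1 override must be positive")


@dataclass
class DepthPairSpec:
    """Two replicates differing only in sequencing depth (factor delta)."""

    base: SimSpec
    delta: float = 10.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ids(prefix: str, n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _draw_nb(rng: np.random.Generator, means: np.ndarray, r: float,
             n_cells: int) -> np.ndarray:
    """NB(mean=E, size=r) counts, genes x cells."""
    p = r / (r + np.asarray(means, float))
    return rng.negative_binomial(r, p[:, None], size=(means.size, n_cells))


def simulate_nb(spec: SimSpec) -> tuple[CountMatrix, np.ndarray]:
    """Negative-binomial count matrix plus the latent gene means."""
    rng = _rng(spec.seed)
    means = rng.lognormal(spec.mu, spec.sigma, spec.n_genes)
    counts = _draw_nb(rng, means, spec.dispersion_r, spec.n_cells)
    m = CountMatrix(
        counts, _ids("g", spec.n_genes), _ids("c", spec.n_cells), Platform.UMI
    )
    return m, means


def dropout_probability(means: np.ndarray, gamma0: float = -1.5,
                        gamma1: float | None = None) -> np.ndarray:
    """Sigmoid dropout rate ``P = sigm(-(g0 + g1 E))``, decreasing in E."""
    means = np.asarray(means, float)
    if gamma1 is None:
        gamma1 = 1.0 / float(np.median(means))
    if gamma1 <= 0:
        raise ValueError("gamma1 must be positive")
    return expit(-(gamma0 + gamma1 * means))


def simulate_zinb(spec: SimSpec) -> tuple[CountMatrix, np.ndarray]:
    """Zero-inflated NB matrix plus the per-gene dropout probabilities."""
    if not spec.zinb:
        raise ValueError("simulate_zinb requires a SimSpec with zinb=True")
    rng = _rng(spec.seed)
    means = rng.lognormal(spec.mu, spec.sigma, spec.n_genes)
    counts = _draw_nb(rng, means, spec.dispersion_r, spec.n_cells)
    p_drop = dropout_probability(means, spec.gamma0, spec.gamma1)
    dropped = rng.random(counts.shape) < p_drop[:, None]
    counts = np.where(dropped, 0, counts)
    m = CountMatrix(
        counts, _ids("g", spec.n_genes), _ids("c", spec.n_cells),
        Platform.FULL_LENGTH,
    )
    return m, p_drop


def inject_de_genes(
    base: CountMatrix,
    means: np.ndarray,
    gene_fraction: float,
    cell_fraction: float,
    dispersion_r: float = 10.0,
    fc_mu: float = 0.0,
    fc_sigma: float = 2.0,
    dropout_p: np.ndarray | None = None,
    seed=None,
) -> tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    """Add differential expression to a shared subset of cells.

    A random ``gene_fraction`` of genes gets its mean multiplied by a
    log-normal fold change (``fc_mu``, ``fc_sigma``) inside one shared
    random ``cell_fraction`` of cells, where counts are re-drawn; all other
    entries are left byte-identical.  If ``dropout_p`` is given (ZINB
    base), redrawn counts are zero-inflated at each gene's original rate.

    Ground truth follows the realized-mean rule: with affected fraction f,
    the population mean ratio is ``1 + f (fc - 1)``; a gene is DE iff that
    ratio exceeds 1.5 or falls below 1/1.5.

    Returns (matrix, truth table, affected cell ids); the truth table has
    one row per gene with columns is_de, fold_change, cell_fraction.
    """
    if not 0 < gene_fraction <= 1 or not 0 < cell_fraction <= 1:
        raise ValueError("gene_fraction and cell_fraction must be in (0, 1]")
    rng = _rng(seed)
    n_genes, n_cells = base.n_genes, base.n_cells
    n_de = int(round(gene_fraction * n_genes))
    if n_de < 1:
        raise ValueError(
            f"gene_fraction={gene_fraction} selects no gene out of {n_genes}"
        )
    n_aff = max(int(round(cell_fraction * n_cells)), 1)
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False))
    cell_idx = np.sort(rng.choice(n_cells, size=n_aff, replace=False))
    fc = rng.lognormal(fc_mu, fc_sigma, n_de)

    counts = np.array(base.values, copy=True)
    new_means = np.asarray(means, float)[de_idx] * fc
    block = _draw_nb(rng, new_means, dispersion_r, n_aff)
    if dropout_p is not None:
        dropped = rng.random(block.shape) < np.asarray(dropout_p)[de_idx, None]
        block = np.where(dropped, 0, block)
    counts[np.ix_(de_idx, cell_idx)] = block

    f = n_aff / n_cells
    realized_ratio = 1.0 + f * (fc - 1.0)
    fold_change = np.ones(n_genes)
    fold_change[de_idx] = fc
    ratio = np.ones(n_genes)
    ratio[de_idx] = realized_ratio
    is_de = (ratio > DE_FOLD_THRESHOLD) | (ratio < 1.0 / DE_FOLD_THRESHOLD)
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "fold_change": fold_change,
            "cell_fraction": np.where(fold_change != 1.0, f, 0.0),
        },
        index=pd.Index(base.gene_ids, name="gene"),
    )
    out = CountMatrix(counts, base.gene_ids, base.cell_ids, base.platform)
    return out, truth, base.cell_ids[cell_idx]


def simulate_depth_pair(spec: DepthPairSpec) -> tuple[CountMatrix, pd.Series]:
    """Pool two replicates whose means differ by the depth factor delta.

    Replicate 1 is drawn from the base means, replicate 2 from
    ``means * delta`` with the same dispersion; both have ``base.n_cells``
    cells.  Returns the pooled matrix and a per-cell replicate label.
    """
    rng = _rng(spec.base.seed)
    base = spec.base
    means = rng.lognormal(base.mu, base.sigma, base.n_genes)
    rep1 = _draw_nb(rng, means, base.dispersion_r, base.n_cells)
    rep2 = _draw_nb(rng, means * spec.delta, base.dispersion_r, base.n_cells)
    counts = np.concatenate([rep1, rep2], axis=1)
    cell_ids = np.concatenate(
        [_ids("r1_c", base.n_cells), _ids("r2_c", base.n_cells)]
    )
    m = CountMatrix(counts, _ids("g", base.n_genes), cell_ids, Platform.UMI)
    labels = pd.Series(
        ["replicate1"] * base.n_cells + ["replicate2"] * base.n_cells,
        index=pd.Index(cell_ids), name="replicate",
    )
    return m, labels


@dataclass
class MultitypeScenario:
    """Mixture of 2-3 cell types sharing one base mean vector.

    Types B and C are similar subtypes: ``n_varied_major`` genes separate A
    from both B and C (fold changes log-normal sigma ``fc_sigma_major``),
    and ``n_varied_minor`` genes separate B from C (sigma
    ``fc_sigma_minor``).  With two types only the major perturbation
    applies (A vs B).  Unequal ``cells_per_type`` covers minority-to-1:1
    mixtures.
    """

    n_genes: int = 10_000
    cells_per_type: tuple[int, ...] = (1_000, 1_000, 1_000)
    n_varied_major: int = 500
    n_varied_minor: int = 100
    fc_mu: float = 0.0
    fc_sigma_major: float = 2.0
    fc_sigma_minor: float = 1.0
    mu: float = 0.0
    sigma: float = 2.0
    dispersion_r: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.cells_per_type) not in (2, 3):
            raise ValueError("cells_per_type must list 2 or 3 types")
        if any(c <= 0 for c in self.cells_per_type):
            raise ValueError("every type needs at least one cell")
        if self.n_varied_major + self.n_varied_minor > self.n_genes:
            raise ValueError(
                "varied-gene counts exceed the number of genes "
                f"({self.n_varied_major}+{self.n_varied_minor} > {self.n_genes})"
            )


def simulate_multitype(
    scenario: MultitypeScenario,
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Simulate a labeled multi-type mixture with per-pair DE truth.

    Returns (pooled matrix, per-cell type labels, truth table).  The truth
    table has one row per (gene, type pair) perturbation with the sampled
    fold change and the 1.5-fold DE flag; since every cell of a perturbed
    type is affected, the realized between-type mean ratio equals the
    sampled fold change.
    """
    sc = scenario
    rng = _rng(sc.seed)
    base_means = rng.lognormal(sc.mu, sc.sigma, sc.n_genes)
    k = len(sc.cells_per_type)
    type_names = ["A", "B", "C"][:k]
    means = {t: base_means.copy() for t in type_names}

    records = []
    gene_ids = _ids("g", sc.n_genes)
    if sc.n_varied_major > 0:
        major_idx = rng.choice(sc.n_genes, size=sc.n_varied_major, replace=False)
        fc_major = rng.lognormal(sc.fc_mu, sc.fc_sigma_major, sc.n_varied_major)
        for t in type_names[1:]:  # B (and C) shift together relative to A
            means[t][major_idx] = base_means[major_idx] * fc_major
        pair = "A|B" if k == 2 else "A|BC"
        for g, f in zip(gene_ids[major_idx], fc_major):
            records.append((g, pair, f))
    if k == 3 and sc.n_varied_minor > 0:
        minor_idx = rng.choice(sc.n_genes, size=sc.n_varied_minor, replace=False)
        fc_minor = rng.lognormal(sc.fc_mu, sc.fc_sigma_minor, sc.n_varied_minor)
        means["C"][minor_idx] = means["C"][minor_idx] * fc_minor
        for g, f in zip(gene_ids[minor_idx], fc_minor):
            records.append((g, "B|C", f))

    blocks, labels, cell_ids = [], [], []
    for t, n_c in zip(type_names, sc.cells_per_type):
        blocks.append(_draw_nb(rng, means[t], sc.dispersion_r, n_c))
        ids = _ids(f"{t}_c", n_c)
        cell_ids.append(ids)
        labels.extend([t] * n_c)
    counts = np.concatenate(blocks, axis=1)
    cell_ids = np.concatenate(cell_ids)
    m = CountMatrix(counts, gene_ids, cell_ids, Platform.UMI)
    label_ser = pd.Series(labels, index=pd.Index(cell_ids), name="cell_type")

    truth = pd.DataFrame(records, columns=["gene", "pair", "fold_change"])
    if len(truth):
        truth["is_de"] = (truth["fold_change"] > DE_FOLD_THRESHOLD) | (
            truth["fold_change"] < 1.0 / DE_FOLD_THRESHOLD
        )
    else:
        truth["is_de"] = pd.Series(dtype=bool)
    return m, label_ser, truth
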