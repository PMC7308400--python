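"""ROGUE: cluster-purity scoring from significant entropy reduction.

ROGUE (Ratio Of Global Unshifted Entropy) summarises how far a cell
population departs from the one-component gamma-Poisson null::

    ROGUE = 1 - sum_sig(ds) / (sum_sig(ds) + K)

where the sum runs over genes with BH-significant entropy reduction ds and
K is a reference factor: half the significant-ds sum of a deliberately
heterogeneous reference dataset.  A perfectly pure population (no
significant genes) scores 1; the reference-level mixture scores 0.5; the
score tends to 0 as heterogeneity grows without bound.

Default K values (derived from the Tabula Muris atlas): 45 for
droplet/UMI data and 500 for full-length data.  A score of ~0.9 is a
practical purity threshold in typical droplet data, but this is guidance,
not behaviour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import (
    CountMatrix,
    Platform,
    compute_se,
    fit_se_null,
    test_ds,
)

logger = logging.getLogger("rogue")

__all__ = [
    "DEFAULT_K",
    "RogueParams",
    "RogueResult",
    "rogue_statistic",
    "determine_k",
    "filter_matrix",
    "run_se_pipeline",
    "rogue_by_group",
]

#: platform-specific defaults for the reference factor K
DEFAULT_K = {Platform.UMI: 45.0, Platform.FULL_LENGTH: 500.0}


@dataclass
class RogueParams:
    """Parameters of a ROGUE computation.

    ``k=None`` selects the platform default (45 UMI / 500 full-length).
    """

    platform: Platform = Platform.UMI
    k: float | None = None
    alpha: float = 0.05
    pseudocount: float = 1.0
    span: float = 0.5
    n_refit: int = 2
    min_cells_filter: int = 10
    min_genes_filter: int = 10

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.k is None:
            self.k = DEFAULT_K[self.platform]
        if self.k <= 0:
            raise ValueError(f"reference factor K must be positive, got {self.k}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class RogueResult:
    """Per (cluster, sample) purity scores.

    ``table`` is tidy with columns cluster, sample, rogue, sig_ds_sum,
    n_sig, n_cells; groups below the cell minimum carry NaN scores
    (missing, never zero).  ``pivot()`` reshapes to clusters x samples.
    """

    table: pd.DataFrame
    k: float

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="cluster", columns="sample", values="rogue")


def rogue_statistic(sig_ds, k: float) -> float:
    """ROGUE purity from the significant entropy reductions.

    ``1 - S/(S + K)`` with ``S = sum(sig_ds)``: equals 1 when the
    significant set is empty, 0.5 when S equals K, and decreases strictly
    toward 0 as S grows.
    """
    if k <= 0:
        raise ValueError(f"reference factor K must be positive, got {k}")
    sig_ds = np.asarray(list(sig_ds), dtype=float)
    if sig_ds.size and sig_ds.min() < 0:
        raise ValueError(
            "negative ds passed to rogue_statistic; only significant positive "
            "entropy reductions qualify"
        )
    total = float(sig_ds.sum())
    return 1.0 - total / (total + k)


def filter_matrix(
    m: CountMatrix, min_cells: int = 10, min_genes: int = 10
) -> CountMatrix:
    """Drop genes detected in < ``min_cells`` cells, then cells with
    < ``min_genes`` detected genes, repeating until stable (a single pass
    is not idempotent: removing cells can re-expose under-detected genes).
    """
    cur = m
    while True:
        detected_cells = (cur.values > 0).sum(axis=1)
        gene_mask = detected_cells >= min_cells
        if not gene_mask.all():
            cur = cur.subset_genes(gene_mask)
        detected_genes = (cur.values > 0).sum(axis=0)
        cell_mask = detected_genes >= min_genes
        if not cell_mask.all():
            cur = cur.subset_cells(cell_mask)
        if cur.n_genes == 0 or cur.n_cells == 0:
            raise ValueError(
                f"filtering (min_cells={min_cells}, min_genes={min_genes}) "
                "removed every gene or cell"
            )
        if gene_mask.all() and cell_mask.all():
            return cur


def run_se_pipeline(
    m: CountMatrix, params: RogueParams | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """filter -> compute_se -> fit_se_null -> test_ds on one population.

    Returns the completed S-E profile and the BH-significant gene list.
    """
    params = params or RogueParams(platform=m.platform)
    filtered = filter_matrix(m, params.min_cells_filter, params.min_genes_filter)
    profile = compute_se(filtered, r=params.pseudocount)
    profile = fit_se_null(
        profile, span=params.span, n_refit=params.n_refit,
        exclude_alpha=params.alpha,
    )
    return test_ds(profile, alpha=params.alpha)


def determine_k(reference: CountMatrix, alpha: float = 0.05) -> float:
    """Reference factor K from a deliberately heterogeneous dataset.

    Runs the full entropy pipeline on the reference and returns one-half of
    the summed significant ds, so that the reference mixture itself would
    score ROGUE = 1/3 and a half-reference mixture 0.5.
    """
    params = RogueParams(platform=reference.platform, alpha=alpha)
    profile, sig = run_se_pipeline(reference, params)
    if not sig:
        raise ValueError(
            "reference not heterogeneous enough; no gene has significant "
            "entropy reduction, K undefined"
        )
    return float(profile.loc[sig, "ds"].sum()) / 2.0


def _as_label_series(labels, cell_ids: np.ndarray, what: str) -> pd.Series:
    if labels is None:
        return pd.Series("all", index=pd.Index(cell_ids), name=what)
    if isinstance(labels, pd.Series):
        ser = labels
    elif isinstance(labels, dict):
        ser = pd.Series(labels)
    else:
        labels = np.asarray(labels, dtype=object)
        if len(labels) != len(cell_ids):
            raise ValueError(
                f"{what} labels length {len(labels)} != number of cells {len(cell_ids)}"
            )
        ser = pd.Series(labels, index=pd.Index(cell_ids))
    return ser.reindex(pd.Index(cell_ids))


def rogue_by_group(
    m: CountMatrix,
    cluster_labels,
    sample_labels=None,
    params: RogueParams | None = None,
    min_cells: int = 20,
) -> RogueResult:
    """ROGUE per (cluster, sample) subset.

    Each subset with at least ``min_cells`` cells gets the *full* entropy
    pipeline run on its own cells (its own filtering, null trend and BH
    test) before the statistic is computed; smaller subsets are reported
    with a missing score.  Cells without a cluster (or sample) label are
    dropped with a warning.  ``sample_labels=None`` scores each cluster as
    a single sample.
    """
    params = params or RogueParams(platform=m.platform)
    clusters = _as_label_series(cluster_labels, m.cell_ids, "cluster")
    samples = _as_label_series(sample_labels, m.cell_ids, "sample")
    unlabeled = clusters.isna() | samples.isna()
    if unlabeled.any():
        warnings.warn(
            f"dropping {int(unlabeled.sum())} cell(s) without cluster/sample labels",
            RuntimeWarning,
        )
    keep = ~unlabeled.to_numpy()
    m = m.subset_cells(keep)
    clusters, samples = clusters[~unlabeled], samples[~unlabeled]

    rows = []
    groups = pd.DataFrame(
        {"cluster": clusters.to_numpy(), "sample": samples.to_numpy()}
    )
    any_scored = False
    for (clu, sam), idx in groups.groupby(["cluster", "sample"], sort=True).groups.items():
        idx = np.asarray(idx)
        if idx.size < min_cells:
            rows.append(
                dict(cluster=clu, sample=sam, rogue=np.nan, sig_ds_sum=np.nan,
                     n_sig=np.nan, n_cells=idx.size)
            )
            continue
        sub = m.subset_cells(idx)
        profile, sig = run_se_pipeline(sub, params)
        sig_sum = float(profile.loc[sig, "ds"].sum()) if sig else 0.0
        rows.append(
            dict(
                cluster=clu, sample=sam,
                rogue=rogue_statistic(profile.loc[sig, "ds"], params.k),
                sig_ds_sum=sig_sum, n_sig=len(sig), n_cells=idx.size,
            )
        )
        any_scored = True
    if not any_scored:
        raise ValueError(
            f"no (cluster, sample) group has at least min_cells={min_cells} cells"
        )
    table = pd.DataFrame(rows).sort_values(["cluster", "sample"]).reset_index(drop=True)
    return RogueResult(table=table, k=params.k)
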