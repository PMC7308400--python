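"""Evaluation statistics: DE-recovery AUC, top-gene reproducibility,
silhouette width, and subsampling stability of the expression entropy."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import pairwise_distances, roc_auc_score

from .entropy import CountMatrix, compute_se
from .purity import filter_matrix

logger = logging.getLogger("rogue")

__all__ = [
    "auc_de_recovery",
    "reproducibility_score",
    "SilhouetteResult",
    "silhouette_width",
    "s_stability",
]


def auc_de_recovery(scores: pd.Series, is_de: pd.Series) -> float:
    """Area under the ROC curve of a per-gene score against DE truth.

    Ties are handled by midranks (Mann-Whitney equivalence), which matters
    because entropy-reduction scores tie at filtered zeros.  Every scored
    gene must carry a truth label and both classes must be present.
    """
    scores = pd.Series(scores)
    truth = pd.Series(is_de).reindex(scores.index)
    if truth.isna().any():
        missing = truth.index[truth.isna()].tolist()[:5]
        raise ValueError(f"scored genes without a truth label: {missing}")
    y = truth.astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ValueError("AUC undefined: truth labels contain a single class")
    return float(roc_auc_score(y, scores.to_numpy(float)))


def reproducibility_score(list_a, list_b, n: int) -> float:
    """Overlap of the top-n prefixes of two ranked gene lists, |A∩B|/n."""
    if n <= 0:
        raise ValueError(f"n must be a positive count, got {n}")
    list_a, list_b = list(list_a), list(list_b)
    if len(list_a) < n or len(list_b) < n:
        raise ValueError(
            f"both lists need at least n={n} entries "
            f"(got {len(list_a)} and {len(list_b)})"
        )
    return len(set(list_a[:n]) & set(list_b[:n])) / n


@dataclass
class SilhouetteResult:
    """Per-cell silhouette decomposition and the overall mean width."""

    table: pd.DataFrame  # columns a, b, s per cell
    mean_s: float


def silhouette_width(
    points: np.ndarray,
    labels,
    metric: str = "euclidean",
    ids=None,
) -> SilhouetteResult:
    """Exact silhouette width s(i) = (b - a) / max(a, b) per cell.

    ``a`` is the mean dissimilarity of cell i to the other members of its
    cluster and ``b`` the smallest mean dissimilarity to any other cluster,
    both from the full pairwise-distance matrix (no centroid shortcut).
    Singleton clusters and degenerate max(a, b) = 0 cells score s = 0.
    """
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    if points.shape[0] != labels.size:
        raise ValueError("points and labels length mismatch")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    dist = pairwise_distances(points, metric=metric)
    n = points.shape[0]
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}

    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size > 1:
            a[i] = dist[i, own].sum() / (own.size - 1)
        else:
            a[i] = 0.0
        b[i] = min(
            dist[i, members[lab]].mean() for lab in uniq if lab != labels[i]
        )
        denom = max(a[i], b[i])
        if own.size == 1 or denom == 0:
            s[i] = 0.0
        else:
            s[i] = (b[i] - a[i]) / denom
    index = pd.Index(ids if ids is not None else np.arange(n), name="cell")
    table = pd.DataFrame({"a": a, "b": b, "s": s}, index=index)
    return SilhouetteResult(table=table, mean_s=float(s.mean()))


def s_stability(
    m: CountMatrix,
    subsample_sizes,
    n_runs: int = 50,
    seed=None,
    pseudocount: float = 1.0,
    min_cells: int = 10,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Stability of per-gene expression entropy under cell down-sampling.

    For each subsample size and run, draws cells without replacement,
    recomputes the observed per-gene entropy S (mean of ln(X + r)) after
    the standard gene/cell filter, and reports the Pearson correlation with
    the full-data S over the genes retained by both (genes dropped by
    either filtering are excluded symmetrically).

    Returns a tidy DataFrame with columns subsample_size, run, pearson_r.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sizes = [int(x) for x in np.atleast_1d(subsample_sizes)]
    for size in sizes:
        if size < 10:
            raise ValueError(f"subsample size must be at least 10 cells, got {size}")
        if size > m.n_cells:
            raise ValueError(
                f"subsample size {size} exceeds the number of cells {m.n_cells}"
            )
    full = filter_matrix(m, min_cells, min_genes)
    full_s = compute_se(full, r=pseudocount)["obs_entropy"]

    rows = []
    for size in sizes:
        for run in range(n_runs):
            if size == m.n_cells:
                idx = np.arange(m.n_cells)
            else:
                idx = rng.choice(m.n_cells, size=size, replace=False)
            sub = filter_matrix(m.subset_cells(idx), min_cells, min_genes)
            sub_s = compute_se(sub, r=pseudocount)["obs_entropy"]
            shared = full_s.index.intersection(sub_s.index)
            r, _ = stats.pearsonr(full_s.loc[shared], sub_s.loc[shared])
            rows.append(dict(subsample_size=size, run=run, pearson_r=float(r)))
    return pd.DataFrame(rows)
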