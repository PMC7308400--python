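"""Expression-entropy (S-E) model for informative-gene detection.

Under a gamma-Poisson model of UMI counts, the differential entropy of a
gene's latent expression reduces to ``S_i = ln E(X_i) + a`` with ``a``
constant across genes.  A homogeneous population therefore places every
gene on a single smooth trend between S and the log mean expression E.
Genes whose per-cell average log expression falls *below* that trend
(positive entropy reduction ``ds``) are more ordered than the one-component
null allows, i.e. heterogeneously expressed.

The pipeline implemented here:

1. :func:`compute_se` -- per-gene mean expression and observed entropy
   (the plug-in estimate ``mean_j ln(X_ij + r)``).
2. :func:`fit_se_null` -- LOESS fit of the S-E null trend with iterative
   exclusion of significant genes; residual ``ds = fit - observed``.
3. :func:`test_ds` -- normal-approximation upper-tail p-values for ds,
   Benjamini-Hochberg adjusted.
4. :func:`select_features` -- ds-ranked gene lists.

All logarithms are natural.  Matrices are genes x cells throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("rogue")

__all__ = [
    "Platform",
    "CountMatrix",
    "DegenerateFitError",
    "normalize_library_size",
    "compute_se",
    "fit_se_null",
    "test_ds",
    "select_features",
]


class Platform(str, Enum):
    """Sequencing protocol family; selects the default reference factor K."""

    UMI = "umi"
    FULL_LENGTH = "full"


class DegenerateFitError(ValueError):
    """Raised when the S-E trend cannot be fit (e.g. all means identical)."""


@dataclass
class CountMatrix:
    """Raw gene x cell expression matrix.

    Parameters
    ----------
    values
        Non-negative expression values, shape ``(n_genes, n_cells)``.
        Integer counts for UMI data; full-length data may carry
        non-integer values (e.g. TPM).
    gene_ids, cell_ids
        Unique identifiers for rows / columns.
    platform
        :class:`Platform` tag.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    platform: Platform = Platform.UMI
    normalized: bool = False  # size-factor scaled; integer invariant waived

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.platform = Platform(self.platform)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} gene ids and {len(self.cell_ids)} cell ids"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative expression values are not allowed")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Series(ids).value_counts()
                dup = dup[dup > 1].index.tolist()[:5]
                raise ValueError(f"duplicate {name} ids: {dup}")
        if self.platform is Platform.UMI and not self.normalized and self.values.size:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("UMI platform requires integer counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        return CountMatrix(
            self.values[mask_or_idx], self.gene_ids[mask_or_idx],
            self.cell_ids, self.platform, self.normalized,
        )

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        return CountMatrix(
            self.values[:, mask_or_idx], self.gene_ids,
            self.cell_ids[mask_or_idx], self.platform, self.normalized,
        )


# ---------------------------------------------------------------------------
# normalization


def normalize_library_size(m: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Divide each cell by its size factor.

    The size factor of cell j is its total count divided by the mean total
    count across cells, so the factors average exactly 1 and the overall
    scale of the matrix is preserved.

    Returns
    -------
    (normalized matrix, size factors)

    Raises
    ------
    ValueError
        If any cell has a zero total count (its size factor is undefined).
    """
    totals = np.asarray(m.values.sum(axis=0), dtype=float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"size factor undefined for cell(s) with zero total count: "
            f"{list(m.cell_ids[zero[:5]])}"
        )
    s = totals / totals.mean()
    norm = CountMatrix(
        m.values / s[None, :], m.gene_ids, m.cell_ids, m.platform, normalized=True
    )
    return norm, s


# ---------------------------------------------------------------------------
# S-E profile


def _mean_log(values: np.ndarray, r: float, chunk: int = 4096) -> np.ndarray:
    """Row-wise mean of ln(x + r), chunked to bound temporary memory."""
    n = values.shape[0]
    out = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[lo:hi] = np.log(values[lo:hi] + r).mean(axis=1)
    return out


def compute_se(m: CountMatrix, r: float = 1.0) -> pd.DataFrame:
    """Per-gene mean expression and observed entropy.

    Returns the S-E profile: a DataFrame indexed by gene id with columns

    - ``mean_expr``: mean over cells of X_ij,
    - ``log_mean``: ln(mean_expr + r)  (expression entropy under the
      one-component null, up to a constant),
    - ``obs_entropy``: mean over cells of ln(X_ij + r),
    - ``fit_entropy``, ``ds``, ``p``, ``p_adj``: NaN until filled by
      :func:`fit_se_null` and :func:`test_ds`.

    The pseudocount ``r`` is applied symmetrically to both terms so a gene
    with identical counts in every cell has ``log_mean == obs_entropy``.
    """
    if r <= 0:
        raise ValueError(f"pseudocount r must be positive, got {r}")
    if m.n_genes == 0 or m.n_cells == 0:
        raise ValueError("cannot compute the S-E profile of an empty matrix")
    mean_expr = np.asarray(m.values.mean(axis=1), dtype=float)
    profile = pd.DataFrame(
        {
            "mean_expr": mean_expr,
            "log_mean": np.log(mean_expr + r),
            "obs_entropy": _mean_log(m.values, r),
            "fit_entropy": np.nan,
            "ds": np.nan,
            "p": np.nan,
            "p_adj": np.nan,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return profile


# ---------------------------------------------------------------------------
# LOESS null trend

_TINY_SPAN_POINTS = 3  # minimum window size for a quadratic fit


def _loess_curve(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    degree: int = 2,
    max_eval: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local polynomial fit.

    Evaluates the fit exactly at every point when ``n <= max_eval`` and at
    ``max_eval`` quantile-spaced knots otherwise; predictions elsewhere are
    linear interpolations between knots (the standard large-n loess
    strategy).  Returns ``(grid_x, grid_y)`` with ``grid_x`` increasing.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = np.asarray(x, float)[order], np.asarray(y, float)[order]
    n = xs.size
    if n < _TINY_SPAN_POINTS or xs[0] == xs[-1]:
        raise DegenerateFitError(
            "cannot fit the S-E trend: all log-mean values are identical "
            "(or fewer than 3 genes)"
        )
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)

    if n <= max_eval:
        eval_idx = np.arange(n)
    else:
        eval_idx = np.unique(
            np.round(np.linspace(0, n - 1, max_eval)).astype(int)
        )

    grid_x = xs[eval_idx]
    grid_y = np.empty(grid_x.size)
    s = 0  # window start; non-decreasing as x0 sweeps right
    for k, i in enumerate(eval_idx):
        x0 = xs[i]
        while s + q < n and (xs[s + q] - x0) < (x0 - xs[s]):
            s += 1
        xl = xs[s : s + q]
        yl = ys[s : s + q]
        d = np.abs(xl - x0)
        dmax = d.max()
        w = np.ones_like(d) if dmax == 0 else (1 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        dx = xl - x0
        design = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w)
        try:
            coef, *_ = np.linalg.lstsq(design * sw[:, None], yl * sw, rcond=None)
            grid_y[k] = coef[0]
        except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely fails
            grid_y[k] = np.average(yl, weights=w)
    # collapse duplicate grid x for interpolation
    if np.any(np.diff(grid_x) == 0):
        df = pd.DataFrame({"x": grid_x, "y": grid_y}).groupby("x", sort=True).mean()
        grid_x = df.index.to_numpy()
        grid_y = df["y"].to_numpy()
    return grid_x, grid_y


def _predict_curve(grid_x: np.ndarray, grid_y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.interp(x, grid_x, grid_y)


def _normal_upper_p(ds: np.ndarray) -> np.ndarray:
    """Upper-tail p-values under Normal(mean(ds), sd(ds))."""
    sd = float(np.std(ds, ddof=1)) if ds.size > 1 else 0.0
    if sd == 0:
        return np.ones_like(ds, dtype=float)
    return stats.norm.sf(ds, loc=float(np.mean(ds)), scale=sd)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def fit_se_null(
    profile: pd.DataFrame,
    span: float = 0.5,
    n_refit: int = 2,
    exclude_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit the S-E null trend and compute entropy-reduction residuals.

    The observed entropy is regressed on the log mean expression with a
    local quadratic (LOESS) fit, and ``ds = fit - observed``.  Because
    heterogeneous genes pull the trend toward themselves, genes whose ds is
    significant (normal approximation + BH at ``exclude_alpha``) are
    excluded and the curve refit ``n_refit`` times; the final ds of *all*
    genes is taken against the final curve.

    Requires at least 20 genes and ``span`` in (0, 1].
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(profile) < 20:
        raise ValueError(
            f"at least 20 genes are required to fit the S-E trend, got {len(profile)}"
        )
    x = profile["log_mean"].to_numpy(float)
    y = profile["obs_entropy"].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegenerateFitError(
            "cannot fit the S-E trend: all log-mean values are identical"
        )

    keep = np.ones(len(x), dtype=bool)
    grid = _loess_curve(x, y, span)
    for _ in range(n_refit):
        ds = _predict_curve(*grid, x) - y
        sig = _bh_adjust(_normal_upper_p(ds)) < exclude_alpha
        new_keep = ~sig
        if new_keep.sum() < 20 or new_keep.all():
            break
        keep = new_keep
        grid = _loess_curve(x[keep], y[keep], span)

    fit = _predict_curve(*grid, x)
    out = profile.copy()
    out["fit_entropy"] = fit
    out["ds"] = fit - y
    return out


# ---------------------------------------------------------------------------
# significance


def test_ds(
    profile: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Upper-tail significance of ds under a fitted normal null.

    The null mean and standard deviation are estimated from the ds values of
    all genes; only positive deviations (reduced entropy) count as evidence
    of heterogeneity.  P-values are Benjamini-Hochberg adjusted and the
    significant set is ``{gene : p_adj < alpha}``, returned in decreasing-ds
    order.
    """
    if profile["ds"].isna().any():
        raise ValueError("ds has not been computed; run fit_se_null first")
    ds = profile["ds"].to_numpy(float)
    sd = float(np.std(ds, ddof=1)) if ds.size > 1 else 0.0
    out = profile.copy()
    if sd == 0:
        warnings.warn(
            "degenerate null: sd(ds) = 0, all p-values set to 1", RuntimeWarning
        )
        out["p"] = 1.0
        out["p_adj"] = 1.0
        return out, []
    out["p"] = _normal_upper_p(ds)
    out["p_adj"] = _bh_adjust(out["p"].to_numpy())
    sig = out.index[out["p_adj"] < alpha]
    sig_sorted = out.loc[sig].sort_values(
        "ds", ascending=False, kind="mergesort"
    ).index.tolist()
    return out, sig_sorted


def select_features(
    profile: pd.DataFrame,
    n: int | None = None,
    mode: str = "top",
) -> list[str]:
    """Rank genes by decreasing entropy reduction ds.

    ``mode="top"`` returns the first ``n`` genes; ``mode="significant"``
    returns the BH-significant set (requires :func:`test_ds` output) in the
    same order.  Ties in ds are broken lexicographically by gene id so the
    ranking is deterministic.
    """
    if profile["ds"].isna().any():
        raise ValueError("ds has not been computed; run fit_se_null first")
    ranked = profile.sort_index(kind="mergesort").sort_values(
        "ds", ascending=False, kind="mergesort"
    )
    if mode == "significant":
        if ranked["p_adj"].isna().any():
            raise ValueError("p_adj missing; run test_ds before mode='significant'")
        return ranked.index[ranked["p_adj"] < 0.05].tolist() if n is None else (
            ranked.index[ranked["p_adj"] < 0.05].tolist()[:n]
        )
    if mode != "top":
        raise ValueError(f"unknown mode {mode!r}; use 'top' or 'significant'")
    if n is None:
        raise ValueError("n is required with mode='top'")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > len(ranked):
        warnings.warn(
            f"requested {n} genes but only {len(ranked)} available; returning all",
            RuntimeWarning,
        )
        n = len(ranked)
    return ranked.index[:n].tolist()
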