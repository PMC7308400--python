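"""Readers and writers: Matrix Market / dense TSV-CSV matrices, label
tables, S-E profiles, ROGUE tables and resolved run configs.

Conventions: genes are rows and cells are columns everywhere; TSV is the
canonical output dialect; gzip is handled transparently from the ``.gz``
extension; Matrix Market files use 1-based coordinate format with an
integer field for raw UMI counts.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .entropy import CountMatrix, Platform
from .purity import RogueResult

logger = logging.getLogger("rogue")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_se_profile",
    "write_rogue_result",
    "write_truth",
    "write_config",
]


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _strip_gz(path: Path) -> str:
    name = path.name
    return name[:-3] if name.endswith(".gz") else name


def _read_id_column(path: Path, what: str) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids in {path}")
    return ids


def read_matrix(
    path,
    genes_path=None,
    cells_path=None,
    platform: Platform = Platform.UMI,
) -> CountMatrix:
    """Read a genes x cells matrix.

    ``.mtx[.gz]`` requires gene/cell sidecar TSVs (first column = id,
    Matrix Market rows = genes).  ``.tsv/.csv[.gz]`` is dense with gene ids
    in the first column and cell ids in the header row.  Negative values,
    duplicate ids, and sidecar/matrix dimension mismatches are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    stem = _strip_gz(path)
    if stem.endswith(".mtx"):
        if genes_path is None or cells_path is None:
            raise ValueError(
                "Matrix Market input requires --genes and --cells sidecar files"
            )
        with _open_maybe_gz(path, "rb") as fh:
            values = scipy.io.mmread(fh)
        values = np.asarray(scipy.sparse.coo_matrix(values).todense())
        gene_ids = _read_id_column(Path(genes_path), "gene")
        cell_ids = _read_id_column(Path(cells_path), "cell")
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix is {values.shape[0]} x {values.shape[1]} but sidecars "
                f"list {len(gene_ids)} genes and {len(cell_ids)} cells"
            )
    elif stem.endswith((".tsv", ".csv")):
        sep = "\t" if stem.endswith(".tsv") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any():
            rows, cols = np.nonzero(bad.isna().to_numpy())
            g, c = df.index[rows[0]], df.columns[cols[0]]
            raise ValueError(
                f"non-numeric value at gene {g!r}, cell {c!r} in {path}"
            )
        values = bad.to_numpy(float)
        gene_ids = df.index.to_numpy(object)
        cell_ids = df.columns.to_numpy(object)
    else:
        raise ValueError(
            f"unsupported matrix format {path.name!r}; use .mtx, .tsv or .csv (.gz ok)"
        )
    if values.size and values.min() < 0:
        raise ValueError(f"negative expression values in {path}")
    return CountMatrix(values, gene_ids, cell_ids, platform)


def write_matrix(m: CountMatrix, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under ``out_dir``.

    UMI matrices are written with an integer Matrix Market field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}matrix.mtx",
        "genes": out_dir / f"{prefix}genes.tsv",
        "cells": out_dir / f"{prefix}barcodes.tsv",
    }
    values = m.values
    if m.platform is Platform.UMI and not m.normalized:
        values = values.astype(np.int64, copy=False)
    sparse = scipy.sparse.coo_matrix(values)
    scipy.io.mmwrite(str(paths["matrix"]), sparse)
    pd.Series(m.gene_ids).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(paths["cells"], sep="\t", index=False, header=False)
    return paths


def read_labels(path) -> pd.Series:
    """Two-column label TSV (cell_id, label; header required) -> Series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (cell_id, label)")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0]),
                    name=df.columns[1])
    if ser.index.duplicated().any():
        raise ValueError(f"duplicate cell ids in label file {path}")
    return ser


def write_labels(labels: pd.Series, path, value_name: str = "label") -> None:
    df = pd.DataFrame({"cell_id": labels.index, value_name: labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def write_se_profile(profile: pd.DataFrame, path) -> None:
    """S-E profile TSV, rows ordered by decreasing ds (NaN ds last),
    ties broken by gene id; full double precision."""
    cols = ["mean_expr", "log_mean", "obs_entropy", "fit_entropy", "ds", "p", "p_adj"]
    out = profile[cols].copy()
    out = out.sort_index(kind="mergesort").sort_values(
        "ds", ascending=False, kind="mergesort", na_position="last"
    )
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_rogue_result(result: RogueResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def write_config(config: dict, path) -> None:
    """Resolved run configuration as deterministic ``key = value`` lines."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key} = {config[key]}\n")
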