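"""Readers and writers for count matrices, cell metadata and result tables.

Counts are accepted either as MatrixMarket sparse files (``.mtx`` with
``genes``/``barcodes`` sidecars, the CellRanger-style trio) or as a dense
delimited matrix with a header row of cell ids and a first column of gene
names. Counts are expected raw (UMI); the log(x + 1) transform is applied
internally by the test, and no per-cell depth normalization is performed by
default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .simulator import SimulatedDataset

__all__ = [
    "read_counts",
    "read_dense_counts",
    "read_cell_metadata",
    "write_dataset",
    "read_truth",
]

METADATA_COLUMNS = ("cell_id", "subject_id", "diagnosis", "cell_type")


def _read_names(path: Path) -> list[str]:
    names = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return names


def read_counts(
    matrix_path, genes_path, barcodes_path, on_non_integer: str = "reject"
) -> pd.DataFrame:
    """Read a MatrixMarket genes x cells count matrix with name sidecars.

    Dimensions are cross-checked against the sidecars; non-integer entries
    are rejected by default (``on_non_integer="round"`` warns and rounds
    instead).
    """
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    genes = _read_names(Path(genes_path))
    cells = _read_names(Path(barcodes_path))
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} barcodes)"
        )
    if not np.allclose(mat, np.round(mat)):
        if on_non_integer == "round":
            import warnings

            warnings.warn("non-integer counts rounded to nearest integer", UserWarning)
        else:
            raise ValueError("count matrix contains non-integer entries")
    return pd.DataFrame(np.round(mat).astype(np.int64), index=genes, columns=cells)


def read_dense_counts(path, sep: str = "\t") -> pd.DataFrame:
    """Read a dense delimited matrix: header row of cell ids, first column genes."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("count matrix contains non-integer entries")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_cell_metadata(
    path, column_map: dict[str, str] | None = None, sep: str = "\t"
) -> pd.DataFrame:
    """Read and validate the cell annotation table.

    ``column_map`` maps the required names (cell_id, subject_id, diagnosis,
    cell_type) to the file's actual headers when they differ.
    """
    raw = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    rename = {column_map.get(c, c): c for c in METADATA_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    cells = raw.rename(columns=rename)[list(METADATA_COLUMNS)].copy()
    for c in METADATA_COLUMNS:
        cells[c] = cells[c].astype(str)
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicated cell id: {dup!r}")
    levels = sorted(cells["diagnosis"].unique())
    if len(levels) != 2:
        raise ValueError(f"diagnosis must take exactly two values, got {levels}")
    return cells


def write_dataset(ds: SimulatedDataset, out_prefix) -> dict[str, Path]:
    """Write a simulated dataset as counts.mtx + genes/barcodes/cells/truth TSVs."""
    text = str(out_prefix)
    if text.endswith(("/", "\\")) or Path(text).is_dir():
        base = Path(text)
        base.mkdir(parents=True, exist_ok=True)
        name = lambda suffix: base / suffix
    else:
        prefix = Path(text)
        if str(prefix.parent) not in (".", ""):
            prefix.parent.mkdir(parents=True, exist_ok=True)
        name = lambda suffix: prefix.with_name(prefix.name + suffix)
    paths = {
        "matrix": name("counts.mtx"),
        "genes": name("genes.tsv"),
        "barcodes": name("barcodes.tsv"),
        "cells": name("cells.tsv"),
        "truth": name("truth.tsv"),
    }
    scipy.io.mmwrite(str(paths["matrix"]), scipy.sparse.coo_matrix(ds.counts))
    pd.Series(ds.gene_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(ds.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    ds.cells_frame().to_csv(paths["cells"], sep="\t", index=False)
    ds.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the literal de_type "null" must not parse as NaN
    truth = pd.read_csv(path, sep="\t", keep_default_na=False)
    if "gene" not in truth.columns or "de_type" not in truth.columns:
        raise ValueError("truth table needs 'gene' and 'de_type' columns")
    return truth
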