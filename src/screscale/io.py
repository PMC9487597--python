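"""Reading and writing count matrices.

Two on-disk layouts are supported:

* 10x-style Matrix Market triplet: ``matrix.mtx`` with co-located
  ``genes.tsv`` (or ``features.tsv``) and ``barcodes.tsv``;
* dense CSV/TSV with a header row of cell ids and a first column of gene ids.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CountMatrix

_GENE_SIDECARS = ("genes.tsv", "features.tsv")
_BARCODE_SIDECAR = "barcodes.tsv"


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer format from {path}; pass format explicitly")


def _read_mtx(path: Path) -> CountMatrix:
    if path.is_dir():
        candidates = sorted(path.glob("*.mtx"))
        if not candidates:
            raise FileNotFoundError(f"no .mtx file in directory {path}")
        mtx_path = candidates[0]
    else:
        mtx_path = path
    folder = mtx_path.parent
    gene_path = None
    for name in _GENE_SIDECARS:
        if (folder / name).exists():
            gene_path = folder / name
            break
    barcode_path = folder / _BARCODE_SIDECAR
    if gene_path is None or not barcode_path.exists():
        raise FileNotFoundError(
            f"mtx sidecar files (genes.tsv/features.tsv and barcodes.tsv) "
            f"not found next to {mtx_path}"
        )
    try:
        values = scipy.io.mmread(str(mtx_path)).tocsc()
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    genes = pd.read_csv(gene_path, sep="\t", header=None).iloc[:, 0].astype(str)
    barcodes = pd.read_csv(barcode_path, sep="\t", header=None).iloc[:, 0].astype(str)
    return CountMatrix(
        values=values,
        gene_ids=genes.to_numpy(),
        cell_ids=barcodes.to_numpy(),
    )


def _read_dense(path: Path, sep: str) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    return CountMatrix(
        values=values,
        gene_ids=df.index.astype(str).to_numpy(),
        cell_ids=df.columns.astype(str).to_numpy(),
    )


def read_counts(path: "str | os.PathLike", format: str | None = None,
                platform: str = "") -> CountMatrix:
    """Read a gene x cell count matrix from ``path``.

    Parameters
    ----------
    path
        ``.mtx`` file (or its directory) for Matrix Market input, otherwise a
        delimited text file.
    format
        One of ``{"mtx", "csv", "tsv"}``; inferred from the path if omitted.
    platform
        Batch/platform tag attached to the result.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    fmt = format or _infer_format(p)
    if fmt == "mtx":
        cm = _read_mtx(p)
    elif fmt == "csv":
        cm = _read_dense(p, ",")
    elif fmt == "tsv":
        cm = _read_dense(p, "\t")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected mtx, csv or tsv")
    cm.platform = platform
    return cm


def write_counts(cm: CountMatrix, path: "str | os.PathLike",
                 format: str | None = None) -> None:
    """Write ``cm`` as Matrix Market triplet (directory) or dense CSV/TSV."""
    p = Path(path)
    fmt = format or ("mtx" if p.is_dir() or p.suffix == "" else _infer_format(p))
    if fmt == "mtx":
        p.mkdir(parents=True, exist_ok=True)
        values = cm.values if sp.issparse(cm.values) else sp.csc_matrix(cm.values)
        # integer field keeps the round-trip exact for count data
        scipy.io.mmwrite(str(p / "matrix.mtx"), values.astype(int), field="integer")
        pd.Series(cm.gene_ids).to_csv(p / "genes.tsv", sep="\t",
                                      header=False, index=False)
        pd.Series(cm.cell_ids).to_csv(p / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        dense = cm.dense()
        if np.allclose(dense, np.round(dense)):
            dense = dense.astype(int)
        df = pd.DataFrame(dense, index=cm.gene_ids, columns=cm.cell_ids)
        df.to_csv(p, sep=sep)
    else:
        raise ValueError(f"unknown format {fmt!r}")
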