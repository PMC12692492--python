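"""Readers and writers for the plain-text formats the pipeline consumes.

Gene sets travel as GMT, sparse expression as Matrix Market (MTX) with
gene/barcode sidecars, and everything tabular as TSV.
"""

from __future__ import annotations

import os
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_mtx_dir(adata: ad.AnnData, outdir: str | os.PathLike,
                  layer: str | None = "counts") -> None:
    """Write an AnnData to ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``.

    The matrix is stored genes x cells (CellRanger convention).
    """
    os.makedirs(outdir, exist_ok=True)
    mat = adata.layers[layer] if layer else adata.X
    mat = sp.csr_matrix(np.asarray(mat).T if not sp.issparse(mat) else mat.T)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False)


def read_mtx_dir(indir: str | os.PathLike) -> ad.AnnData:
    """Read a ``matrix.mtx`` + sidecars directory into an AnnData (cells x genes)."""
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).tocsr()
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t",
                        header=None)[0].astype(str).tolist()
    cells = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t",
                        header=None)[0].astype(str).tolist()
    adata = ad.AnnData(X=mat.T.toarray().astype(float))
    adata.var_names = genes
    adata.obs_names = cells
    adata.layers["counts"] = adata.X.copy()
    return adata


def read_tsv_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with row labels in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t")
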