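"""Readers/writers: Matrix Market counts with TSV sidecars, TSV outputs,
and run metadata."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .model import CountMatrix

logger = logging.getLogger("scfactor")


def _read_ids(path) -> list:
    ids = [line.split("\t")[0].strip() for line in
           Path(path).read_text().splitlines() if line.strip()]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in {path}: {dupes[:5]}")
    return ids


def read_counts(mtx_path, genes_tsv, cells_tsv) -> CountMatrix:
    """Read a Matrix Market count matrix with gene/cell id sidecars.

    Orientation (cells x genes vs genes x cells) is auto-detected from the
    sidecar lengths and logged.  Non-integer entries are a format error.
    """
    mat = sio.mmread(mtx_path)
    mat = sp.coo_matrix(mat)
    bad = np.nonzero(mat.data != np.round(mat.data))[0]
    if bad.size:
        i = bad[0]
        raise ValueError(
            f"non-integer entry {mat.data[i]} at ({mat.row[i] + 1}, {mat.col[i] + 1}) "
            f"in {mtx_path}")
    if np.any(mat.data < 0):
        raise ValueError(f"negative counts in {mtx_path}")
    genes = _read_ids(genes_tsv)
    cells = _read_ids(cells_tsv)
    r, c = mat.shape
    if (r, c) == (len(cells), len(genes)):
        logger.info("matrix read as cells x genes (%d x %d)", r, c)
    elif (r, c) == (len(genes), len(cells)):
        logger.info("matrix read as genes x cells; transposing to cells x genes")
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (cells={len(cells)}, "
            f"genes={len(genes)}) orientation")
    return CountMatrix(sp.csr_matrix(mat).astype(np.int64), cells, genes)


def write_counts(outdir, data: CountMatrix, prefix: str = "counts"):
    """Write counts.mtx + genes.tsv + cells.tsv (cells x genes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / f"{prefix}.mtx"), sp.coo_matrix(data.counts), field="integer")
    (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in data.gene_ids))
    (outdir / "cells.tsv").write_text("".join(f"{c}\n" for c in data.cell_ids))
    return outdir / f"{prefix}.mtx"


def _frame(cell_ids, arr, columns) -> pd.DataFrame:
    df = pd.DataFrame(np.asarray(arr), columns=columns)
    df.insert(0, "cell_id", list(cell_ids))
    return df


def write_outputs(outdir, cell_ids, *, embeddings=None, labels=None,
                  probabilities=None, prob_columns=None, clusters=None,
                  corrected=None, gene_ids=None, umap_coords=None,
                  seed=None, config=None, version="0.1.0"):
    """Write TSV outputs (cell_id first column, full precision) + metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = {"sep": "\t", "index": False, "float_format": "%.17g"}
    written = []

    def _emit(name, df):
        path = outdir / name
        df.to_csv(path, **fmt)
        written.append(name)

    n = len(list(cell_ids))
    for arr, name in ((embeddings, "embeddings"), (probabilities, "probabilities"),
                      (corrected, "corrected"), (umap_coords, "umap")):
        if arr is not None and len(np.asarray(arr)) != n:
            raise ValueError(f"{name} row count does not match cell_ids")

    if embeddings is not None:
        d = np.asarray(embeddings).shape[1]
        _emit("embeddings.tsv", _frame(cell_ids, embeddings,
                                       [f"zy{i}" for i in range(d)]))
    if labels is not None:
        _emit("labels.tsv", _frame(cell_ids, np.asarray(labels, dtype=object)[:, None],
                                   ["predicted_label"]))
    if probabilities is not None:
        cols = prob_columns or [f"class{i}" for i in
                                range(np.asarray(probabilities).shape[1])]
        _emit("probabilities.tsv", _frame(cell_ids, probabilities, cols))
    if clusters is not None:
        _emit("clusters.tsv", _frame(cell_ids, np.asarray(clusters)[:, None],
                                     ["cluster"]))
    if corrected is not None:
        cols = gene_ids or [f"gene{i}" for i in range(np.asarray(corrected).shape[1])]
        _emit("corrected.tsv", _frame(cell_ids, corrected, cols))
    if umap_coords is not None:
        _emit("umap.tsv", _frame(cell_ids, umap_coords, ["umap1", "umap2"]))

    meta = {
        "seed": seed,
        "config": config,
        "package_version": version,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": written,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return written


def read_label_column(path) -> list:
    """Per-cell labels from a 1- or 2-column TSV; empty/NA fields -> None."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        val = fields[-1].strip()
        out.append(None if val in ("", "NA", "None", "-") else val)
    return out
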