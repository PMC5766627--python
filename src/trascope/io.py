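"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel either as Matrix Market sparse files with gene /
cell TSV sidecars or as a single dense TSV (genes as rows, header row of
cell ids).  Gene annotation is BED6 plus a TRA classification TSV; QC stats,
TF pairs and all result tables are plain TSV.  Dense TSV round-trips
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    AIRE_CLASSES,
    ExpressionMatrix,
    GeneAnnotation,
    validate_qc_table,
)

log = logging.getLogger("trascope")

_CELL_META_COLUMNS = ("batch", "age", "dataset")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(matrix_path, genes_path=None, cells_path=None) -> ExpressionMatrix:
    """Read an expression matrix.

    With ``genes_path`` and ``cells_path`` given, ``matrix_path`` is a Matrix
    Market file (genes x cells) and the sidecars are TSVs whose first column
    holds gene / cell ids (cell sidecars may carry batch / age / dataset
    columns).  Otherwise ``matrix_path`` is a dense TSV with a header row of
    cell ids and gene ids in the first column.
    """
    matrix_path = Path(matrix_path)
    if genes_path is None and cells_path is None:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
        return ExpressionMatrix(
            frame.to_numpy(dtype=float),
            pd.Index(frame.index.astype(str)),
            pd.Index(frame.columns.astype(str)),
        )
    if genes_path is None or cells_path is None:
        raise ValueError("provide both genes_path and cells_path, or neither")

    values = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(values):
        values = values.toarray()
    values = np.asarray(values, dtype=float)

    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    gene_ids = pd.Index(genes.iloc[:, 0].astype(str))
    cell_ids = pd.Index(cells.iloc[:, 0].astype(str))
    if values.shape[0] != len(gene_ids):
        raise ValueError(
            f"matrix has {values.shape[0]} rows but gene table "
            f"{Path(genes_path).name} lists {len(gene_ids)} genes"
        )
    if values.shape[1] != len(cell_ids):
        raise ValueError(
            f"matrix has {values.shape[1]} columns but cell table "
            f"{Path(cells_path).name} lists {len(cell_ids)} cells"
        )
    meta_cols = [c for c in cells.columns[1:] if c in _CELL_META_COLUMNS]
    meta = cells.set_index(cells.columns[0])[meta_cols] if meta_cols else pd.DataFrame()
    if len(meta):
        meta.index = cell_ids
    return ExpressionMatrix(values, gene_ids, cell_ids, meta)


def write_expression_dense(matrix: ExpressionMatrix, path) -> None:
    """Write a dense TSV (bit-identical round trip with read_expression)."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def write_expression_mtx(matrix: ExpressionMatrix, out_dir, prefix="matrix") -> dict:
    """Write Matrix Market + gene/cell TSV sidecars; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.coo_matrix(matrix.values))
    pd.DataFrame({"gene_id": matrix.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": matrix.cell_ids})
    for col in _CELL_META_COLUMNS:
        if col in matrix.cell_meta.columns:
            cells[col] = matrix.cell_meta[col].to_numpy()
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_annotation(bed_path, tra_table_path=None) -> GeneAnnotation:
    """Read a BED6-like annotation plus an optional TRA classification table.

    BED columns: chrom, start, end, gene_id, score (ignored), strand.  The
    TRA table maps gene_id to an Aire class token and a Fezf2 flag; genes
    absent from it default to NON_TRA / fezf2_induced = False.  A column
    ``is_mito`` in the TRA table is honoured; otherwise mitochondrial genes
    are recognised by chromosome names chrM / chrMT / MT / M.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    frame = bed.set_index("gene_id")[["chrom", "start", "end", "strand"]]
    frame["is_mito"] = frame["chrom"].isin(["chrM", "chrMT", "MT", "M"])
    frame["aire_class"] = "NON_TRA"
    frame["fezf2_induced"] = False

    if tra_table_path is not None:
        tra = pd.read_csv(tra_table_path, sep="\t", dtype={"gene_id": str})
        tra = tra.set_index("gene_id")
        unknown_class = set(tra["aire_class"]) - set(AIRE_CLASSES)
        if unknown_class:
            raise ValueError(f"unknown aire_class token(s): {sorted(unknown_class)}")
        known = tra.index.intersection(frame.index)
        frame.loc[known, "aire_class"] = tra.loc[known, "aire_class"]
        if "fezf2_induced" in tra.columns:
            frame.loc[known, "fezf2_induced"] = tra.loc[known, "fezf2_induced"].astype(bool)
        if "is_mito" in tra.columns:
            frame.loc[known, "is_mito"] = tra.loc[known, "is_mito"].astype(bool)
    return GeneAnnotation(frame)


def write_annotation(annotation: GeneAnnotation, bed_path, tra_table_path=None) -> None:
    f = annotation.frame
    bed = pd.DataFrame(
        {
            "chrom": f["chrom"],
            "start": f["start"],
            "end": f["end"],
            "gene_id": f.index,
            "score": ".",
            "strand": f["strand"],
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if tra_table_path is not None:
        tra = f[["aire_class", "fezf2_induced", "is_mito"]].copy()
        tra.index.name = "gene_id"
        tra.to_csv(tra_table_path, sep="\t")


# ---------------------------------------------------------------------------
# QC tables, TF pairs
# ---------------------------------------------------------------------------

def read_qc_table(path) -> pd.DataFrame:
    qc = pd.read_csv(path, sep="\t", index_col=0)
    qc.index = qc.index.astype(str)
    return validate_qc_table(qc)


def write_qc_table(qc: pd.DataFrame, path) -> None:
    out = qc.copy()
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t")


def read_tf_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "target_id": str})
    for col in ("tf_id", "target_id"):
        if col not in pairs.columns:
            raise ValueError(f"TF pair table is missing column {col!r}")
    return pairs


def write_tsv(frame: pd.DataFrame, path, index=False) -> None:
    frame.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, command: str, config: dict, seed, inputs: dict) -> Path:
    """Write a machine-readable provenance record for a pipeline run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in inputs.items()
            if p is not None
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    log.info("run %s with seed %s; provenance at %s", command, seed, path)
    return path
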