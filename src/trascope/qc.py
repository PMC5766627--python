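"""Cell- and gene-level quality filters.

Cells are excluded when they detect fewer than 1000 genes, have fewer than
500,000 exon-mapped reads, or more than 20% mitochondrial reads; the
boundary values themselves pass (the criteria are strict inequalities).
Genes are kept when expressed at 5 or more TPM in at least 5 cells.  The
gene filter runs after the cell filter so that failed cells cannot rescue
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, validate_qc_table


@dataclass
class QCReport:
    """Per-cell and per-gene pass/fail decisions with summary counts."""

    cell_table: pd.DataFrame  # index cell_id: passed (bool), reasons (str)
    gene_keep: pd.Index | None = None
    n_genes_total: int | None = None

    @property
    def passed_cells(self) -> pd.Index:
        return self.cell_table.index[self.cell_table["passed"]]

    @property
    def failed_cells(self) -> pd.Index:
        return self.cell_table.index[~self.cell_table["passed"]]

    def summary(self) -> dict:
        out = {
            "n_cells_total": len(self.cell_table),
            "n_cells_passed": int(self.cell_table["passed"].sum()),
            "n_cells_failed": int((~self.cell_table["passed"]).sum()),
        }
        if self.gene_keep is not None:
            out["n_genes_total"] = self.n_genes_total
            out["n_genes_kept"] = len(self.gene_keep)
        return out


def filter_cells(
    qc_table: pd.DataFrame,
    min_genes: int = 1000,
    min_reads: int = 500_000,
    max_mito: float = 0.20,
) -> QCReport:
    """Apply the cell quality filter to a per-cell QC table.

    A cell fails iff ``n_detected_genes < min_genes`` OR
    ``exon_mapped_reads < min_reads`` OR ``mito_fraction > max_mito``;
    the detected-gene count is the raw (pre-gene-filter) count.
    """
    qc = validate_qc_table(qc_table)
    reasons = []
    for cell_id, row in qc.iterrows():
        r = []
        if row["n_detected_genes"] < min_genes:
            r.append("min_genes")
        if row["exon_mapped_reads"] < min_reads:
            r.append("min_reads")
        if row["mito_fraction"] > max_mito:
            r.append("max_mito")
        reasons.append(",".join(r))
    table = pd.DataFrame(
        {"passed": [r == "" for r in reasons], "reasons": reasons}, index=qc.index
    )
    return QCReport(cell_table=table)


def filter_genes(
    matrix: ExpressionMatrix, min_tpm: float = 5.0, min_cells: int = 5
) -> pd.Index:
    """Keep-list of genes expressed at ``>= min_tpm`` in ``>= min_cells`` cells."""
    n_expressing = (matrix.values >= min_tpm).sum(axis=1)
    return matrix.gene_ids[n_expressing >= min_cells]


def apply_qc(
    matrix: ExpressionMatrix,
    qc_table: pd.DataFrame,
    min_genes: int = 1000,
    min_reads: int = 500_000,
    max_mito: float = 0.20,
    min_tpm: float = 5.0,
    min_cells: int = 5,
) -> tuple[ExpressionMatrix, QCReport]:
    """Cell filter followed by gene filter; returns the filtered matrix."""
    missing = matrix.cell_ids.difference(qc_table.index)
    if len(missing):
        raise ValueError(
            f"QC table is missing row(s) for matrix cell(s): {missing.tolist()[:5]}"
        )
    report = filter_cells(
        qc_table.loc[matrix.cell_ids], min_genes=min_genes, min_reads=min_reads, max_mito=max_mito
    )
    filtered = matrix.subset_cells(report.passed_cells)
    keep = filter_genes(filtered, min_tpm=min_tpm, min_cells=min_cells)
    report.gene_keep = keep
    report.n_genes_total = matrix.n_genes
    return filtered.subset_genes(keep), report
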