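"""Core data containers shared by every stage of the pipeline.

The pipeline's universal substrate is a genes x cells TPM matrix
(:class:`ExpressionMatrix`) together with a genomic/functional annotation of
the genes (:class:`GeneAnnotation`).  Genes are classified by their response
to Aire loss (Aire-dependent / Aire-enhanced / Aire-unaffected tissue
restricted antigens, or non-TRA) with an independent Fezf2-induced flag, the
categories that drive every downstream TRA statistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mutually exclusive Aire-response classes.  NON_TRA genes are excluded from
#: every TRA subset.
AIRE_CLASSES = ("AIRE_DEPENDENT", "AIRE_ENHANCED", "AIRE_UNAFFECTED", "NON_TRA")

#: TRA subset names understood by :meth:`GeneAnnotation.tra_subset`.
TRA_SUBSETS = ("aire_dependent", "aire_enhanced", "aire_unaffected", "fezf2")

_SUBSET_TO_CLASS = {
    "aire_dependent": "AIRE_DEPENDENT",
    "aire_enhanced": "AIRE_ENHANCED",
    "aire_unaffected": "AIRE_UNAFFECTED",
}

ANNOTATION_COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "is_mito",
    "aire_class",
    "fezf2_induced",
)

QC_COLUMNS = ("exon_mapped_reads", "n_detected_genes", "mito_fraction")

SUBPOPULATIONS = ("jTEC", "mTEChi", "mTEClo")


@dataclass
class GeneAnnotation:
    """Genomic coordinates (BED convention, 0-based half-open) plus TRA class
    per gene.

    ``frame`` is indexed by unique ``gene_id`` and carries the columns in
    :data:`ANNOTATION_COLUMNS`.  The gene position used for all base-pair
    distance computations is the midpoint ``floor((start + end) / 2)`` —
    symmetric, strand-free and robust to overlapping genes.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ANNOTATION_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"annotation is missing columns: {missing}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dups[:5]}")
        bad = f.index[(f["end"] <= f["start"]) | (f["start"] < 0)]
        if len(bad):
            g = bad[0]
            raise ValueError(
                f"invalid coordinates for gene {g!r}: "
                f"start={f.loc[g, 'start']}, end={f.loc[g, 'end']}"
            )
        bad_strand = set(f["strand"]) - {"+", "-", "."}
        if bad_strand:
            raise ValueError(f"invalid strand symbols: {sorted(bad_strand)}")
        bad_class = set(f["aire_class"]) - set(AIRE_CLASSES)
        if bad_class:
            raise ValueError(f"unknown aire_class token(s): {sorted(bad_class)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def n_genes(self) -> int:
        return len(self.frame)

    @property
    def midpoints(self) -> pd.Series:
        """Gene midpoint, ``floor((start + end) / 2)`` in bp."""
        return (self.frame["start"] + self.frame["end"]) // 2

    def tra_subset(self, name: str) -> pd.Index:
        """Gene ids belonging to one TRA subset.

        ``name`` is one of :data:`TRA_SUBSETS`; ``"fezf2"`` selects the
        Fezf2-induced overlay, which cuts across the Aire classes but never
        includes NON_TRA genes.
        """
        f = self.frame
        if name == "fezf2":
            mask = f["fezf2_induced"] & (f["aire_class"] != "NON_TRA")
        elif name in _SUBSET_TO_CLASS:
            mask = f["aire_class"] == _SUBSET_TO_CLASS[name]
        else:
            raise ValueError(f"unknown TRA subset {name!r}; expected one of {TRA_SUBSETS}")
        return f.index[mask]

    def tra_ids(self) -> pd.Index:
        """All TRA-classified genes (any class except NON_TRA)."""
        return self.frame.index[self.frame["aire_class"] != "NON_TRA"]

    def subset(self, gene_ids) -> "GeneAnnotation":
        return GeneAnnotation(self.frame.loc[pd.Index(gene_ids)].copy())


@dataclass
class ExpressionMatrix:
    """TPM values for genes x cells plus per-cell metadata.

    A gene is "detected" in a cell iff its TPM is strictly positive.
    ``cell_meta`` is indexed by cell id and may carry batch / age / dataset
    labels; it is allowed to be empty.
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x cells array")
        ng, nc = self.values.shape
        if ng != len(self.gene_ids):
            raise ValueError(
                f"matrix has {ng} rows but {len(self.gene_ids)} gene ids"
            )
        if nc != len(self.cell_ids):
            raise ValueError(
                f"matrix has {nc} columns but {len(self.cell_ids)} cell ids"
            )
        for label, idx in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if idx.has_duplicates:
                dups = idx[idx.duplicated()].unique().tolist()
                raise ValueError(f"duplicate {label} ids: {dups[:5]}")
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )
        if len(self.cell_meta) and not self.cell_meta.index.equals(self.cell_ids):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def log2p1(self) -> np.ndarray:
        """log2(TPM + 1), the working scale for PCA, clustering and DE."""
        return np.log2(self.values + 1.0)

    def detected(self) -> np.ndarray:
        """Boolean genes x cells detection matrix (TPM > 0)."""
        return self.values > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = pd.Index(gene_ids)
        pos = self.gene_ids.get_indexer(gene_ids)
        if (pos < 0).any():
            missing = gene_ids[pos < 0].tolist()
            raise KeyError(f"gene id(s) absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[pos], gene_ids, self.cell_ids, self.cell_meta.copy()
        )

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        cell_ids = pd.Index(cell_ids)
        pos = self.cell_ids.get_indexer(cell_ids)
        if (pos < 0).any():
            missing = cell_ids[pos < 0].tolist()
            raise KeyError(f"cell id(s) absent from matrix: {missing[:5]}")
        meta = self.cell_meta.loc[cell_ids].copy() if len(self.cell_meta) else pd.DataFrame()
        return ExpressionMatrix(self.values[:, pos], self.gene_ids, cell_ids, meta)


def validate_qc_table(qc: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell QC table (indexed by cell id).

    Columns: exon-mapped read count, number of detected genes, and the
    fraction of reads mapping to mitochondrial genes (in [0, 1]).
    """
    missing = [c for c in QC_COLUMNS if c not in qc.columns]
    if missing:
        raise ValueError(f"QC table is missing columns: {missing}")
    if qc.index.has_duplicates:
        raise ValueError("duplicate cell ids in QC table")
    bad = qc.index[(qc["mito_fraction"] < 0) | (qc["mito_fraction"] > 1)]
    if len(bad):
        raise ValueError(f"mito_fraction outside [0, 1] for cell {bad[0]!r}")
    if (qc["exon_mapped_reads"] < 0).any() or (qc["n_detected_genes"] < 0).any():
        raise ValueError("negative read or gene counts in QC table")
    return qc


def seeded_rng(seed: int) -> np.random.Generator:
    """Return a NumPy random generator for a non-negative integer seed.

    Every stochastic operation in the package takes either a seed or a
    generator produced here, so that a fixed seed yields bit-identical
    outputs across runs.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    return np.random.default_rng(int(seed))


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return seeded_rng(rng_or_seed)
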