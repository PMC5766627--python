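"""Subpopulation structure: PCA, loading-based gene selection, resampling
consensus clustering, marker-based stage labelling, and PC / cell-size
diagnostics.

The consensus procedure follows the resampling scheme of Monti-style
consensus clustering: each of ``n_resamples`` events draws 70% of cells and
70% of genes without replacement, clusters the subsample by agglomerative
hierarchical clustering (Euclidean distance on log2(TPM+1), Ward linkage —
average linkage degenerates to outlier-peeling on single-cell dropout
noise), and the consensus index of a cell pair is the fraction of
co-samplings in which the pair co-clustered.  The final partition cuts a
hierarchical tree of (1 - consensus); per-k stability is the mean consensus
over within-cluster pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .types import ExpressionMatrix, SUBPOPULATIONS, as_rng


@dataclass
class PCAResult:
    """PCA of cells on log2(TPM+1): scores are cells x components, loadings
    genes x components with unit-norm columns.  Component signs are fixed by
    making each loading column's largest-magnitude entry positive."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index


@dataclass
class ConsensusResult:
    """Consensus matrix and partition for one value of k.

    ``consensus[i, j]`` = co-clusterings / co-samplings of cells i and j;
    pairs never co-sampled are imputed 0 (with a warning).  ``stability`` is
    the mean consensus over within-cluster pairs of the final partition.
    """

    k: int
    consensus: np.ndarray
    assignments: pd.Series
    stability: float
    n_undefined_pairs: int = 0

    def __post_init__(self) -> None:
        c = self.consensus
        assert np.allclose(c, c.T), "consensus matrix must be symmetric"
        assert np.allclose(np.diag(c), 1.0), "consensus diagonal must be 1"
        assert c.min() >= 0 and c.max() <= 1 + 1e-12, "consensus entries must lie in [0, 1]"


def run_pca(
    matrix: ExpressionMatrix, n_components: int | None = None, log_transform: bool = True
) -> PCAResult:
    """PCA with cells as observations and genes as (centred) features."""
    if matrix.n_cells < 3 or matrix.n_genes < 3:
        raise ValueError("PCA requires at least 3 cells and 3 genes")
    X = (matrix.log2p1() if log_transform else matrix.values).T  # cells x genes
    max_comp = min(matrix.n_cells - 1, matrix.n_genes)
    if n_components is None:
        n_components = min(10, max_comp)
    elif n_components > max_comp:
        raise ValueError(
            f"requested {n_components} components but at most {max_comp} are available"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-|entry| of each loading column is positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    return PCAResult(
        scores=U * S,
        loadings=Vt.T,
        explained_variance_ratio=S**2 / total_var if total_var > 0 else S * 0,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
    )


def select_loading_genes(
    pca: PCAResult, components=(2, 3), threshold: float = 0.02
) -> pd.Index:
    """Genes with |loading| strictly above ``threshold`` on any of the
    requested (1-based) components."""
    n_comp = pca.loadings.shape[1]
    for comp in components:
        if not 1 <= comp <= n_comp:
            raise ValueError(f"component {comp} not available (PCA has {n_comp})")
    cols = [c - 1 for c in components]
    mask = (np.abs(pca.loadings[:, cols]) > threshold).any(axis=1)
    return pca.gene_ids[mask]


def pc_cellsize_correlation(pca: PCAResult, qc_table: pd.DataFrame) -> pd.Series:
    """Spearman rho between each PC's scores and per-cell detected-gene
    counts (ties mid-ranked); constant inputs yield NaN with a warning."""
    counts = qc_table.loc[pca.cell_ids, "n_detected_genes"].to_numpy(dtype=float)
    rhos = {}
    for j in range(pca.scores.shape[1]):
        s = pca.scores[:, j]
        if np.ptp(s) == 0 or np.ptp(counts) == 0:
            warnings.warn(f"constant input for PC{j + 1}; Spearman rho undefined")
            rhos[f"PC{j + 1}"] = np.nan
        else:
            rhos[f"PC{j + 1}"] = spearmanr(s, counts).statistic
    return pd.Series(rhos, name="spearman_rho")


def consensus_cluster(
    matrix: ExpressionMatrix,
    k_range=range(2, 7),
    n_resamples: int = 2000,
    cell_frac: float = 0.7,
    gene_frac: float = 0.7,
    rng=None,
    linkage_method: str = "ward",
) -> dict[int, ConsensusResult]:
    """Resampling consensus clustering; returns one result per k.

    The resampling stream is applied to a canonical (sorted-id) ordering of
    cells and genes, so permuting the input order permutes the assignments
    identically.  A single linkage tree per resample is cut at every k.
    """
    rng = as_rng(rng if rng is not None else 0)
    k_range = list(k_range)
    order = np.argsort(matrix.cell_ids)
    gorder = np.argsort(matrix.gene_ids)
    cell_ids = matrix.cell_ids[order]
    X = matrix.log2p1()[np.ix_(gorder, order)].T  # cells x genes, canonical
    n, g = X.shape
    m = int(round(cell_frac * n))
    mg = max(1, int(round(gene_frac * g)))
    if m < max(k_range):
        raise ValueError("too few cells per resample for the largest k")

    co_sample = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(n_resamples):
        cells = np.sort(rng.choice(n, size=m, replace=False))
        genes = rng.choice(g, size=mg, replace=False)
        sub = X[np.ix_(cells, genes)]
        Z = sch.linkage(sub, method=linkage_method, metric="euclidean")
        ix = np.ix_(cells, cells)
        co_sample[ix] += 1
        for k in k_range:
            lab = sch.fcluster(Z, t=k, criterion="maxclust")
            co_cluster[k][ix] += lab[:, None] == lab[None, :]

    undefined = co_sample == 0
    np.fill_diagonal(undefined, False)
    n_undef = int(undefined.sum() // 2)
    if n_undef:
        warnings.warn(
            f"{n_undef} cell pair(s) never co-sampled; consensus imputed as 0"
        )
    denom = np.where(co_sample > 0, co_sample, 1.0)

    results = {}
    for k in k_range:
        consensus = co_cluster[k] / denom
        consensus[undefined] = 0.0
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2
        Z = sch.linkage(squareform(1.0 - consensus, checks=False), method=linkage_method)
        lab = sch.fcluster(Z, t=k, criterion="maxclust")
        within = lab[:, None] == lab[None, :]
        np.fill_diagonal(within, False)
        stability = float(consensus[within].mean()) if within.any() else float("nan")
        results[k] = ConsensusResult(
            k=k,
            consensus=consensus,
            assignments=pd.Series(lab, index=cell_ids, name="cluster"),
            stability=stability,
            n_undefined_pairs=n_undef,
        )
    return results


def label_clusters(
    assignments: pd.Series,
    matrix: ExpressionMatrix,
    jtec_markers=("Pdpn", "Ccl21"),
    maturation_markers=("Aire",),
) -> pd.Series:
    """Map the k=3 clusters to maturation stages.

    The cluster with the highest mean jTEC-marker expression becomes jTEC;
    of the remaining two, the one with higher mean Aire expression becomes
    mTEChi and the other mTEClo.  Exact ties raise, demanding a manual
    override.
    """
    clusters = sorted(assignments.unique())
    if len(clusters) != 3:
        raise ValueError(f"expected 3 clusters, got {len(clusters)}")
    for marker in tuple(jtec_markers) + tuple(maturation_markers):
        if marker not in matrix.gene_ids:
            raise KeyError(f"marker gene {marker!r} absent from matrix")
    Y = pd.DataFrame(matrix.log2p1(), index=matrix.gene_ids, columns=matrix.cell_ids)

    def cluster_mean(markers, cluster):
        cells = assignments.index[assignments == cluster]
        return float(Y.loc[list(markers), cells].to_numpy().mean())

    jtec_means = {c: cluster_mean(jtec_markers, c) for c in clusters}
    ranked = sorted(clusters, key=lambda c: jtec_means[c], reverse=True)
    if jtec_means[ranked[0]] == jtec_means[ranked[1]]:
        raise ValueError(
            "tie in mean jTEC-marker expression; provide a manual label override"
        )
    jtec = ranked[0]
    rest = ranked[1:]
    aire_means = {c: cluster_mean(maturation_markers, c) for c in rest}
    if aire_means[rest[0]] == aire_means[rest[1]]:
        raise ValueError(
            "tie in mean maturation-marker expression; provide a manual label override"
        )
    hi = max(rest, key=lambda c: aire_means[c])
    lo = min(rest, key=lambda c: aire_means[c])
    mapping = {jtec: "jTEC", hi: "mTEChi", lo: "mTEClo"}
    labels = assignments.map(mapping)
    labels.name = "subpopulation"
    return labels
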