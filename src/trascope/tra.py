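"""Population-level TRA expression statistics.

Covers: per-gene expression frequency and mean level by gene category with
pairwise Mann-Whitney-Wilcoxon tests (Bonferroni-adjusted within a panel),
the gene-accumulation curve over random cell orderings, the repertoire
overlap of TRA subsets across maturation stages, and the per-cell TRA load
(detected TRAs normalised to detected genes).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .types import ExpressionMatrix, GeneAnnotation, SUBPOPULATIONS, TRA_SUBSETS, as_rng


def _pairwise_mww(groups: dict[str, np.ndarray], panel: str) -> pd.DataFrame:
    """Two-sided MWW for every pair of groups; the Bonferroni family is the
    set of comparisons performed within this panel."""
    names = [n for n, v in groups.items() if len(v)]
    skipped = set(groups) - set(names)
    if skipped:
        warnings.warn(f"empty group(s) skipped in panel {panel!r}: {sorted(skipped)}")
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        stat, p = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            {
                "panel": panel,
                "group_a": a,
                "group_b": b,
                "mww_u": stat,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(
        rows, columns=["panel", "group_a", "group_b", "mww_u", "p_raw", "p_bonferroni"]
    )


def category_stats(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    detected_only: bool = False,
    include_fezf2: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene expression frequency and mean level by Aire category.

    Frequency is the fraction of cells with TPM > 0; the mean level is the
    mean log2(TPM+1) across all cells (or across detecting cells only when
    ``detected_only``).  For each metric, all category pairs are compared by
    a two-sided MWW test with Bonferroni adjustment over the pairs of that
    panel.  ``include_fezf2`` adds the Fezf2-induced TRAs as an overlay
    category (its genes also appear under their Aire class).
    """
    det = matrix.detected()
    freq = det.mean(axis=1)
    Y = matrix.log2p1()
    if detected_only:
        with np.errstate(invalid="ignore"):
            level = np.where(det.any(axis=1), (Y * det).sum(axis=1) / det.sum(axis=1), 0.0)
    else:
        level = Y.mean(axis=1)

    cat = annotation.frame.loc[matrix.gene_ids, "aire_class"]
    stats = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "category": cat.to_numpy(),
            "expression_frequency": freq,
            "mean_level": level,
        }
    )
    if include_fezf2:
        fez = annotation.tra_subset("fezf2").intersection(matrix.gene_ids)
        sub = stats[stats["gene_id"].isin(fez)].copy()
        sub["category"] = "FEZF2_INDUCED"
        stats = pd.concat([stats, sub], ignore_index=True)

    tests = []
    for metric in ("expression_frequency", "mean_level"):
        groups = {
            c: g[metric].to_numpy() for c, g in stats.groupby("category")
        }
        tests.append(_pairwise_mww(groups, panel=metric))
    return stats, pd.concat(tests, ignore_index=True)


@dataclass
class AccumulationCurve:
    """Mean distinct detected genes after m cells, averaged over random
    orderings.  Non-decreasing in m; the endpoint equals the total number of
    detected genes regardless of ordering."""

    mean_detected: np.ndarray  # length n_cells; entry m-1 = after m cells
    n_orders: int

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.mean_detected) >= -1e-9), "curve must be non-decreasing"


def accumulation_curve(
    matrix: ExpressionMatrix, n_orders: int = 100, rng=None, gene_ids=None
) -> AccumulationCurve:
    """Gene-accumulation curve over ``n_orders`` random cell orderings.

    Optionally restricted to ``gene_ids`` (e.g. a TRA subset).
    """
    if matrix.n_cells < 1:
        raise ValueError("accumulation curve requires at least 1 cell")
    rng = as_rng(rng if rng is not None else 0)
    det = matrix.detected()
    if gene_ids is not None:
        det = det[matrix.gene_ids.get_indexer_for(pd.Index(gene_ids))]
    n_genes, n_cells = det.shape
    total = np.zeros(n_cells)
    cells_idx = np.arange(n_cells)
    for _ in range(n_orders):
        order = rng.permutation(cells_idx)
        d = det[:, order]
        # first cell (in this order) at which each gene is detected
        first = np.where(d.any(axis=1), d.argmax(axis=1), n_cells)
        counts = np.bincount(first, minlength=n_cells + 1)[:n_cells]
        total += np.cumsum(counts)
    return AccumulationCurve(mean_detected=total / n_orders, n_orders=n_orders)


def repertoire_overlap(
    matrix: ExpressionMatrix,
    assignments: pd.Series,
    annotation: GeneAnnotation,
    subsets=("aire_dependent", "aire_enhanced", "aire_unaffected"),
    min_cells: int = 1,
) -> pd.DataFrame:
    """Fraction of each TRA subset's genes in each of the 8 detection
    regions over {jTEC, mTEChi, mTEClo}.

    A gene is detected in a population iff TPM > 0 in at least ``min_cells``
    of its cells; each gene lands in exactly one region, so the fractions
    sum to 1 per subset.
    """
    labels = assignments.loc[matrix.cell_ids]
    det = matrix.detected()
    pop_detect = {}
    for pop in SUBPOPULATIONS:
        mask = (labels == pop).to_numpy()
        pop_detect[pop] = det[:, mask].sum(axis=1) >= min_cells

    regions = []
    for r in range(len(SUBPOPULATIONS) + 1):
        regions += [frozenset(c) for c in itertools.combinations(SUBPOPULATIONS, r)]

    rows = []
    for subset in subsets:
        ids = annotation.tra_subset(subset).intersection(matrix.gene_ids)
        pos = matrix.gene_ids.get_indexer_for(ids)
        row = {"tra_subset": subset, "n_genes": len(ids)}
        if len(ids) == 0:
            for reg in regions:
                row["+".join(sorted(reg)) or "none"] = np.nan
            rows.append(row)
            continue
        pattern = [
            frozenset(p for p in SUBPOPULATIONS if pop_detect[p][i]) for i in pos
        ]
        for reg in regions:
            frac = sum(pat == reg for pat in pattern) / len(ids)
            row["+".join(sorted(reg)) or "none"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def per_cell_tra_load(
    matrix: ExpressionMatrix,
    assignments: pd.Series,
    annotation: GeneAnnotation,
    subsets=TRA_SUBSETS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell detected-TRA count normalised by detected-gene count, per
    TRA subset, with pairwise subpopulation MWW tests per subset panel.

    Cells detecting zero genes are excluded with a warning.
    """
    labels = assignments.loc[matrix.cell_ids]
    det = matrix.detected()
    n_detected = det.sum(axis=0)
    usable = n_detected > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} cell(s) with zero detected genes excluded"
        )

    loads = []
    for subset in subsets:
        ids = annotation.tra_subset(subset).intersection(matrix.gene_ids)
        pos = matrix.gene_ids.get_indexer_for(ids)
        n_subset = det[pos].sum(axis=0)
        frame = pd.DataFrame(
            {
                "cell_id": matrix.cell_ids,
                "subpopulation": labels.to_numpy(),
                "tra_subset": subset,
                "n_detected_genes": n_detected,
                "n_detected_tras": n_subset,
                "load": np.where(usable, n_subset / np.maximum(n_detected, 1), np.nan),
            }
        )[usable]
        loads.append(frame)
    loads = pd.concat(loads, ignore_index=True)

    tests = []
    for subset, sub in loads.groupby("tra_subset"):
        groups = {
            pop: g["load"].to_numpy() for pop, g in sub.groupby("subpopulation")
        }
        tests.append(_pairwise_mww(groups, panel=f"load:{subset}"))
    return loads, pd.concat(tests, ignore_index=True)
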