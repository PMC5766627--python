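"""One-vs-rest differential expression by a nested-linear-model
likelihood-ratio test.

Per gene, on y = log2(TPM+1): the full model fits one mean per
subpopulation, the reduced model a single intercept.  Under Gaussian
likelihood the LRT statistic is n * ln(RSS_reduced / RSS_full), referred to
a chi-square with (number of populations - 1) degrees of freedom; p-values
are Benjamini-Hochberg adjusted across genes.  Per-population direction is
the difference of means (population minus rest) on the log2 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

_RSS_FLOOR = 1e-12


def lrt_de(
    matrix,
    assignments: pd.Series,
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Likelihood-ratio-test DE of every gene across subpopulations.

    Returns a long table with one row per gene x population carrying the
    shared omnibus statistic (lrt_stat, df, p, q) and the per-population
    log2 fold change; ``is_significant`` is q < q_threshold and
    |log2fc| > lfc_threshold.  Genes whose full-model residual sum of
    squares underflows are floored at 1e-12 and flagged.
    """
    labels = assignments.loc[matrix.cell_ids]
    pops = sorted(labels.unique())
    if len(pops) < 2:
        raise ValueError("differential expression requires >= 2 populations")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"population(s) with fewer than 2 cells: {small.index.tolist()}"
        )

    Y = matrix.log2p1()  # genes x cells
    n = Y.shape[1]
    grand = Y.mean(axis=1, keepdims=True)
    rss_reduced = ((Y - grand) ** 2).sum(axis=1)

    rss_full = np.zeros(Y.shape[0])
    pop_means = {}
    masks = {}
    for p in pops:
        mask = (labels == p).to_numpy()
        masks[p] = mask
        mean_p = Y[:, mask].mean(axis=1)
        pop_means[p] = mean_p
        rss_full += ((Y[:, mask] - mean_p[:, None]) ** 2).sum(axis=1)

    floored = rss_full < _RSS_FLOOR
    rss_full_safe = np.maximum(rss_full, _RSS_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(np.maximum(rss_reduced, _RSS_FLOOR) / rss_full_safe)
    stat = np.maximum(stat, 0.0)
    df = len(pops) - 1
    p_vals = np.clip(chi2.sf(stat, df), 1e-300, 1.0)
    q_vals = multipletests(p_vals, method="fdr_bh")[1]

    records = []
    for p in pops:
        rest_mean = Y[:, ~masks[p]].mean(axis=1)
        log2fc = pop_means[p] - rest_mean
        sig = (q_vals < q_threshold) & (np.abs(log2fc) > lfc_threshold)
        records.append(
            pd.DataFrame(
                {
                    "gene_id": matrix.gene_ids,
                    "population": p,
                    "log2fc": log2fc,
                    "lrt_stat": stat,
                    "df": df,
                    "p": p_vals,
                    "q": q_vals,
                    "is_significant": sig,
                    "rss_floored": floored,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def de_summary(records: pd.DataFrame, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Per-population counts of significant up- and down-regulated genes."""
    rows = []
    for pop, sub in records.groupby("population"):
        sig = sub[sub["is_significant"]]
        rows.append(
            {
                "population": pop,
                "n_up": int((sig["log2fc"] > lfc_threshold).sum()),
                "n_down": int((sig["log2fc"] < -lfc_threshold).sum()),
            }
        )
    return pd.DataFrame(rows)
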