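"""Co-expression filtering of candidate TF-target pairs.

Each pair is scored by Spearman correlation of TPM across all cells (ties
mid-ranked, p from the large-sample t approximation) and by the Jaccard
index of binarized detection (TPM > 0).  A pair is kept when |r| > 0.3,
p < 0.005 and j > 0.3 (all strict), the stringent conjunction used to build
the regulatory network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import ExpressionMatrix


def jaccard_detection(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two detection vectors; 0 when neither detects."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def score_pairs(
    matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    r_threshold: float = 0.3,
    p_threshold: float = 0.005,
    j_threshold: float = 0.3,
) -> pd.DataFrame:
    """Score every candidate TF-target pair and mark the kept edges.

    Pairs referencing a gene absent from the matrix are flagged
    (``missing_gene`` = True, scores NaN, kept = False) rather than dropped.
    """
    frame = matrix.to_frame()
    out = pairs.copy()
    r = np.full(len(pairs), np.nan)
    p = np.full(len(pairs), np.nan)
    j = np.full(len(pairs), np.nan)
    missing = np.zeros(len(pairs), dtype=bool)
    for i, (tf, tg) in enumerate(zip(pairs["tf_id"], pairs["target_id"])):
        if tf not in frame.index or tg not in frame.index:
            missing[i] = True
            continue
        x = frame.loc[tf].to_numpy()
        y = frame.loc[tg].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r[i], p[i] = np.nan, np.nan
        else:
            res = spearmanr(x, y)
            r[i], p[i] = res.statistic, res.pvalue
        j[i] = jaccard_detection(x > 0, y > 0)
    out["spearman_r"] = r
    out["spearman_p"] = p
    out["jaccard"] = j
    out["missing_gene"] = missing
    with np.errstate(invalid="ignore"):
        out["kept"] = (
            ~missing
            & (np.abs(r) > r_threshold)
            & (p < p_threshold)
            & (j > j_threshold)
        )
    return out


def network_export(
    edges: pd.DataFrame, graphml_path=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kept edges (weight = |spearman_r|) plus a node table carrying any
    TF-family annotation passed through from the input; optionally writes
    GraphML."""
    kept = edges[edges["kept"]].copy()
    kept["weight"] = kept["spearman_r"].abs()
    cols = ["tf_id", "target_id", "spearman_r", "spearman_p", "jaccard", "weight"]
    edge_list = kept[cols].reset_index(drop=True)

    nodes = pd.unique(pd.concat([kept["tf_id"], kept["target_id"]], ignore_index=True))
    node_table = pd.DataFrame({"node_id": nodes})
    node_table["is_tf"] = node_table["node_id"].isin(kept["tf_id"])
    if "tf_family" in kept.columns:
        fam = kept.set_index("tf_id")["tf_family"]
        fam = fam[~fam.index.duplicated()]
        node_table["tf_family"] = node_table["node_id"].map(fam).fillna("")

    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph()
        for _, row in node_table.iterrows():
            g.add_node(row["node_id"], **row.drop("node_id").to_dict())
        for _, row in edge_list.iterrows():
            g.add_edge(
                row["tf_id"],
                row["target_id"],
                weight=float(row["weight"]),
                spearman_r=float(row["spearman_r"]),
            )
        nx.write_graphml(g, graphml_path)
    return edge_list, node_table
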