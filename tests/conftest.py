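import warnings

import numpy as np
import pandas as pd
import pytest

import trascope as ts


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated dataset shared across read-only tests."""
    return ts.simulate_dataset(ts.SimConfig(seed=1))


@pytest.fixture(scope="session")
def filtered(default_dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, report = ts.apply_qc(default_dataset.matrix, default_dataset.qc)
    return matrix, report


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 cells with hand-set TPM values."""
    values = np.array(
        [
            [10.0, 0.0, 5.0, 1.0],
            [0.0, 2.0, 0.0, 0.0],
            [90.0, 98.0, 95.0, 99.0],
        ]
    )
    return ts.ExpressionMatrix(
        values, pd.Index(["g1", "g2", "g3"]), pd.Index(["c1", "c2", "c3", "c4"])
    )


def make_annotation(rows):
    """rows: (gene_id, chrom, start, end, aire_class[, fezf2])"""
    recs = []
    for r in rows:
        gene_id, chrom, start, end, aire = r[:5]
        fez = r[5] if len(r) > 5 else False
        recs.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+",
                "is_mito": False,
                "aire_class": aire,
                "fezf2_induced": fez,
            }
        )
    frame = pd.DataFrame(recs).set_index("gene_id")
    return ts.GeneAnnotation(frame)
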