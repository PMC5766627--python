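"""Generate a synthetic mTEC single-cell dataset with planted ground truth.

The generator plants three maturation stages (jTEC, mTEChi, mTEClo), TRA
categories with mosaic activation, genomic microclusters of co-activated
Aire-dependent genes, and a handful of cells engineered to fail quality
control.
"""

import trascope as ts

ds = ts.simulate_dataset(ts.SimConfig(seed=1))

print(f"matrix: {ds.matrix.n_genes} genes x {ds.matrix.n_cells} cells (TPM)")
print(ds.truth.cell_table["population"].value_counts().to_string())
print("\nplanted QC failures:")
print(ds.truth.cell_table.query("fail_mode != 'none'")["fail_mode"].to_string())
print("\nTRA classes:")
print(ds.annotation.frame["aire_class"].value_counts().to_string())
n_block = (ds.truth.gene_table["microcluster_id"] >= 0).sum()
print(f"\n{n_block} Aire-dependent genes sit in co-activated genomic microclusters.")
# Write to disk in the pipeline's standard formats:
#   ts.write_dataset(ds, "out_dir/")
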