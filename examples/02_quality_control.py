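"""Apply the cell and gene quality filters.

Cells failing any of the three criteria (fewer than 1000 detected genes,
fewer than 500,000 exon-mapped reads, more than 20% mitochondrial reads)
are excluded; genes must then reach 5 TPM in at least 5 surviving cells.
"""

import trascope as ts

ds = ts.simulate_dataset(ts.SimConfig(seed=1))
matrix, report = ts.apply_qc(ds.matrix, ds.qc)

print(report.summary())
failed = report.cell_table[~report.cell_table["passed"]]
print("\nfailed cells and the criteria they failed:")
print(failed["reasons"].to_string())
print(f"\nfiltered matrix: {matrix.n_genes} genes x {matrix.n_cells} cells")
# Every planted failure mode is caught; boundary values (exactly 1000 genes,
# exactly 500,000 reads, exactly 20% mito) pass, since the criteria are strict.
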