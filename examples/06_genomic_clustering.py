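"""Per-cell genomic clustering of expressed Aire-dependent TRAs.

For each cell, the nearest-neighbour base-pair distances among its
expressed Aire-dependent TRAs are compared to 1000 same-sized draws of
expressed control genes (a KL-matched set of non-TRA genes).  Pooled per
subpopulation, a Mann-Whitney test compares the distance distributions and
KL(observed || background) - KLgen - KLsamp quantifies clustering strength.
"""

import trascope as ts

ds = ts.simulate_dataset(ts.SimConfig(seed=1))
matrix, _ = ts.apply_qc(ds.matrix, ds.qc)
labels = ds.truth.populations.loc[matrix.cell_ids]

annotation = ds.annotation
spec = ts.DistanceHistogramSpec()
rng = ts.seeded_rng(3)

targets = annotation.tra_subset("aire_dependent").intersection(matrix.gene_ids)
pool = ts.control_candidate_pool(annotation, matrix.gene_ids)
control = ts.build_control_set(targets, pool, annotation, spec, rng=rng)
print(f"control set: {len(control.control_ids)} genes, residual KLgen = "
      f"{control.kl_gen:.3f} after {control.n_accepted} accepted swaps")

for pop in ts.SUBPOPULATIONS:
    res = ts.clustering_statistic(
        matrix, labels, pop, targets, control, annotation, spec,
        n_resamples=1000, rng=rng,
    )
    print(f"{pop:7s} cells used {res.n_cells_used:3d}  "
          f"KL {res.kl:6.3f}  adjusted {res.kl_adjusted:+.3f}  "
          f"MWW p {res.mww_p:.2e}")
# jTEC (no co-activation) stays near zero; the mature stages, where
# microcluster blocks switch on together, show a strong positive signal.
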