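# trascope

Single-cell analysis of promiscuous tissue-restricted antigen (TRA)
expression along the maturation of medullary thymic epithelial cells
(mTECs).

mTECs delete autoreactive thymocytes by ectopically expressing thousands
of TRAs — genes normally confined to peripheral tissues — each in only a
small fraction of cells, many under the control of the transcriptional
regulator Aire. `trascope` is a tested, reusable implementation of the
analysis pipeline for this setting, aimed at computational immunologists
working with plate-based single-cell RNA-seq of thymic epithelium:

- **quality control**: cell filters (detected genes, exon-mapped reads,
  mitochondrial fraction) and the 5-TPM/5-cell gene filter;
- **population structure**: PCA on log2(TPM+1), selection of genes with
  |loading| > 0.02 on PC2/PC3, Monti-style consensus clustering (70% cell
  and gene resampling) into the three maturation stages jTEC → mTEChi →
  mTEClo, named by marker expression (Pdpn/Ccl21, Aire);
- **differential expression**: per-gene likelihood-ratio test of a
  stage-means linear model against an intercept model,
  n·ln(RSS₀/RSS₁) ~ χ²(k−1), Benjamini–Hochberg FDR, calls at q < 0.05
  and |log2FC| > 1;
- **TRA statistics**: expression frequency vs level by Aire class
  (Aire-dependent / -enhanced / -unaffected, plus Fezf2-induced),
  gene-accumulation curves over random cell orders, repertoire overlap
  across stages, per-cell TRA load;
- **genomic clustering**: the per-cell nearest-neighbour distance
  statistic for expressed TRAs against a KL-matched control gene set —
  MWW p-value plus KL(observed‖background) − KLgen − KLsamp;
- **TF network**: co-expression filtering of candidate TF→target pairs
  (Spearman |r| > 0.3, p < 0.005, Jaccard j > 0.3);
- **synthetic data**: a generator planting all of the above structure
  (stages, markers, mosaic TRA activation, co-activated genomic
  microclusters, library-size and dropout noise, QC failures) with a full
  ground-truth record for recovery tests.

The scientific core, the genomic-clustering statistic, works per cell: for
each expressed TRA of a subset, the base-pair distance to its nearest
expressed TRA is compared with distances among equally many expressed
control genes, resampled 1000 times per cell. The control set is chosen to
minimise the Kullback–Leibler divergence of its annotation-level distance
distribution from the target's (residual: KLgen), and the reported effect
subtracts both KLgen and the estimator's measured small-sample bias
(KLsamp). Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
import trascope as ts

ds = ts.simulate_dataset(ts.SimConfig(seed=1))     # 2000 genes x 306 cells
matrix, report = ts.apply_qc(ds.matrix, ds.qc)     # -> 1875 genes x 299 cells

pca = ts.run_pca(matrix)
selected = ts.select_loading_genes(pca)            # 284 genes on PC2/PC3
consensus = ts.consensus_cluster(matrix.subset_genes(selected),
                                 n_resamples=500, rng=ts.seeded_rng(5))
print({k: round(r.stability, 3) for k, r in consensus.items()})
# {2: 0.933, 3: 0.945, 4: 0.81, 5: 0.733, 6: 0.643}   -> k = 3 most stable
labels = ts.label_clusters(consensus[3].assignments, matrix)
print(labels.value_counts().to_dict())
# {'mTEChi': 129, 'mTEClo': 86, 'jTEC': 84}  (100% agreement with truth)

targets = ds.annotation.tra_subset("aire_dependent").intersection(matrix.gene_ids)
pool = ts.control_candidate_pool(ds.annotation, matrix.gene_ids)
control = ts.build_control_set(targets, pool, ds.annotation, rng=ts.seeded_rng(3))
res = ts.clustering_statistic(matrix, labels, "mTEChi", targets, control,
                              ds.annotation, n_resamples=1000, rng=ts.seeded_rng(3))
print(round(res.kl_adjusted, 3), f"{res.mww_p:.1e}")
# 1.396 5.0e-75   -> strong genomic clustering of Aire-dependent TRAs in mTEChi
```

The adjusted KL near zero in jTEC (−0.02 on the same run) against ≈ 1.4 in
mTEChi reproduces the qualitative finding the statistic was designed for:
co-expression of genomically adjacent Aire-dependent TRAs switches on
during the jTEC→mTEC transition.

Narrative walk-throughs of each capability live in `examples/` (run them
as `python examples/03_population_structure.py`). The same pipeline is
scriptable from a shell:

```bash
trascope simulate --seed 1 --out sim/
trascope qc --matrix sim/matrix.mtx --genes sim/genes.tsv --cells sim/cells.tsv \
            --qc sim/qc.tsv --out qc/
trascope cluster --matrix qc/filtered.mtx --genes qc/genes.tsv --cells qc/cells.tsv \
            --qc sim/qc.tsv --out cluster/
trascope de --matrix qc/filtered.mtx --genes qc/genes.tsv --cells qc/cells.tsv \
            --labels cluster/assignments.tsv --out de.tsv
trascope genoclust --matrix qc/filtered.mtx --genes qc/genes.tsv --cells qc/cells.tsv \
            --labels cluster/assignments.tsv --annotation sim/annotation.bed \
            --tra-classes sim/tra_classes.tsv --subset aire_dependent --out genoclust/
```

Every run writes a `provenance.json` recording the command, configuration,
seed and input checksums.

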