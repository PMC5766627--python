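"""Co-expression filtering of candidate TF-target pairs.

Each candidate pair is scored by Spearman correlation of TPM across cells
and by the Jaccard index of binarized detection; pairs passing |r| > 0.3,
p < 0.005 and j > 0.3 form the regulatory network.
"""

import trascope as ts

ds = ts.simulate_dataset(ts.SimConfig(seed=1))
matrix, _ = ts.apply_qc(ds.matrix, ds.qc)

scored = ts.score_pairs(matrix, ds.tf_pairs)
edges, nodes = ts.network_export(scored)

kept = scored.groupby("label")["kept"].mean()
print(f"kept {len(edges)} of {len(scored)} candidate pairs")
print(f"planted true pairs kept: {kept.get('true', 0):.0%}; "
      f"decoys kept: {kept.get('decoy', 0):.0%}")
print("\nstrongest edges:")
print(edges.nlargest(5, "weight")[["tf_id", "target_id", "spearman_r", "jaccard"]]
      .to_string(index=False))
# The planted pairs link a marker transcription factor to co-regulated
# markers of the same maturation stage; decoys fail the correlation filter.
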