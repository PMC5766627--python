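"""Run configuration: every threshold and seed used by the pipeline.

Defaults equal the study's stated analysis parameters (QC cut-offs, the
|loading| > 0.02 gene selection, 70% / 2000-event consensus resampling,
q < 0.05 and |log2FC| > 1 DE calls, 1000 background resamples per cell for
the genomic-clustering statistic, and the |r| > 0.3, p < 0.005, j > 0.3
network filters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0

    # cell QC ("fewer than"/"more than" are strict, so boundaries pass)
    min_genes: int = 1000
    min_reads: int = 500_000
    max_mito: float = 0.20

    # gene filter (TPM >= min_tpm in >= min_cells cells)
    min_tpm: float = 5.0
    min_cells: int = 5

    # PCA / gene selection
    n_components: int = 10
    loading_components: tuple[int, ...] = (2, 3)
    loading_threshold: float = 0.02

    # consensus clustering
    k: int = 3
    k_min: int = 2
    k_max: int = 6
    n_consensus_resamples: int = 2000
    cell_frac: float = 0.7
    gene_frac: float = 0.7
    jtec_markers: tuple[str, ...] = ("Pdpn", "Ccl21")
    maturation_markers: tuple[str, ...] = ("Aire",)

    # differential expression
    de_q_threshold: float = 0.05
    de_lfc_threshold: float = 1.0

    # TRA metrics
    n_orders: int = 100
    detection_min_cells: int = 1

    # genomic clustering statistic
    n_background_resamples: int = 1000
    hist_n_bins: int = 30
    hist_min_bp: float = 1e3
    hist_max_bp: float = 1e8
    hist_pseudocount: float = 0.5
    control_max_proposals: int = 10_000
    control_tol: float = 1e-3

    # TF network
    r_threshold: float = 0.3
    p_threshold: float = 0.005
    j_threshold: float = 0.3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                val = raw[f.name]
                if isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
        return cls(**kwargs)
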