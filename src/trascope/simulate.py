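"""Synthetic single-cell dataset generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes for a
medullary thymic epithelial cell (mTEC) population:

* three maturation stages (jTEC, mTEChi, mTEClo), each with its own set of
  up-shifted marker genes (including the canonical jTEC markers Pdpn and
  Ccl21, Aire for mTEChi and Krt10 for mTEClo);
* tissue-restricted antigen (TRA) categories with mosaic, low-frequency
  activation — Aire-dependent TRAs fire in ~2% of cells but at the highest
  expression level, Aire-enhanced / -unaffected TRAs more often at lower
  levels;
* genomic microclusters: blocks of Aire-dependent TRAs packed within a
  short chromosomal window that switch on together (one Bernoulli per block
  per cell) in the mature stages only, mimicking activation of contiguous
  stretches of chromatin;
* library-size variation, negative-binomial counting noise with a logistic
  dropout layer acting on expected counts (so shallow cells detect fewer
  genes and cell size dominates the leading principal component, as in real
  data), optional batch shifts, and a handful of planted cells that fail
  quality control.

Counts are converted to TPM (columns sum to 1e6) and per-cell QC statistics
are derived from the realized counts.  Every planted parameter is recorded
in a :class:`SimTruth` for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .types import ExpressionMatrix, GeneAnnotation, SUBPOPULATIONS, as_rng

#: special marker gene names guaranteed to exist in every simulated dataset
NAMED_MARKERS = {
    "jTEC": ("Pdpn", "Ccl21"),
    "mTEChi": ("Aire",),
    "mTEClo": ("Krt10",),
}

_FAIL_MODES = ("low_reads", "few_genes", "high_mito")


@dataclass
class SimConfig:
    """All planted parameters of a synthetic dataset.

    Defaults describe a scaled-down study: 300 analysable cells in
    proportions 28/43/29% across jTEC / mTEChi / mTEClo, 2000 genes of which
    150 per Aire class are TRAs, 12 microclusters of 6 Aire-dependent genes
    within 50 kb, Aire-dependent activation frequency 0.02 (versus 0.3 for
    the other TRA classes) with an 8-fold expression-level premium, and
    block co-activation of microclusters only in the mature stages at a
    rate keeping overall Aire-dependent detection in the observed 1-3%
    per-cell range.
    """

    seed: int = 0

    # genome
    n_chroms: int = 5
    chrom_length: int = 100_000_000
    n_genes: int = 2000
    n_mito: int = 8
    mito_chrom_length: int = 16_299

    # TRA structure
    n_aire_dependent: int = 150
    n_aire_enhanced: int = 150
    n_aire_unaffected: int = 150
    n_fezf2: int = 40  # flagged among the Aire-unaffected TRAs
    n_microclusters: int = 12
    microcluster_genes: int = 3
    microcluster_span: int = 50_000

    # populations
    pop_sizes: dict = field(
        default_factory=lambda: {"jTEC": 84, "mTEChi": 129, "mTEClo": 87}
    )
    n_markers_per_pop: int = 40
    marker_log2_shift: float = 3.0

    # activation / expression levels
    activation_freq: dict = field(
        default_factory=lambda: {
            "AIRE_DEPENDENT": 0.02,
            "AIRE_ENHANCED": 0.3,
            "AIRE_UNAFFECTED": 0.3,
        }
    )
    level_mult: dict = field(
        default_factory=lambda: {
            "AIRE_DEPENDENT": 8.0,
            "AIRE_ENHANCED": 3.0,
            "AIRE_UNAFFECTED": 1.5,
            "NON_TRA": 1.0,
        }
    )
    fezf2_level_mult: float = 2.0
    coactivation: dict = field(
        default_factory=lambda: {"jTEC": 0.0, "mTEChi": 0.05, "mTEClo": 0.04}
    )

    # noise model
    base_log_mean: float = np.log(5.0)
    base_log_sigma: float = 2.0
    marker_base_log_mean: float = np.log(20.0)
    marker_base_log_sigma: float = 0.5
    libsize_mean_reads: float = 3.0e6
    libsize_sigma: float = 0.6
    nb_dispersion: float = 0.2  # var = mu + phi * mu^2
    dropout_midpoint_counts: float = 30.0
    dropout_slope: float = 2.0
    mito_fraction_target: float = 0.04

    # batch structure (additive log2 shift; default off — the study found no
    # batch expression biases)
    n_batches: int = 3
    batch_log2_shift: float = 0.0

    # planted QC failures (extra cells on top of pop_sizes)
    n_failing_cells: int = 6

    def validate(self) -> None:
        if any(n < 1 for n in self.pop_sizes.values()):
            raise ValueError("population sizes must be >= 1")
        for name, f in self.activation_freq.items():
            if not 0 <= f <= 1:
                raise ValueError(f"activation frequency for {name} outside [0, 1]")
        for name, c in self.coactivation.items():
            if not 0 <= c <= 1:
                raise ValueError(f"coactivation for {name} outside [0, 1]")
        n_tra = self.n_aire_dependent + self.n_aire_enhanced + self.n_aire_unaffected
        n_special = n_tra + self.n_mito + 3 * self.n_markers_per_pop
        if n_special > self.n_genes:
            raise ValueError("TRA + mito + marker genes exceed n_genes")
        if self.n_microclusters * self.microcluster_genes > self.n_aire_dependent:
            raise ValueError("microcluster genes must fit inside the Aire-dependent set")
        if self.n_fezf2 > self.n_aire_unaffected:
            raise ValueError("n_fezf2 exceeds the Aire-unaffected count")
        # coarse packing feasibility: ~1 kb per gene body plus elbow room
        autosomal = self.n_genes - self.n_mito
        if autosomal * 2000 > self.n_chroms * self.chrom_length:
            raise ValueError("gene count infeasible for the configured genome size")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    cell_table: pd.DataFrame  # index cell_id: population, batch, fail_mode
    gene_table: pd.DataFrame  # index gene_id: marker_of, microcluster_id
    activation: pd.DataFrame  # genes x cells boolean activation indicators

    @property
    def populations(self) -> pd.Series:
        return self.cell_table["population"]

    def passing_cells(self) -> pd.Index:
        return self.cell_table.index[self.cell_table["fail_mode"] == "none"]

    def markers_of(self, population: str) -> pd.Index:
        return self.gene_table.index[self.gene_table["marker_of"] == population]

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        cells = self.cell_table.copy()
        cells.index.name = "cell_id"
        cells.to_csv(out_dir / "truth_cells.tsv", sep="\t")
        genes = self.gene_table.copy()
        genes.index.name = "gene_id"
        genes.to_csv(out_dir / "truth_genes.tsv", sep="\t")
        act = self.activation
        gi, ci = np.nonzero(act.to_numpy())
        pd.DataFrame(
            {"gene_id": act.index[gi], "cell_id": act.columns[ci]}
        ).to_csv(out_dir / "truth_activation.tsv", sep="\t", index=False)


def simulate_annotation(config: SimConfig, rng) -> tuple[GeneAnnotation, pd.DataFrame]:
    """Simulate a gene annotation with planted microclusters and markers.

    Non-microcluster genes are placed uniformly at random (distinct
    midpoints per chromosome); each microcluster's genes fall within one
    ``microcluster_span`` window, so their pairwise midpoint distances are
    bounded by the span.  Returns the annotation together with a gene-level
    truth table (marker-of-population and microcluster id per gene).
    """
    config.validate()
    rng = as_rng(rng)
    n_auto = config.n_genes - config.n_mito

    gene_ids = np.array([f"g{i:05d}" for i in range(n_auto)], dtype=object)

    # role assignment by random permutation over autosomal genes
    perm = rng.permutation(n_auto)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = perm[cursor : cursor + n]
        cursor += n
        return out

    idx_dep = take(config.n_aire_dependent)
    idx_enh = take(config.n_aire_enhanced)
    idx_unaff = take(config.n_aire_unaffected)
    marker_idx = {pop: take(config.n_markers_per_pop) for pop in SUBPOPULATIONS}

    aire_class = np.full(n_auto, "NON_TRA", dtype=object)
    aire_class[idx_dep] = "AIRE_DEPENDENT"
    aire_class[idx_enh] = "AIRE_ENHANCED"
    aire_class[idx_unaff] = "AIRE_UNAFFECTED"

    fezf2 = np.zeros(n_auto, dtype=bool)
    fezf2[idx_unaff[: config.n_fezf2]] = True

    microcluster_id = np.full(n_auto, -1, dtype=int)
    cluster_members = []
    for m in range(config.n_microclusters):
        members = idx_dep[m * config.microcluster_genes : (m + 1) * config.microcluster_genes]
        microcluster_id[members] = m
        cluster_members.append(members)

    marker_of = np.full(n_auto, "none", dtype=object)
    for pop in SUBPOPULATIONS:
        marker_of[marker_idx[pop]] = pop
        names = NAMED_MARKERS[pop][: len(marker_idx[pop])]
        gene_ids[marker_idx[pop][: len(names)]] = names

    # placement
    half = 500  # genes are 1 kb bodies; midpoint == drawn position
    chrom = np.empty(n_auto, dtype=object)
    midpoint = np.empty(n_auto, dtype=np.int64)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    placed: dict[str, set] = {c: set() for c in chrom_names}

    def draw_unique(chrom_name, low, high, n):
        """Draw n distinct midpoints in [low, high) not colliding with
        previously placed genes on the chromosome."""
        out = []
        seen = placed[chrom_name]
        attempts = 0
        while len(out) < n:
            pos = int(rng.integers(low, high))
            if pos not in seen:
                seen.add(pos)
                out.append(pos)
            attempts += 1
            if attempts > 1000 * n + 1000:
                raise ValueError("could not place genes without midpoint collisions")
        return out

    free = np.ones(n_auto, dtype=bool)
    for m, members in enumerate(cluster_members):
        c = chrom_names[int(rng.integers(config.n_chroms))]
        anchor = int(
            rng.integers(half + 1, config.chrom_length - config.microcluster_span - half - 1)
        )
        pos = draw_unique(c, anchor, anchor + config.microcluster_span - 2 * half, len(members))
        chrom[members] = c
        midpoint[members] = pos
        free[members] = False

    free_idx = np.where(free)[0]
    chrom_assign = rng.integers(0, config.n_chroms, size=len(free_idx))
    for ci, cname in enumerate(chrom_names):
        sel = free_idx[chrom_assign == ci]
        pos = draw_unique(cname, half + 1, config.chrom_length - half - 1, len(sel))
        chrom[sel] = cname
        midpoint[sel] = pos

    frames = [
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": midpoint - half,
                "end": midpoint + half,
                "strand": np.where(rng.random(n_auto) < 0.5, "+", "-"),
                "is_mito": False,
                "aire_class": aire_class,
                "fezf2_induced": fezf2,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    ]

    if config.n_mito:
        mito_ids = [f"mt-{i}" for i in range(config.n_mito)]
        mito_pos = np.sort(
            rng.choice(
                np.arange(100, config.mito_chrom_length - 100), config.n_mito, replace=False
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "chrM",
                    "start": mito_pos - 50,
                    "end": mito_pos + 50,
                    "strand": "+",
                    "is_mito": True,
                    "aire_class": "NON_TRA",
                    "fezf2_induced": False,
                },
                index=pd.Index(mito_ids, name="gene_id"),
            )
        )

    frame = pd.concat(frames)
    gene_truth = pd.DataFrame(
        {
            "marker_of": np.concatenate([marker_of, ["none"] * config.n_mito]),
            "microcluster_id": np.concatenate(
                [microcluster_id, [-1] * config.n_mito]
            ).astype(int),
        },
        index=frame.index,
    )
    return GeneAnnotation(frame), gene_truth


def simulate_expression(
    config: SimConfig, annotation: GeneAnnotation, gene_truth: pd.DataFrame, rng
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate TPM expression, per-cell QC stats and the ground truth.

    Per cell of population P: (1) each non-microcluster TRA of category cat
    activates with frequency f(cat); each microcluster draws one block-level
    Bernoulli(coactivation(P)) and falls back to per-gene activation when
    the block is silent; (2) the latent mean multiplies a per-gene baseline
    by the category level, the marker shift for P's markers and the
    activation indicator; (3) counts are negative-binomial around the
    library-scaled mean; (4) a logistic dropout in log expected counts
    zeroes low-abundance genes (deeper libraries detect more genes);
    (5) TPM = counts / column sum * 1e6.
    """
    config.validate()
    rng = as_rng(rng)
    f = annotation.frame
    gene_ids = f.index
    n_genes = len(gene_ids)

    # cells: analysable + planted failing, shuffled population labels
    pops = np.concatenate(
        [np.repeat(p, n) for p, n in config.pop_sizes.items()]
    )
    pops = pops[rng.permutation(len(pops))]
    n_fail = config.n_failing_cells
    fail_pops = rng.choice(list(config.pop_sizes), size=n_fail)
    populations = np.concatenate([pops, fail_pops])
    n_cells = len(populations)
    cell_ids = pd.Index([f"cell_{i:04d}" for i in range(n_cells)], name="cell_id")
    fail_mode = np.array(["none"] * n_cells, dtype=object)
    fail_mode[len(pops) :] = [_FAIL_MODES[i % len(_FAIL_MODES)] for i in range(n_fail)]
    batch = rng.integers(0, config.n_batches, size=n_cells)

    # per-gene baseline (relative abundance units)
    base = rng.lognormal(config.base_log_mean, config.base_log_sigma, size=n_genes)
    is_marker = (gene_truth["marker_of"] != "none").to_numpy()
    base[is_marker] = rng.lognormal(
        config.marker_base_log_mean, config.marker_base_log_sigma, size=is_marker.sum()
    )

    level = f["aire_class"].map(config.level_mult).to_numpy(dtype=float)
    level[f["fezf2_induced"].to_numpy()] *= config.fezf2_level_mult

    # activation indicators
    aire_class = f["aire_class"].to_numpy()
    is_tra = aire_class != "NON_TRA"
    freq = np.zeros(n_genes)
    for cat, fr in config.activation_freq.items():
        freq[aire_class == cat] = fr
    cluster_id = gene_truth["microcluster_id"].to_numpy()

    active = np.ones((n_genes, n_cells), dtype=bool)
    active[is_tra] = rng.random((is_tra.sum(), n_cells)) < freq[is_tra][:, None]
    coact_p = np.array([config.coactivation.get(p, 0.0) for p in populations])
    for m in range(config.n_microclusters):
        members = np.where(cluster_id == m)[0]
        if not len(members):
            continue
        block_on = rng.random(n_cells) < coact_p
        active[np.ix_(members, np.where(block_on)[0])] = True

    # latent means
    mu = (base * level)[:, None] * active
    for pop in SUBPOPULATIONS:
        markers = (gene_truth["marker_of"] == pop).to_numpy()
        cells_in = populations == pop
        mu[np.ix_(markers, cells_in)] *= 2.0 ** config.marker_log2_shift
    if config.batch_log2_shift:
        # batch 0 is the reference; later batches get an additive log2 shift
        mu *= 2.0 ** (config.batch_log2_shift * (batch > 0)[None, :].astype(float))

    # scale mitochondrial genes to the target read share
    is_mito = f["is_mito"].to_numpy()
    if is_mito.any() and config.mito_fraction_target > 0:
        t = config.mito_fraction_target
        nonmito_mass = mu[~is_mito].sum(axis=0).mean()
        mito_mass = mu[is_mito].sum(axis=0).mean()
        if mito_mass > 0:
            mu[is_mito] *= (t / (1 - t)) * nonmito_mass / mito_mass

    # library sizes (exon-mapped reads), with planted failures
    libsize = rng.lognormal(
        np.log(config.libsize_mean_reads) - config.libsize_sigma**2 / 2,
        config.libsize_sigma,
        size=n_cells,
    )
    libsize[fail_mode == "low_reads"] = 2.0e5
    libsize[fail_mode == "few_genes"] = 3.0e6  # stays above the read cut after dropout
    mito_boost = np.ones(n_cells)
    mito_boost[fail_mode == "high_mito"] = 12.0
    mu[np.ix_(is_mito, np.arange(n_cells))] *= mito_boost[None, :]

    # expected counts
    colsum = mu.sum(axis=0)
    rel = mu / colsum
    lam = rel * libsize

    phi = config.nb_dispersion
    if phi > 0:
        shape = 1.0 / phi
        gamma = rng.gamma(shape, scale=phi * lam)
        counts = rng.poisson(gamma).astype(float)
    else:
        counts = rng.poisson(lam).astype(float)

    # logistic dropout in log expected counts: deeper cells detect more;
    # midpoint 0 disables dropout entirely
    if config.dropout_midpoint_counts > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = lam / config.dropout_midpoint_counts
            p_drop = np.where(ratio > 0, 1.0 / (1.0 + ratio**config.dropout_slope), 1.0)
    else:
        p_drop = np.where(lam > 0, 0.0, 1.0)
    extra = np.where(fail_mode == "few_genes", 0.55, 0.0)
    p_drop = p_drop + (1 - p_drop) * extra[None, :]
    counts *= rng.random((n_genes, n_cells)) >= p_drop

    total = counts.sum(axis=0)
    total[total == 0] = 1.0
    tpm = counts / total * 1e6

    qc = pd.DataFrame(
        {
            "exon_mapped_reads": counts.sum(axis=0).astype(int),
            "n_detected_genes": (counts > 0).sum(axis=0).astype(int),
            "mito_fraction": counts[is_mito].sum(axis=0) / np.maximum(counts.sum(axis=0), 1),
        },
        index=cell_ids,
    )

    meta = pd.DataFrame(
        {
            "batch": [f"batch{b + 1}" for b in batch],
            "age": np.where(batch == 0, "wk2", "wk4"),
            "dataset": "simulated",
        },
        index=cell_ids,
    )
    matrix = ExpressionMatrix(tpm, gene_ids, cell_ids, meta)
    truth = SimTruth(
        cell_table=pd.DataFrame(
            {"population": populations, "batch": meta["batch"], "fail_mode": fail_mode},
            index=cell_ids,
        ),
        gene_table=gene_truth,
        activation=pd.DataFrame(active, index=gene_ids, columns=cell_ids),
    )
    return matrix, qc, truth


def simulate_tf_pairs(
    truth: SimTruth, n_true: int = 30, n_decoy: int = 30, rng=None
) -> pd.DataFrame:
    """Candidate TF-target pair list: per-population marker TF linked to
    co-regulated markers of the same population, plus random decoy pairs.

    Stands in for a motif-derived candidate list; the ``label`` column
    records which pairs are planted as true.
    """
    rng = as_rng(rng if rng is not None else 0)
    pops = [p for p in SUBPOPULATIONS if len(truth.markers_of(p)) >= 2]
    if n_true > sum(len(truth.markers_of(p)) - 1 for p in pops):
        raise ValueError("n_true exceeds the available marker genes")
    rows = []
    i = 0
    while len(rows) < n_true:
        pop = pops[i % len(pops)]
        markers = truth.markers_of(pop)
        tf = markers[0]
        targets = [m for m in markers[1:] if not any(r["target_id"] == m for r in rows)]
        if targets:
            rows.append(
                {"tf_id": tf, "target_id": targets[0], "tf_family": f"fam_{pop}", "label": "true"}
            )
        i += 1
        if i > 10 * n_true + 10:
            break

    all_genes = truth.gene_table.index.to_numpy()
    marker_of = truth.gene_table["marker_of"]
    n = 0
    guard = 0
    while n < n_decoy and guard < 100 * (n_decoy + 1):
        a, b = rng.choice(all_genes, size=2, replace=False)
        guard += 1
        if marker_of[a] != "none" and marker_of[a] == marker_of[b]:
            continue  # would be a genuinely co-regulated pair
        rows.append({"tf_id": a, "target_id": b, "tf_family": "decoy", "label": "decoy"})
        n += 1
    return pd.DataFrame(rows, columns=["tf_id", "target_id", "tf_family", "label"])


def simulate_twin_null(
    rng,
    n_pairs: int = 60,
    n_cells: int = 60,
    target_freq: float = 0.3,
    n_chroms: int = 2,
    chrom_length: int = 40_000_000,
) -> tuple[GeneAnnotation, ExpressionMatrix]:
    """Exchangeable null for the genomic-clustering statistic.

    Places ``n_pairs`` uniformly positioned control genes and, 1 bp away
    from each, a positional twin labelled as an Aire-dependent target, so
    every pairwise target distance equals the corresponding control
    distance.  Targets are expressed independently with ``target_freq``;
    controls are constitutive.  Under this construction the observed
    per-cell distances and the resampled control background are draws from
    the same law, so the Mann-Whitney p-value is uniform and the adjusted
    KL centres at zero — a calibration check of the statistic's machinery.
    """
    rng = as_rng(rng)
    pos = np.sort(rng.choice(np.arange(10_000, chrom_length), size=n_pairs, replace=False))
    chrom = rng.integers(0, n_chroms, size=n_pairs)
    rows = []
    for i in range(n_pairs):
        c = f"chr{chrom[i] + 1}"
        rows.append((f"t{i:03d}", c, int(pos[i]) + 1, int(pos[i]) + 1001, "AIRE_DEPENDENT"))
        rows.append((f"c{i:03d}", c, int(pos[i]), int(pos[i]) + 1000, "NON_TRA"))
    frame = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "aire_class"]
    ).set_index("gene_id")
    frame["strand"] = "+"
    frame["is_mito"] = False
    frame["fezf2_induced"] = False
    annotation = GeneAnnotation(
        frame[["chrom", "start", "end", "strand", "is_mito", "aire_class", "fezf2_induced"]]
    )
    ids = annotation.gene_ids
    t_mask = np.array([g.startswith("t") for g in ids])
    values = np.zeros((len(ids), n_cells))
    values[t_mask] = (rng.random((t_mask.sum(), n_cells)) < target_freq) * 100.0
    values[~t_mask] = 100.0
    matrix = ExpressionMatrix(
        values, ids, pd.Index([f"cell{j:03d}" for j in range(n_cells)])
    )
    return annotation, matrix


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: GeneAnnotation
    matrix: ExpressionMatrix
    qc: pd.DataFrame
    truth: SimTruth
    tf_pairs: pd.DataFrame


def simulate_dataset(config: SimConfig | None = None, seed=None) -> SimulatedDataset:
    """Generate a complete dataset (annotation, expression, QC, TF pairs)."""
    config = config or SimConfig()
    rng = as_rng(config.seed if seed is None else seed)
    annotation, gene_truth = simulate_annotation(config, rng)
    matrix, qc, truth = simulate_expression(config, annotation, gene_truth, rng)
    available = sum(
        max(0, len(truth.markers_of(p)) - 1) for p in SUBPOPULATIONS
    )
    n_true = min(30, available)
    tf_pairs = simulate_tf_pairs(truth, n_true=n_true, n_decoy=30, rng=rng)
    return SimulatedDataset(config, annotation, matrix, qc, truth, tf_pairs)


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write a dataset as matrix.mtx + sidecars, annotation, QC, pairs, truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tio.write_expression_mtx(ds.matrix, out_dir)
    tio.write_annotation(ds.annotation, out_dir / "annotation.bed", out_dir / "tra_classes.tsv")
    tio.write_qc_table(ds.qc, out_dir / "qc.tsv")
    tio.write_tsv(ds.tf_pairs, out_dir / "tf_pairs.tsv")
    ds.truth.write(out_dir)
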