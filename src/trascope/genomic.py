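"""Per-cell genomic clustering of expressed TRA genes.

The statistic asks whether the TRA genes a single cell expresses sit closer
together along the genome than expected.  It has four ingredients:

1. **Nearest-neighbour distances** — for a gene set, the bp distance from
   each gene's midpoint to the closest other member on the same chromosome
   (singletons on a chromosome contribute nothing).
2. **KL-matched control set** — a same-size set of non-TRA genes chosen by
   a greedy hill-climb to minimise the KL divergence between the target's
   and the control's annotation-level nearest-neighbour distance
   histograms.  The residual divergence (KLgen) is carried forward.
3. **Per-cell background** — in each cell expressing k >= 2 target genes,
   the observed distances are the nearest-neighbour distances among those k
   genes; the background resamples k of the cell's expressed control genes
   1000 times and pools their distances.
4. **Pooled comparison** — per subpopulation x TRA subset, observed and
   background distances pooled over cells are compared by a two-sided
   Mann-Whitney-Wilcoxon test, and the KL divergence of observed from
   background, minus KLgen, quantifies the clustering effect.

KL divergences are estimated on a fixed log10-spaced histogram (default 30
bins spanning 1e3..1e8 bp plus underflow/overflow) with a pseudocount, in
nats, which makes KL(P||P) exactly 0 and KLgen comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .types import ExpressionMatrix, GeneAnnotation, as_rng


@dataclass
class DistanceHistogramSpec:
    """Shared binning for every KL estimate: log10-spaced edges plus an
    underflow and an overflow bin, a per-bin pseudocount, natural log."""

    n_bins: int = 30
    min_bp: float = 1e3
    max_bp: float = 1e8
    pseudocount: float = 0.5

    @property
    def edges(self) -> np.ndarray:
        inner = np.logspace(np.log10(self.min_bp), np.log10(self.max_bp), self.n_bins + 1)
        return np.concatenate([[0.0], inner, [np.inf]])

    def probabilities(self, distances: np.ndarray, n_effective: float | None = None) -> np.ndarray:
        """Histogram probabilities with pseudocount smoothing, summing to 1.

        ``n_effective`` rescales the sample's bin frequencies to a common
        count total before the pseudocount is added; comparing two samples
        on the same effective scale keeps the estimator's small-sample bias
        from loading entirely onto the smaller sample.
        """
        distances = np.asarray(distances, dtype=float)
        if distances.size == 0:
            raise ValueError("cannot histogram an empty distance sample")
        counts, _ = np.histogram(distances, bins=self.edges)
        counts = counts.astype(float)
        if n_effective is not None and counts.sum() > 0:
            counts = counts / counts.sum() * n_effective
        counts = counts + self.pseudocount
        return counts / counts.sum()


@dataclass
class ControlSet:
    """KL-matched control genes for one TRA subset; kl_gen is the residual
    annotation-level divergence left after the hill-climb."""

    target_subset: str
    control_ids: pd.Index
    kl_gen: float
    n_proposals: int
    n_accepted: int
    objective_trace: list = field(default_factory=list)


@dataclass
class ClusteringStatResult:
    """Observed vs background nearest-neighbour distances pooled over the
    cells of one subpopulation, for one TRA subset."""

    subpopulation: str
    tra_subset: str
    n_cells_used: int
    n_cells_skipped: int
    n_cells_shortfall: int
    n_resamples: int
    observed: np.ndarray
    background: np.ndarray
    mww_p: float
    kl: float
    kl_gen: float
    kl_sampling: float
    kl_adjusted: float

    def to_dict(self) -> dict:
        return {
            "subpopulation": self.subpopulation,
            "tra_subset": self.tra_subset,
            "n_cells_used": self.n_cells_used,
            "n_cells_skipped": self.n_cells_skipped,
            "n_cells_shortfall": self.n_cells_shortfall,
            "n_resamples": self.n_resamples,
            "n_observed_distances": int(len(self.observed)),
            "n_background_distances": int(len(self.background)),
            "mww_p": self.mww_p,
            "kl": self.kl,
            "kl_gen": self.kl_gen,
            "kl_sampling": self.kl_sampling,
            "kl_adjusted": self.kl_adjusted,
        }


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nn_distances(gene_ids, annotation: GeneAnnotation) -> np.ndarray:
    """Distance from each listed gene to its closest listed neighbour.

    Distances are |midpoint difference| restricted to the same chromosome;
    genes without a same-chromosome companion contribute nothing, so the
    output length is at most the input length.
    """
    gene_ids = pd.Index(gene_ids)
    missing = gene_ids.difference(annotation.gene_ids)
    if len(missing):
        raise KeyError(f"gene id(s) absent from annotation: {missing.tolist()[:5]}")
    sub = annotation.frame.loc[gene_ids]
    mids = (sub["start"] + sub["end"]) // 2
    out = []
    for _, group in mids.groupby(sub["chrom"].to_numpy()):
        if len(group) < 2:
            continue
        pos = np.sort(group.to_numpy(dtype=np.int64))
        gaps = np.diff(pos).astype(float)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        out.append(np.minimum(left, right))
    if not out:
        return np.array([], dtype=float)
    return np.concatenate(out)


# offset larger than any chromosome so chrom code + midpoint packs into one
# exactly representable float64 key
_CHROM_OFFSET = 1e9


def _pack_positions(gene_ids, annotation: GeneAnnotation) -> np.ndarray:
    """Encode (chrom, midpoint) as a single sortable float key per gene."""
    sub = annotation.frame.loc[pd.Index(gene_ids)]
    codes = pd.factorize(sub["chrom"].to_numpy())[0]
    mids = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=np.int64)
    if mids.max(initial=0) >= _CHROM_OFFSET:
        raise ValueError("midpoint exceeds the chromosome packing offset")
    return codes * _CHROM_OFFSET + mids


def _nn_rows(keys: np.ndarray) -> list[np.ndarray]:
    """Row-wise nearest-neighbour distances for packed position keys.

    ``keys`` is (n_rows, k); each row is one resample.  Returns one distance
    array per row (lengths vary: cross-chromosome neighbours are excluded).
    """
    keys = np.sort(np.asarray(keys, dtype=float), axis=1)
    chrom = np.floor(keys / _CHROM_OFFSET)
    gaps = np.diff(keys, axis=1)
    same = np.diff(chrom, axis=1) == 0
    gaps = np.where(same, gaps, np.inf)
    left = np.concatenate([np.full((keys.shape[0], 1), np.inf), gaps], axis=1)
    right = np.concatenate([gaps, np.full((keys.shape[0], 1), np.inf)], axis=1)
    d = np.minimum(left, right)
    return [row[np.isfinite(row)] for row in d]


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------

def kl_divergence(sample_a, sample_b, spec: DistanceHistogramSpec) -> float:
    """KL(a || b) in nats over the shared histogram spec.

    Both samples are smoothed on the first sample's count scale, so a small
    observed sample compared against a large pooled background is not
    penalised for its empty bins; identical samples give exactly 0.
    """
    n_a = float(np.asarray(sample_a).size)
    p = spec.probabilities(sample_a, n_effective=n_a)
    q = spec.probabilities(sample_b, n_effective=n_a)
    if np.any(q == 0):
        # only possible with pseudocount 0; empty-bin contributions where
        # p == 0 are 0 by convention, p > 0 against q == 0 is infinite
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
        return float(terms.sum())
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


# ---------------------------------------------------------------------------
# control set construction
# ---------------------------------------------------------------------------

def build_control_set(
    target_ids,
    candidate_pool,
    annotation: GeneAnnotation,
    spec: DistanceHistogramSpec | None = None,
    max_proposals: int = 10_000,
    tol: float = 1e-3,
    rng=None,
    target_subset: str = "",
) -> ControlSet:
    """Greedy hill-climb for a control set matching the target's
    annotation-level nearest-neighbour distance distribution.

    Starts from a uniform random draw of |target| candidates and repeatedly
    proposes swapping one member for one non-member, accepting a swap iff
    the KL divergence of the target histogram from the control histogram
    strictly decreases.  Stops after ``max_proposals`` proposals or when the
    objective drops to ``tol``; the final objective is KLgen.
    """
    spec = spec or DistanceHistogramSpec()
    rng = as_rng(rng if rng is not None else 0)
    target_ids = pd.Index(target_ids)
    pool = pd.Index(candidate_pool).difference(target_ids)
    if len(pool) < len(target_ids):
        raise ValueError(
            f"candidate pool ({len(pool)} genes outside the target) is smaller "
            f"than the target set ({len(target_ids)})"
        )
    target_d = nn_distances(target_ids, annotation)
    n_t = float(target_d.size)
    target_p = spec.probabilities(target_d, n_effective=n_t)

    pool_arr = pool.to_numpy()
    keys = dict(zip(pool_arr, _pack_positions(pool, annotation)))

    member_idx = rng.choice(len(pool_arr), size=len(target_ids), replace=False)
    in_set = np.zeros(len(pool_arr), dtype=bool)
    in_set[member_idx] = True

    def objective(mask) -> float:
        ids = pool_arr[mask]
        d = _nn_rows(np.array([[keys[g] for g in ids]]))[0]
        if d.size == 0:
            return float("inf")
        q = np.histogram(d, bins=spec.edges)[0].astype(float)
        q = q / q.sum() * n_t + spec.pseudocount
        q = q / q.sum()
        masked = target_p > 0
        return float((target_p[masked] * np.log(target_p[masked] / q[masked])).sum())

    current = objective(in_set)
    trace = [current]
    n_accepted = 0
    n_proposals = 0
    members = np.where(in_set)[0]
    non_members = np.where(~in_set)[0]
    while n_proposals < max_proposals and current > tol and len(non_members):
        n_proposals += 1
        i = int(rng.integers(len(members)))
        j = int(rng.integers(len(non_members)))
        gi, gj = members[i], non_members[j]
        in_set[gi], in_set[gj] = False, True
        proposed = objective(in_set)
        if proposed < current:
            current = proposed
            members[i], non_members[j] = gj, gi
            n_accepted += 1
            trace.append(current)
        else:
            in_set[gi], in_set[gj] = True, False

    return ControlSet(
        target_subset=target_subset,
        control_ids=pd.Index(np.sort(pool_arr[in_set])),
        kl_gen=current,
        n_proposals=n_proposals,
        n_accepted=n_accepted,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# per-cell background and the pooled statistic
# ---------------------------------------------------------------------------

def cell_background(
    cell_id,
    target_ids,
    control: ControlSet,
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    n_resamples: int = 1000,
    rng=None,
) -> tuple[np.ndarray, list[np.ndarray], bool]:
    """Observed and resampled background distances for one cell.

    k is the number of target genes detected in the cell; cells with k < 2
    are skipped (both outputs empty).  Each of the ``n_resamples`` draws
    takes k expressed control genes without replacement; when fewer than k
    control genes are expressed, all are drawn and the shortfall is flagged
    (third return value).  The background is returned as one distance array
    per resample so that each resample can also serve as a same-sized null
    draw when estimating the KL estimator's sampling bias.
    """
    rng = as_rng(rng if rng is not None else 0)
    col = matrix.values[:, matrix.cell_ids.get_loc(cell_id)]
    detected = pd.Index(matrix.gene_ids[col > 0])

    expressed_targets = pd.Index(target_ids).intersection(detected)
    k = len(expressed_targets)
    if k < 2:
        return np.array([]), [], False
    observed = nn_distances(expressed_targets, annotation)

    expressed_controls = control.control_ids.intersection(detected)
    m = len(expressed_controls)
    shortfall = m < k
    if m < 2:
        return observed, [], True
    draw = min(k, m)
    ctrl_keys = _pack_positions(expressed_controls, annotation)
    idx = np.array(
        [rng.choice(m, size=draw, replace=False) for _ in range(n_resamples)]
    )
    rows = _nn_rows(ctrl_keys[idx])
    return observed, rows, shortfall


def clustering_statistic(
    matrix: ExpressionMatrix,
    assignments: pd.Series,
    subpopulation: str,
    target_ids,
    control: ControlSet,
    annotation: GeneAnnotation,
    spec: DistanceHistogramSpec | None = None,
    n_resamples: int = 1000,
    rng=None,
    tra_subset: str = "",
) -> ClusteringStatResult:
    """Pooled genomic-clustering statistic for one subpopulation x subset.

    Observed and background distances are pooled over the subpopulation's
    non-skipped cells; the pooled distributions are compared by a two-sided
    MWW test, and kl_adjusted = KL(observed || background) - KLgen -
    KLsamp, which may be negative and is reported as computed.  KLsamp is
    the mean KL of a single pooled background resample (the same sample
    size as the observed pool) against the full background: the sampling
    bias a null sample of this size incurs under the plug-in histogram
    estimator.  Subtracting it, in the same spirit as subtracting KLgen,
    centres the statistic at zero for an unclustered target.
    """
    spec = spec or DistanceHistogramSpec()
    rng = as_rng(rng if rng is not None else 0)
    labels = assignments.loc[matrix.cell_ids]
    cells = labels.index[labels == subpopulation]
    if len(cells) < 2:
        raise ValueError(
            f"subpopulation {subpopulation!r} has fewer than 2 labelled cells"
        )
    observed, per_resample = [], []
    n_used = n_skipped = n_shortfall = 0
    for cell_id in cells:
        obs, bg_rows, short = cell_background(
            cell_id, target_ids, control, matrix, annotation,
            n_resamples=n_resamples, rng=rng,
        )
        if obs.size == 0:
            n_skipped += 1
            continue
        n_used += 1
        n_shortfall += bool(short)
        observed.append(obs)
        if bg_rows:
            per_resample.append(bg_rows)
    if n_used < 2:
        raise ValueError(
            f"fewer than 2 usable cells in {subpopulation!r} for subset {tra_subset!r}"
        )
    if n_shortfall:
        warnings.warn(
            f"{n_shortfall} cell(s) had fewer expressed control genes than "
            f"targets; all expressed controls were drawn"
        )
    observed = np.concatenate(observed)
    # pool across cells within each resample, then across resamples
    resample_pools = [
        np.concatenate([rows[r] for rows in per_resample])
        for r in range(n_resamples)
    ]
    background = np.concatenate(resample_pools)
    mww_p = float(mannwhitneyu(observed, background, alternative="two-sided").pvalue)
    kl = kl_divergence(observed, background, spec)
    n_bias = min(100, n_resamples)
    kl_sampling = float(
        np.mean(
            [
                kl_divergence(resample_pools[r], background, spec)
                for r in range(n_bias)
                if resample_pools[r].size
            ]
        )
    )
    return ClusteringStatResult(
        subpopulation=subpopulation,
        tra_subset=tra_subset or control.target_subset,
        n_cells_used=n_used,
        n_cells_skipped=n_skipped,
        n_cells_shortfall=n_shortfall,
        n_resamples=n_resamples,
        observed=observed,
        background=background,
        mww_p=mww_p,
        kl=kl,
        kl_gen=control.kl_gen,
        kl_sampling=kl_sampling,
        kl_adjusted=kl - control.kl_gen - kl_sampling,
    )


def control_candidate_pool(
    annotation: GeneAnnotation, kept_genes, exclude_all_tra: bool = True
) -> pd.Index:
    """Default candidate pool: genes passing the expression filter, with all
    TRA-classified genes (or only the target subset, if ``exclude_all_tra``
    is False the caller removes the target itself) excluded."""
    kept = pd.Index(kept_genes).intersection(annotation.gene_ids)
    if exclude_all_tra:
        kept = kept.difference(annotation.tra_ids())
    return kept
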