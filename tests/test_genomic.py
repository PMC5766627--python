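import numpy as np
import pandas as pd
import pytest

import trascope as ts
from conftest import make_annotation
from trascope.genomic import _nn_rows, _pack_positions


def uniform_annotation(rng, n=60, n_chroms=3, length=40_000_000, aire="NON_TRA"):
    rows = []
    for i in range(n):
        c = f"chr{rng.integers(n_chroms) + 1}"
        start = int(rng.integers(1000, length))
        rows.append((f"g{i:03d}", c, start, start + 1000, aire))
    return make_annotation(rows)


def brute_force_nn(gene_ids, annotation):
    mids = annotation.midpoints.loc[list(gene_ids)]
    chroms = annotation.frame.loc[list(gene_ids), "chrom"]
    out = []
    for g in gene_ids:
        best = np.inf
        for h in gene_ids:
            if g == h or chroms[g] != chroms[h]:
                continue
            best = min(best, abs(int(mids[g]) - int(mids[h])))
        if np.isfinite(best):
            out.append(best)
    return np.array(sorted(out), dtype=float)


class TestNNDistances:
    def test_hand_case_three_midpoints(self):
        ann = make_annotation(
            [
                ("a", "chr1", 50, 150, "NON_TRA"),   # midpoint 100
                ("b", "chr1", 150, 250, "NON_TRA"),  # midpoint 200
                ("c", "chr1", 450, 550, "NON_TRA"),  # midpoint 500
            ]
        )
        d = sorted(ts.nn_distances(["a", "b", "c"], ann))
        assert d == [100, 100, 300]

    def test_singleton_on_chromosome_contributes_nothing(self):
        ann = make_annotation(
            [("a", "chr1", 0, 100, "NON_TRA"), ("b", "chr2", 0, 100, "NON_TRA")]
        )
        assert ts.nn_distances(["a", "b"], ann).size == 0

    def test_unknown_id_rejected(self):
        ann = make_annotation([("a", "chr1", 0, 100, "NON_TRA")])
        with pytest.raises(KeyError, match="zz"):
            ts.nn_distances(["zz"], ann)

    def test_matches_all_pairs_brute_force_on_random_annotations(self):
        """Oracle equivalence over 20 random annotations of <= 200 genes."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            ann = uniform_annotation(rng, n=n)
            ids = ann.gene_ids[rng.random(n) < 0.7]
            got = np.sort(ts.nn_distances(ids, ann))
            assert np.array_equal(got, brute_force_nn(ids, ann))

    def test_vectorised_rows_agree_with_scalar_path(self):
        rng = np.random.default_rng(1)
        ann = uniform_annotation(rng, n=50)
        keys = _pack_positions(ann.gene_ids, ann)
        for _ in range(10):
            pick = rng.choice(50, size=8, replace=False)
            row = _nn_rows(keys[pick][None, :])[0]
            assert np.array_equal(
                np.sort(row), np.sort(ts.nn_distances(ann.gene_ids[pick], ann))
            )


class TestKL:
    def test_identical_samples_give_exact_zero(self):
        spec = ts.DistanceHistogramSpec()
        sample = np.array([1e3, 5e4, 2e6, 2e6, 9e7])
        assert ts.kl_divergence(sample, sample, spec) == 0.0

    def test_two_bin_hand_value(self):
        """p_a=(0.5,0.5), p_b=(0.25,0.75), pseudocount off:
        KL = 0.5 ln2 + 0.5 ln(2/3) = 0.14384... nats."""
        spec = ts.DistanceHistogramSpec(n_bins=1, min_bp=10.0, max_bp=100.0, pseudocount=0.0)
        # bins: [0,10), [10,100), [100,inf) -- use the first two
        a = np.array([5.0, 5.0, 50.0, 50.0])
        b = np.array([5.0, 50.0, 50.0, 50.0])
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert ts.kl_divergence(a, b, spec) == pytest.approx(expected, abs=1e-6)

    def test_non_negative_on_random_sample_pairs(self):
        rng = np.random.default_rng(2)
        spec = ts.DistanceHistogramSpec()
        for _ in range(1000):
            a = rng.lognormal(10, 2, size=rng.integers(2, 40))
            b = rng.lognormal(11, 2, size=rng.integers(2, 40))
            assert ts.kl_divergence(a, b, spec) >= 0

    def test_empty_sample_rejected(self):
        spec = ts.DistanceHistogramSpec()
        with pytest.raises(ValueError, match="empty"):
            ts.kl_divergence(np.array([]), np.array([1.0]), spec)


def twin_annotation(rng, n_pairs=40, n_chroms=2, length=40_000_000):
    """Target genes placed 1 bp from positional control twins: all pairwise
    target distances equal the corresponding control distances."""
    pos = np.sort(rng.choice(np.arange(10_000, length), size=n_pairs, replace=False))
    chrom = rng.integers(0, n_chroms, size=n_pairs)
    rows = []
    for i in range(n_pairs):
        c = f"chr{chrom[i] + 1}"
        rows.append((f"t{i:03d}", c, int(pos[i]) + 1, int(pos[i]) + 1001, "AIRE_DEPENDENT"))
        rows.append((f"c{i:03d}", c, int(pos[i]), int(pos[i]) + 1000, "NON_TRA"))
    return make_annotation(rows)


class TestControlSet:
    def test_planted_twin_solution_is_found(self):
        rng = ts.seeded_rng(0)
        ann = twin_annotation(rng)
        targets = ann.tra_subset("aire_dependent")
        decoys = uniform_annotation(np.random.default_rng(5), n=60)
        # pool = twins plus unrelated decoy positions merged into one annotation
        frame = pd.concat([ann.frame, decoys.frame.add_prefix("")])
        frame = frame[~frame.index.duplicated()]
        merged = ts.GeneAnnotation(frame)
        pool = merged.frame.index[merged.frame["aire_class"] == "NON_TRA"]
        ctrl = ts.build_control_set(targets, pool, merged, rng=ts.seeded_rng(1))
        assert ctrl.kl_gen <= 0.01

    def test_objective_trace_is_non_increasing_and_deterministic(self):
        rng = np.random.default_rng(3)
        ann = uniform_annotation(rng, n=120)
        targets = ann.gene_ids[:30]
        pool = ann.gene_ids[30:]
        c1 = ts.build_control_set(targets, pool, ann, max_proposals=500, rng=ts.seeded_rng(2))
        c2 = ts.build_control_set(targets, pool, ann, max_proposals=500, rng=ts.seeded_rng(2))
        trace = np.array(c1.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert list(c1.control_ids) == list(c2.control_ids)
        assert len(c1.control_ids) == len(targets)
        assert len(set(c1.control_ids) & set(targets)) == 0

    def test_pool_too_small_rejected(self):
        ann = uniform_annotation(np.random.default_rng(4), n=10)
        with pytest.raises(ValueError, match="smaller"):
            ts.build_control_set(ann.gene_ids[:8], ann.gene_ids[6:], ann)


def twin_matrix(ann, rng, n_cells=40, f=0.4):
    ids = ann.gene_ids
    t_mask = np.array([g.startswith("t") for g in ids])
    vals = np.zeros((len(ids), n_cells))
    vals[t_mask] = (rng.random((t_mask.sum(), n_cells)) < f) * 100.0
    vals[~t_mask] = 100.0
    return ts.ExpressionMatrix(vals, ids, pd.Index([f"cell{j}" for j in range(n_cells)]))


class TestCellBackground:
    def test_cells_with_fewer_than_two_expressed_targets_are_skipped(self):
        rng = ts.seeded_rng(0)
        ann = twin_annotation(rng, n_pairs=5)
        m = twin_matrix(ann, rng, n_cells=3, f=0.0)
        ctrl = ts.ControlSet("aire_dependent", ann.frame.index[ann.frame.aire_class == "NON_TRA"], 0.0, 0, 0)
        obs, bg, short = ts.cell_background("cell0", ann.tra_subset("aire_dependent"), ctrl, m, ann)
        assert obs.size == 0 and bg == [] and not short

    def test_twin_construction_reproduces_observed_in_a_resample(self):
        """When the expressed controls are exactly the positional twins of
        the expressed targets, a full-size resample gives identical
        distances."""
        rng = ts.seeded_rng(1)
        ann = twin_annotation(rng, n_pairs=8)
        targets = ann.tra_subset("aire_dependent")
        controls = ann.frame.index[ann.frame.aire_class == "NON_TRA"]
        # express target ti and its twin ci only, for a chosen subset
        vals = np.zeros((len(ann.gene_ids), 1))
        chosen = [0, 2, 5, 7]
        for i in chosen:
            vals[ann.gene_ids.get_loc(f"t{i:03d}")] = 50.0
            vals[ann.gene_ids.get_loc(f"c{i:03d}")] = 50.0
        m = ts.ExpressionMatrix(vals, ann.gene_ids, pd.Index(["cellA"]))
        ctrl = ts.ControlSet("aire_dependent", controls, 0.0, 0, 0)
        obs, bg_rows, short = ts.cell_background(
            "cellA", targets, ctrl, m, ann, n_resamples=5, rng=ts.seeded_rng(2)
        )
        assert not short
        for row in bg_rows:  # k == m, so every draw is the full twin set
            assert np.array_equal(np.sort(row), np.sort(obs))


class TestClusteringStatistic:
    def test_requires_enough_usable_cells(self):
        rng = ts.seeded_rng(0)
        ann = twin_annotation(rng, n_pairs=10)
        m = twin_matrix(ann, rng, n_cells=4, f=0.0)
        labels = pd.Series("mTEChi", index=m.cell_ids)
        ctrl = ts.ControlSet("aire_dependent", ann.frame.index[ann.frame.aire_class == "NON_TRA"], 0.0, 0, 0)
        with pytest.raises(ValueError, match="usable"):
            ts.clustering_statistic(m, labels, "mTEChi", ann.tra_subset("aire_dependent"), ctrl, ann)

    def test_exchangeable_twin_null_is_centred(self):
        """Relabelled-control construction: the statistic must sit near 0
        and the MWW must not fire."""
        rng = ts.seeded_rng(3)
        ann = twin_annotation(rng, n_pairs=50)
        m = twin_matrix(ann, rng, n_cells=50, f=0.3)
        targets = ann.tra_subset("aire_dependent")
        pool = ann.frame.index[ann.frame.aire_class == "NON_TRA"]
        ctrl = ts.build_control_set(targets, pool, ann, rng=ts.seeded_rng(4))
        assert ctrl.kl_gen <= 1e-9  # twins match exactly
        labels = pd.Series("mTEChi", index=m.cell_ids)
        res = ts.clustering_statistic(
            m, labels, "mTEChi", targets, ctrl, ann, n_resamples=300, rng=ts.seeded_rng(5)
        )
        assert abs(res.kl_adjusted) <= 0.05
        assert res.mww_p > 0.01

    def test_doubling_resamples_barely_moves_kl(self, default_dataset, filtered):
        matrix, _ = filtered
        ds = default_dataset
        ann = ds.annotation
        targets = ann.tra_subset("aire_dependent").intersection(matrix.gene_ids)
        pool = ts.control_candidate_pool(ann, matrix.gene_ids)
        ctrl = ts.build_control_set(targets, pool, ann, max_proposals=3000, rng=ts.seeded_rng(6))
        labels = ds.truth.populations.loc[matrix.cell_ids]
        kls = []
        for n in (2000, 4000):
            r = ts.clustering_statistic(
                matrix, labels, "mTEChi", targets, ctrl, ann,
                n_resamples=n, rng=ts.seeded_rng(7),
            )
            kls.append(r.kl)
        assert abs(kls[1] - kls[0]) < 0.02
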