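"""Capped-depth z-scores, sLCR detection, consistency, Venn, contrasts."""

import numpy as np
import pandas as pd
import pytest

import lcrqc as L
from lcrqc.errors import ValidationError


def _profiles(depth_matrix: np.ndarray, ids, batch_id="b1"):
    return [
        L.DepthProfile(
            sample_id=f"{batch_id}_s{c}", assay="ES", batch_id=batch_id,
            depths=pd.Series(depth_matrix[:, c], index=ids),
        )
        for c in range(depth_matrix.shape[1])
    ]


def _universe(n):
    return L.TargetIntervalSet([L.TargetInterval("chr1", 10 * i, 10 * i + 5) for i in range(n)])


class TestCapDepth:
    @pytest.mark.parametrize("depth,expected", [(35.0, 20.0), (12.3, 12.3), (20.0, 20.0)])
    def test_truncation(self, depth, expected):
        assert L.cap_depth(depth, 20.0) == expected

    def test_idempotent_on_arrays(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 100, 500)
        once = L.cap_depth(d, 20.0)
        np.testing.assert_array_equal(once, L.cap_depth(once, 20.0))


class TestBatchZscores:
    def test_single_low_interval_is_sole_slcr(self):
        uni = _universe(50)
        mat = np.full((50, 3), 25.0)
        mat[7, :] = 5.0
        table = L.batch_zscores(_profiles(mat, uni.ids), uni)
        assert table.slcr_ids == {uni.ids[7]}
        assert table.table["z"].idxmin() == uni.ids[7]

    def test_zscores_standardized_over_intervals(self, batch_ztables):
        for t in batch_ztables:
            z = t.table["z"]
            assert abs(z.mean()) < 1e-9
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_depths_above_cap(self):
        """Coverage magnitude above the cap cannot influence z-scores."""
        uni = _universe(30)
        rng = np.random.default_rng(2)
        base = rng.uniform(21, 40, (30, 4))
        base[:5, :] = rng.uniform(1, 10, (5, 4))
        inflated = base.copy()
        inflated[base > 20] *= 10
        t1 = L.batch_zscores(_profiles(base, uni.ids), uni)
        t2 = L.batch_zscores(_profiles(inflated, uni.ids), uni)
        pd.testing.assert_series_equal(t1.table["z"], t2.table["z"])

    def test_degenerate_batch_rejected(self):
        uni = _universe(10)
        mat = np.full((10, 3), 50.0)  # all capped to 20 -> zero variance
        with pytest.raises(ValidationError, match="degenerate"):
            L.batch_zscores(_profiles(mat, uni.ids), uni)

    def test_single_sample_batch_rejected(self):
        uni = _universe(10)
        with pytest.raises(ValidationError, match=">=2"):
            L.batch_zscores(_profiles(np.ones((10, 1)), uni.ids), uni)

    def test_planted_systematic_dropout_recovered(self, batch_cohort, batch_ztables):
        """200 planted intervals per batch at severity 0.05 recovered
        with sensitivity and precision >= 0.95 at z < -1.96."""
        for t in batch_ztables:
            truth = batch_cohort.truth.planted_by_batch[t.batch_id]
            tp = len(t.slcr_ids & truth)
            assert tp / len(truth) >= 0.95  # sensitivity
            assert tp / max(len(t.slcr_ids), 1) >= 0.95  # precision

    def test_slcr_sets_nested_across_cutoffs(self, batch_ztables):
        for t in batch_ztables:
            strict = t.at_cutoff(-2.58).slcr_ids
            mid = t.at_cutoff(-1.96).slcr_ids
            lax = t.at_cutoff(-1.64).slcr_ids
            assert strict <= mid <= lax

    def test_pooled_mode_flags_uniformly_low_intervals_too(self):
        uni = _universe(40)
        mat = np.full((40, 3), 25.0)
        mat[3, :] = 2.0
        pooled = L.batch_zscores(_profiles(mat, uni.ids), uni, mode="pooled")
        assert uni.ids[3] in pooled.slcr_ids


class TestIntraBatchConsistency:
    def _matrix(self, rows: np.ndarray, batch="b1"):
        uni = {f"chr1:{i}-{i+1}" for i in range(rows.shape[0])}
        callsets = []
        ids = sorted(uni)
        for c in range(rows.shape[1]):
            lcrs = {ids[r] for r in range(rows.shape[0]) if rows[r, c]}
            callsets.append(
                L.LcrCallSet(
                    sample_id=f"s{c}", assay="ES", batch_id=batch, threshold_x=20.0,
                    lcr_ids=frozenset(lcrs), universe_ids=frozenset(uni),
                )
            )
        return L.build_binary_matrix(callsets)

    def test_all_zero_matrix_fully_consistent(self):
        rep = L.intra_batch_consistency(self._matrix(np.zeros((5, 4), dtype=int)), "b1")
        assert rep.percent_consistent == 100.0
        assert rep.n_inconsistent == 0

    def test_single_discordant_sample_makes_interval_inconsistent(self):
        rows = np.zeros((4, 5), dtype=int)
        rows[2, 0] = 1  # LCR in exactly 1 of 5 samples
        rep = L.intra_batch_consistency(self._matrix(rows), "b1")
        assert rep.n_inconsistent == 1
        assert rep.n_consistent == 3

    def test_counts_sum_to_total(self, batch_matrix):
        for b in ["batch1", "batch2", "batch3", "batch4"]:
            rep = L.intra_batch_consistency(batch_matrix, b)
            assert rep.n_consistent + rep.n_inconsistent == rep.n_total
            assert rep.n_total == len(batch_matrix.interval_ids)

    def test_invariant_under_column_permutation(self):
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 2, (30, 6))
        rep1 = L.intra_batch_consistency(self._matrix(rows), "b1")
        rep2 = L.intra_batch_consistency(self._matrix(rows[:, ::-1]), "b1")
        assert rep1.n_consistent == rep2.n_consistent

    def test_single_sample_batch_undefined(self):
        with pytest.raises(ValidationError, match="consistency undefined"):
            L.intra_batch_consistency(self._matrix(np.zeros((3, 1), dtype=int)), "b1")

    @pytest.mark.parametrize(
        "consistent,total,expected",
        [(11_684, 11_911, 98.0), (9_705, 11_911, 81.5),
         (9_537, 11_911, 80.0), (10_068, 11_911, 84.5)],
    )
    def test_percent_rounded_to_nearest_half_point(self, consistent, total, expected):
        assert L.percent_consistent(consistent, total) == expected


class TestInterBatchVenn:
    def _table(self, batch, slcrs, universe):
        df = pd.DataFrame(
            {"capped_batch_mean": 0.0, "z": 0.0, "is_slcr": [i in slcrs for i in universe]},
            index=pd.Index(sorted(universe), name="interval_id"),
        )
        df["z"] = np.where(df["is_slcr"], -3.0, 0.0)
        return L.BatchZScoreTable(batch_id=batch, table=df, threshold_x=20.0,
                                  z_cutoff=-1.96, n_samples=3)

    UNI = {f"i{k}" for k in range(8)}

    def test_identical_sets_all_in_joint_region(self):
        venn = L.inter_batch_venn(
            [self._table("a", {"i0", "i1"}, self.UNI), self._table("b", {"i0", "i1"}, self.UNI)]
        )
        assert venn == {("a", "b"): 2}

    def test_disjoint_sets_only_singletons(self):
        venn = L.inter_batch_venn(
            [self._table("a", {"i0"}, self.UNI), self._table("b", {"i1", "i2"}, self.UNI)]
        )
        assert venn == {("a",): 1, ("b",): 2}

    def test_region_counts_partition_union(self, batch_ztables):
        venn = L.inter_batch_venn(batch_ztables)
        union = frozenset().union(*(t.slcr_ids for t in batch_ztables))
        assert sum(venn.values()) == len(union)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            L.inter_batch_venn(
                [self._table("a", set(), self.UNI), self._table("b", set(), {"x"})]
            )


class TestZScoreContrasts:
    def test_identical_distributions_not_significant(self, batch_ztables):
        same = []
        for k, t in enumerate(batch_ztables[:3]):
            clone = batch_ztables[0].at_cutoff(-1.96)
            clone.batch_id = f"c{k}"
            same.append(clone)
        res = L.batch_zscore_contrasts(same)
        assert res.kruskal_p > 0.5

    def test_shifted_dropout_burden_detected(self):
        """Batches with different systematic-dropout burdens have
        different sLCR z-score distributions (z is standardized within
        batch, so the *number* of affected intervals, not the raw
        severity, shapes the distribution)."""
        cfg = L.SimConfig(
            n_intervals=5000, n_chromosomes=5,
            batches=(
                L.BatchSpec("few", 5, 120.0, n_planted=50, dropout_factor=0.05),
                L.BatchSpec("many", 5, 120.0, n_planted=500, dropout_factor=0.05),
            ),
            seed=9,
        )
        co = L.simulate_cohort(cfg)
        tables = [
            L.batch_zscores(co.profiles_for(batch_id=b), co.universe)
            for b in ("few", "many")
        ]
        res = L.batch_zscore_contrasts(tables)
        assert res.kruskal_p < 0.01

    def test_bh_adjustment_monotone_in_raw_rank(self, batch_ztables):
        res = L.batch_zscore_contrasts(batch_ztables)
        df = res.pairwise.sort_values("p_raw")
        bh = df["p_bh"].to_numpy()
        assert (np.diff(bh) >= -1e-12).all()

    def test_batch_without_slcrs_excluded_with_warning(self, batch_ztables):
        empty = batch_ztables[0].at_cutoff(-100.0)
        empty.batch_id = "empty"
        with pytest.warns(UserWarning, match="excluded"):
            res = L.batch_zscore_contrasts([empty] + [t for t in batch_ztables[:2]])
        assert res.excluded_batches == ["empty"]
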