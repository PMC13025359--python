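"""Gene aggregation, exon-1 stratification, burden rates, GC contrasts."""

import numpy as np
import pytest
from scipy import stats

import lcrqc as L
from lcrqc.errors import ValidationError
from lcrqc.io_formats import Gene, GeneModel, Transcript


def make_gene(gid, chrom, strand, segs, extra_tx=None):
    txs = [Transcript(f"{gid}.t1", tuple(segs), strand)]
    if extra_tx is not None:
        txs.append(Transcript(f"{gid}.t2", tuple(extra_tx), strand))
    return Gene(gene_id=gid, gene_name=gid, chrom=chrom, strand=strand,
                transcripts=tuple(txs))


class TestCategorize:
    def test_three_way_assignment(self):
        cat = L.categorize_lcrs({"a", "b"}, {"b", "c"})
        assert cat == {"a": "ES_only", "b": "shared", "c": "GS_only"}

    def test_equal_sets_all_shared(self):
        cat = L.categorize_lcrs({"a", "b"}, {"a", "b"})
        assert set(cat.values()) == {"shared"}

    def test_partition_conserves_union(self, paired_callsets):
        es, gs = paired_callsets
        es_union = set().union(*(c.lcr_ids for c in es.values()))
        gs_union = set().union(*(c.lcr_ids for c in gs.values()))
        cat = L.categorize_lcrs(es_union, gs_union)
        counts = {c: sum(v == c for v in cat.values()) for c in L.CATEGORIES}
        assert sum(counts.values()) == len(es_union | gs_union)
        assert counts["shared"] == len(es_union & gs_union)


class TestCanonicalTranscript:
    def test_longest_cds_wins(self):
        g = make_gene("G", "chr1", "+", [(0, 100), (200, 300)], extra_tx=[(0, 100)])
        assert L.canonical_transcript(g).transcript_id == "G.t1"

    def test_tie_breaks_lexicographically(self):
        g = Gene(
            gene_id="G", gene_name="G", chrom="chr1", strand="+",
            transcripts=(
                Transcript("G.tB", ((0, 100),), "+"),
                Transcript("G.tA", ((200, 300),), "+"),
            ),
        )
        assert L.canonical_transcript(g).transcript_id == "G.tA"


class TestAssignGeneAndExon:
    def test_minus_strand_first_exon_is_rightmost_segment(self):
        model = GeneModel({"G": make_gene("G", "chr1", "-", [(100, 200), (300, 400)])})
        assert L.assign_gene_and_exon("chr1:350-360", model) == [("G", True)]
        assert L.assign_gene_and_exon("chr1:150-160", model) == [("G", False)]

    def test_plus_strand_second_segment_not_first_exon(self):
        model = GeneModel({"G": make_gene("G", "chr1", "+", [(100, 200), (300, 400)])})
        assert L.assign_gene_and_exon("chr1:350-360", model) == [("G", False)]

    def test_interval_spanning_two_genes_yields_two_records(self):
        model = GeneModel(
            {
                "A": make_gene("A", "chr1", "+", [(100, 200)]),
                "B": make_gene("B", "chr1", "+", [(180, 260)]),
            }
        )
        assert L.assign_gene_and_exon("chr1:150-220", model) == [("A", True), ("B", True)]

    def test_intergenic_interval_yields_empty_list(self):
        model = GeneModel({"G": make_gene("G", "chr1", "+", [(100, 200)])})
        assert L.assign_gene_and_exon("chr2:0-10", model) == []

    def test_matches_brute_force_exon_rank_oracle(self):
        """Random gene models: the first-coding-exon flag agrees with a
        direct scan over strand-ordered CDS segments."""
        rng = np.random.default_rng(21)
        for trial in range(60):
            n_seg = int(rng.integers(1, 6))
            starts = np.sort(rng.choice(np.arange(0, 5000, 10), n_seg, replace=False))
            segs = [(int(s), int(s + rng.integers(5, 9))) for s in starts]
            strand = "+" if rng.random() < 0.5 else "-"
            model = GeneModel({"G": make_gene("G", "chr1", strand, segs)})
            index = L.GeneModelIndex(model)
            q_start = int(rng.integers(0, 5000))
            q_end = q_start + int(rng.integers(1, 40))
            iid = L.make_interval_id("chr1", q_start, q_end)
            got = dict(index.assign(iid))
            ordered = segs if strand == "+" else segs[::-1]
            overlapping = [
                k for k, (s, e) in enumerate(ordered) if q_start < e and q_end > s
            ]
            if not overlapping:
                assert got == {}
            else:
                assert got == {"G": 0 in overlapping}


class TestGeneBurden:
    def _model(self):
        return GeneModel(
            {
                "A": make_gene("A", "chr1", "+", [(0, 1000), (2000, 3000)]),  # 2 kb CDS
                "B": make_gene("B", "chr2", "-", [(0, 500)]),
            }
        )

    def test_per_kb_rate_arithmetic(self):
        cat = {
            "chr1:0-100": "ES_only", "chr1:200-300": "ES_only",
            "chr1:2000-2100": "ES_only", "chr1:2200-2300": "ES_only",
        }
        rec = L.gene_burden(cat, self._model()).loc["A"]
        assert rec["n_es_only"] == 4
        assert rec["rate_es_only"] == pytest.approx(2.0)  # 4 per 2 kb

    def test_rate_halves_when_cds_doubles(self):
        cat = {"chr1:0-100": "ES_only"}
        short = GeneModel({"A": make_gene("A", "chr1", "+", [(0, 1000)])})
        long = GeneModel({"A": make_gene("A", "chr1", "+", [(0, 2000)])})
        r_short = L.gene_burden(cat, short).loc["A", "rate_es_only"]
        r_long = L.gene_burden(cat, long).loc["A", "rate_es_only"]
        assert r_short == pytest.approx(2 * r_long)

    def test_tiling_lcrs_give_full_base_fraction(self):
        cat = {"chr1:0-1000": "shared", "chr1:2000-3000": "shared"}
        rec = L.gene_burden(cat, self._model()).loc["A"]
        assert rec["cds_base_fraction_lcr"] == pytest.approx(1.0)

    def test_overlapping_lcrs_count_bases_once(self):
        cat = {"chr1:0-60": "ES_only", "chr1:40-100": "GS_only"}
        rec = L.gene_burden(cat, self._model()).loc["A"]
        assert rec["cds_base_fraction_lcr"] == pytest.approx(100 / 2000)

    def test_base_fraction_matches_base_set_oracle(self):
        rng = np.random.default_rng(8)
        model = GeneModel({"A": make_gene("A", "chr1", "+", [(0, 300), (400, 700)])})
        cds_bases = set(range(0, 300)) | set(range(400, 700))
        for _ in range(50):
            n = int(rng.integers(1, 8))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 800))
                ivs.append((s, s + int(rng.integers(1, 120))))
            cat = {L.make_interval_id("chr1", s, e): "shared" for s, e in ivs}
            covered = set()
            for s, e in ivs:
                covered |= set(range(s, e)) & cds_bases
            rec = L.gene_burden(cat, model).loc["A"]
            assert rec["cds_base_fraction_lcr"] == pytest.approx(len(covered) / 600)

    def test_base_fraction_invariant_under_interval_splitting(self):
        whole = {"chr1:100-300": "ES_only"}
        split = {"chr1:100-200": "ES_only", "chr1:200-300": "ES_only"}
        model = self._model()
        f1 = L.gene_burden(whole, model).loc["A", "cds_base_fraction_lcr"]
        f2 = L.gene_burden(split, model).loc["A", "cds_base_fraction_lcr"]
        assert f1 == pytest.approx(f2)

    def test_exon1_indicators_strand_aware(self):
        cat = {"chr2:0-50": "GS_only"}  # minus-strand single-exon gene
        rec = L.gene_burden(cat, self._model()).loc["B"]
        assert rec["has_lcr_exon1"]
        assert not rec["has_lcr_other_exon"]


class TestTopGeneConcentration:
    def _records(self, counts):
        import pandas as pd

        genes = [f"G{i}" for i in range(len(counts))]
        df = pd.DataFrame(
            {
                "gene_id": genes,
                "n_total": counts,
                "rate_total": [c / 1.0 for c in counts],
            }
        ).set_index("gene_id")
        return df

    def test_all_lcrs_in_one_gene(self):
        obs, exp = L.top_gene_concentration(self._records([10, 0, 0]), k=1)
        assert obs == 100.0

    def test_uniform_distribution_observed_equals_expected(self):
        obs, exp = L.top_gene_concentration(self._records([1] * 40), k=10)
        assert obs == pytest.approx(exp)

    def test_expected_uniform_formula(self):
        assert round(L.expected_uniform_percent(100, 4427), 1) == 2.3

    def test_k_of_all_genes_is_everything(self):
        obs, _ = L.top_gene_concentration(self._records([3, 2, 1]), k=3)
        assert obs == 100.0

    def test_no_genes_with_lcrs_rejected(self):
        with pytest.raises(ValidationError, match="no genes"):
            L.top_gene_concentration(self._records([0, 0]), k=1)


class TestGcComparison:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        vals = rng.beta(8, 10, 300)
        gc_map = {f"i{k}": float(v) for k, v in enumerate(vals)}
        cat_map = {f"i{k}": L.CATEGORIES[k % 3] for k in range(300)}
        res = L.gc_category_comparison(gc_map, cat_map)
        assert res.kruskal_p > 0.05

    def test_three_category_simulation_all_contrasts_flagged(self):
        """Medians 0.33 / 0.43 / 0.37 at n=500 each: Kruskal-Wallis and
        every BH-adjusted Dunn contrast significant."""
        groups = L.simulate_gc_categories(n_per_category=500, seed=17)
        gc_map, cat_map = {}, {}
        i = 0
        for cat, vals in groups.items():
            for v in vals:
                gc_map[f"i{i}"] = float(v)
                cat_map[f"i{i}"] = cat
                i += 1
        res = L.gc_category_comparison(gc_map, cat_map)
        assert res.kruskal_p < 1e-10
        assert (res.dunn["p_bh"] < 0.05).all()
        assert res.medians["ES_only"] < res.medians["shared"] < res.medians["GS_only"]

    def test_two_group_dunn_tracks_rank_sum_test(self):
        """With two groups, Dunn's z is the (uncorrected) normal
        approximation of the Wilcoxon rank-sum test."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 35)
        dunn = L.dunn_test({"a": a, "b": b})
        z_ref = stats.ranksums(a, b).statistic
        assert abs(dunn.loc[0, "z"]) == pytest.approx(abs(z_ref), rel=1e-9)

    def test_small_category_excluded_with_warning(self):
        gc_map = {"i0": 0.5, "i1": 0.4, "i2": 0.45, "i3": 0.3, "i4": 0.2}
        cat_map = {"i0": "ES_only", "i1": "ES_only", "i2": "GS_only",
                   "i3": "GS_only", "i4": "shared"}
        with pytest.warns(UserWarning, match="excluded"):
            res = L.gc_category_comparison(gc_map, cat_map)
        assert res.excluded == ["shared"]
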