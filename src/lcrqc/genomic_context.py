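"""Gene-level aggregation and genomic context of low-coverage regions.

LCR intervals from a paired ES/GS cohort are partitioned into three
categories (ES-only / GS-only / shared), mapped onto genes, and
summarised per gene as:

* counts per category and length-normalised rates (LCRs per kb of CDS),
* binary indicators for LCR presence in the first coding exon vs any
  other coding exon (strand-aware: "exon 1" is the 5'-most CDS segment
  of the canonical transcript in transcript orientation),
* the fraction of CDS bases overlapped by any LCR (base-level burden,
  double-counting prevented).

The canonical transcript of a gene is the one with the longest total
CDS, ties broken lexicographically by transcript_id.

GC content of the three categories is compared with a Kruskal–Wallis
test followed by Dunn's post hoc z-tests (rank-sum based, tie-corrected)
with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import Gene, GeneModel, Transcript, parse_interval_id

ES_ONLY = "ES_only"
GS_ONLY = "GS_only"
SHARED = "shared"
CATEGORIES = (ES_ONLY, GS_ONLY, SHARED)


def categorize_lcrs(es_union: set[str], gs_union: set[str]) -> dict[str, str]:
    """Exact three-way partition of the ES ∪ GS LCR interval union."""
    out: dict[str, str] = {}
    for iid in es_union | gs_union:
        if iid in es_union and iid in gs_union:
            out[iid] = SHARED
        elif iid in es_union:
            out[iid] = ES_ONLY
        else:
            out[iid] = GS_ONLY
    return out


def canonical_transcript(gene: Gene) -> Transcript:
    """Longest-total-CDS transcript; lexicographically smallest
    transcript_id on ties."""
    return min(gene.transcripts, key=lambda t: (-t.cds_length, t.transcript_id))


class GeneModelIndex:
    """Overlap index over a gene model's canonical-transcript CDS."""

    def __init__(self, model: GeneModel):
        self.model = model
        self.canonical: dict[str, Transcript] = {
            gid: canonical_transcript(g) for gid, g in model.genes.items()
        }
        self._trees: dict[str, IntervalTree] = {}
        for gid, gene in model.genes.items():
            tx = self.canonical[gid]
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for s, e in tx.cds:
                tree.addi(s, e, gid)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(start, end)}

    def assign(self, interval_id: str) -> list[tuple[str, bool]]:
        """All genes whose canonical CDS the interval overlaps, each with
        a flag for whether the overlap touches the first coding exon
        (5'-most CDS segment in transcript orientation).

        An interval overlapping no gene yields an empty list (reported as
        intergenic relative to this model)."""
        chrom, start, end = parse_interval_id(interval_id)
        out = []
        for gid in sorted(self.genes_overlapping(chrom, start, end)):
            first_s, first_e = self.canonical[gid].cds_5prime_first[0]
            out.append((gid, start < first_e and end > first_s))
        return out


def assign_gene_and_exon(
    interval_id: str, model: GeneModel | GeneModelIndex
) -> list[tuple[str, bool]]:
    """Convenience wrapper over :meth:`GeneModelIndex.assign`; pass a
    prebuilt index when annotating many intervals."""
    index = model if isinstance(model, GeneModelIndex) else GeneModelIndex(model)
    return index.assign(interval_id)


def _overlap_bases(segments: Sequence[tuple[int, int]], intervals: Sequence[tuple[int, int]]) -> int:
    """Bases of ``segments`` covered by the union of ``intervals``
    (each base counted once)."""
    if not segments or not intervals:
        return 0
    # merge intervals, then sweep segments
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = 0
    for seg_s, seg_e in segments:
        for s, e in merged:
            lo, hi = max(seg_s, s), min(seg_e, e)
            if hi > lo:
                total += hi - lo
    return total


def gene_burden(
    category_map: Mapping[str, str],
    model: GeneModel,
) -> pd.DataFrame:
    """Per-gene LCR burden table.

    One row per gene with >=0 overlapping LCRs (genes without any LCR
    are included with zero counts so list-level denominators are
    available). Columns: gene_id, gene_name, cds_length_bp, n_es_only,
    n_gs_only, n_shared, n_total, rate_* (per kb of CDS),
    has_lcr_exon1, has_lcr_other_exon, cds_base_fraction_lcr.

    Intervals overlapping several genes count toward each (no fractional
    splitting); base-level burden counts each CDS base at most once.
    """
    index = GeneModelIndex(model)
    per_gene_hits: dict[str, list[str]] = {gid: [] for gid in model.genes}
    exon1_flag: dict[str, bool] = {gid: False for gid in model.genes}
    other_flag: dict[str, bool] = {gid: False for gid in model.genes}
    for iid in category_map:
        for gid, is_first in index.assign(iid):
            per_gene_hits[gid].append(iid)
            if is_first:
                exon1_flag[gid] = True
            else:
                other_flag[gid] = True

    rows = []
    for gid, gene in model.genes.items():
        tx = index.canonical[gid]
        cds_len = tx.cds_length
        if cds_len == 0:
            warnings.warn(f"gene {gid}: zero CDS length, excluded", stacklevel=2)
            continue
        hits = per_gene_hits[gid]
        counts = {c: 0 for c in CATEGORIES}
        for iid in hits:
            counts[category_map[iid]] += 1
        coords = [parse_interval_id(iid)[1:] for iid in hits]
        frac = _overlap_bases(tx.cds, coords) / cds_len
        row = {
            "gene_id": gid,
            "gene_name": gene.gene_name,
            "cds_length_bp": cds_len,
            "n_es_only": counts[ES_ONLY],
            "n_gs_only": counts[GS_ONLY],
            "n_shared": counts[SHARED],
        }
        row["n_total"] = sum(counts.values())
        for cat, key in ((ES_ONLY, "rate_es_only"), (GS_ONLY, "rate_gs_only"), (SHARED, "rate_shared")):
            row[key] = counts[cat] * 1000.0 / cds_len
        row["rate_total"] = row["n_total"] * 1000.0 / cds_len
        row["has_lcr_exon1"] = exon1_flag[gid]
        row["has_lcr_other_exon"] = other_flag[gid]
        row["cds_base_fraction_lcr"] = frac
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def top_gene_concentration(records: pd.DataFrame, k: int) -> tuple[float, float]:
    """Observed vs uniform-expected concentration of LCRs in the top-k
    genes.

    Genes are ranked by total LCR count (ties: per-kb total rate, then
    gene_id). Observed = percent of all LCRs carried by the top-k genes;
    expected under a uniform spread = 100 * k / (genes with >=1 LCR).
    """
    with_lcr = records[records["n_total"] > 0]
    n_genes = len(with_lcr)
    if n_genes == 0:
        raise ValidationError("no genes with LCRs")
    if k > n_genes:
        raise ValidationError(f"k={k} exceeds genes with LCRs ({n_genes})")
    ranked = with_lcr.sort_values(
        by=["n_total", "rate_total", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    total = with_lcr["n_total"].sum()
    observed = 100.0 * ranked["n_total"].head(k).sum() / total
    expected = 100.0 * k / n_genes
    return float(observed), float(expected)


def expected_uniform_percent(k: int, n_genes_with_lcr: int) -> float:
    """Percent of LCRs the top-k genes would carry were LCRs spread
    uniformly over the genes that harbor any."""
    if n_genes_with_lcr <= 0:
        raise ValidationError("n_genes_with_lcr must be positive")
    return 100.0 * k / n_genes_with_lcr


# ---------------------------------------------------------------------------
# GC comparison across LCR categories
# ---------------------------------------------------------------------------

def dunn_test(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post hoc test on >=2 groups after a Kruskal–Wallis test.

    Pooled ranks with the standard tie correction; pairwise z statistics
    with two-sided normal p-values and Benjamini–Hochberg adjustment
    across the contrasts.
    """
    names = sorted(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {}
    pos = 0
    for g in names:
        mean_ranks[g] = ranks[pos : pos + sizes[g]].mean()
        pos += sizes[g]
    # tie correction: sum(t^3 - t) over tied groups
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(((counts**3) - counts).sum())
    var_factor = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append(
            {"group_a": a, "group_b": b, "z": float(z),
             "p_raw": float(2 * stats.norm.sf(abs(z)))}
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


@dataclass
class GcComparison:
    """GC-content contrast across LCR categories."""

    medians: dict[str, float]
    kruskal_stat: float
    kruskal_p: float
    dunn: pd.DataFrame
    excluded: list[str]


def gc_category_comparison(
    gc_map: Mapping[str, float | None],
    category_map: Mapping[str, str],
) -> GcComparison:
    """Compare GC distributions of ES-only / GS-only / shared LCRs.

    Intervals without a GC value (all-N) are dropped; categories with
    fewer than 2 values are excluded with a warning.
    """
    groups: dict[str, list[float]] = {}
    for iid, cat in category_map.items():
        gc = gc_map.get(iid)
        if gc is not None:
            groups.setdefault(cat, []).append(gc)
    usable: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for cat, vals in groups.items():
        if len(vals) < 2:
            excluded.append(cat)
            warnings.warn(f"category {cat}: <2 GC values, excluded", stacklevel=2)
        else:
            usable[cat] = np.asarray(vals)
    if len(usable) < 2:
        raise ValidationError("need >=2 categories with GC values")
    kw = stats.kruskal(*usable.values())
    return GcComparison(
        medians={c: float(np.median(v)) for c, v in usable.items()},
        kruskal_stat=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        dunn=dunn_test(usable),
        excluded=excluded,
    )
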