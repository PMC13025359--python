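"""Clinical overlay: recurrent LCRs, disease-gene lists, pathogenic variants.

A *recurrent* LCR is an interval flagged low-coverage in every sample of
a cohort (the all-sample intersection; a lower recurrence fraction is
exposed for exploratory use). Recurrent and per-sample LCRs are joined
against disease-gene lists (OMIM-morbid-like, SysNDD-like with evidence
tiers) by case-insensitive gene symbol, and against pathogenic-variant
catalogs by position: a variant overlaps an LCR when its VCF POS base
falls inside the interval (multi-base deletions are anchored at POS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .genomic_context import GeneModelIndex
from .io_formats import GeneList, VariantRecord, parse_interval_id
from .lcr_core import BinaryLcrMatrix


@dataclass
class RecurrentLcrSet:
    """Intervals low-covered in (a fraction of, default all) samples of
    one assay cohort, with their host genes."""

    assay: str | None
    recurrence_fraction: float
    interval_ids: frozenset[str]
    n_samples: int
    gene_ids: frozenset[str] = frozenset()
    gene_names: frozenset[str] = frozenset()
    list_hits: dict[str, frozenset[str]] = field(default_factory=dict)


def recurrent_lcrs(
    matrix: BinaryLcrMatrix,
    assay: str | None = None,
    recurrence_fraction: float = 1.0,
    model_index: GeneModelIndex | None = None,
    gene_lists: Sequence[GeneList] = (),
    evidence_filter: set[str] | None = None,
) -> RecurrentLcrSet:
    """Intervals flagged LCR in >= ``recurrence_fraction`` of the
    (optionally assay-filtered) samples; default 1.0 = every sample.

    With a gene-model index, host genes are attached; with gene lists,
    the recurrent genes are intersected with each list.
    """
    if not 0 < recurrence_fraction <= 1:
        raise ValidationError("recurrence_fraction must be in (0, 1]")
    cols = matrix.columns_for(assay=assay)
    if not cols:
        raise ValidationError(f"no samples match assay filter {assay!r}")
    sub = matrix.data[cols]
    frac = sub.sum(axis=1) / len(cols)
    ids = frozenset(sub.index[frac >= recurrence_fraction])

    gene_ids: set[str] = set()
    gene_names: set[str] = set()
    if model_index is not None:
        for iid in ids:
            for gid, _ in model_index.assign(iid):
                gene_ids.add(gid)
                gene_names.add(model_index.model.genes[gid].gene_name)
    hits: dict[str, frozenset[str]] = {}
    for gl in gene_lists:
        members = {g.upper() for g in gl.filtered(evidence_filter)}
        hits[gl.list_name] = frozenset(g for g in gene_names if g.upper() in members)
    return RecurrentLcrSet(
        assay=assay,
        recurrence_fraction=recurrence_fraction,
        interval_ids=ids,
        n_samples=len(cols),
        gene_ids=frozenset(gene_ids),
        gene_names=frozenset(gene_names),
        list_hits=hits,
    )


@dataclass
class GeneListReport:
    """Membership of LCR-affected genes in one disease-gene list."""

    list_name: str
    n_list_genes: int
    affected_genes: frozenset[str]
    fraction_affected: float
    per_sample_counts: dict[str, int] = field(default_factory=dict)


def annotate_gene_lists(
    lcr_gene_symbols: Iterable[str],
    gene_lists: Sequence[GeneList],
    evidence_filter: set[str] | None = None,
    per_sample_gene_symbols: Mapping[str, set[str]] | None = None,
) -> list[GeneListReport]:
    """Intersect LCR-affected gene symbols with each disease-gene list.

    Join is case-insensitive exact symbol match (no alias resolution).
    The evidence filter shrinks both numerator and denominator of lists
    that carry evidence tiers. ``per_sample_gene_symbols`` adds, per
    list, the count of affected list genes in each sample.
    """
    lcr_syms = {g.upper() for g in lcr_gene_symbols}
    reports: list[GeneListReport] = []
    any_hit = False
    for gl in gene_lists:
        members = gl.filtered(evidence_filter)
        members_uc = {m.upper(): m for m in members}
        affected = frozenset(members_uc[s] for s in lcr_syms & set(members_uc))
        if affected:
            any_hit = True
        per_sample: dict[str, int] = {}
        if per_sample_gene_symbols is not None:
            for sid, syms in per_sample_gene_symbols.items():
                per_sample[sid] = len({s.upper() for s in syms} & set(members_uc))
        reports.append(
            GeneListReport(
                list_name=gl.list_name,
                n_list_genes=len(members),
                affected_genes=affected,
                fraction_affected=len(affected) / len(members) if members else 0.0,
                per_sample_counts=per_sample,
            )
        )
    if lcr_syms and gene_lists and not any_hit:
        warnings.warn(
            "no LCR gene found in any list: possible symbol mismatch", stacklevel=2
        )
    return reports


@dataclass(frozen=True)
class VariantOverlapHit:
    """A catalog variant whose position falls inside an LCR interval."""

    variant: VariantRecord
    interval_id: str
    n_samples_lcr: int
    gene_ids: tuple[str, ...] = ()


def variant_overlap(
    lcr_intervals: Iterable[str],
    variants: Sequence[VariantRecord],
    matrix: BinaryLcrMatrix,
    model_index: GeneModelIndex | None = None,
) -> list[VariantOverlapHit]:
    """Variants whose POS base falls inside any of the given intervals.

    ``n_samples_lcr`` is the number of cohort samples in which the
    hosting interval is an LCR (the interval's binary-matrix row sum).
    Zero hits is a valid result.
    """
    trees: dict[str, IntervalTree] = {}
    for iid in lcr_intervals:
        chrom, start, end = parse_interval_id(iid)
        trees.setdefault(chrom, IntervalTree()).addi(start, end, iid)
    row_sums = matrix.data.sum(axis=1)
    hits: list[VariantOverlapHit] = []
    for var in variants:
        tree = trees.get(var.chrom)
        if tree is None:
            continue
        for node in sorted(tree.at(var.pos0)):
            iid = node.data
            genes: tuple[str, ...] = ()
            if model_index is not None:
                genes = tuple(g for g, _ in model_index.assign(iid))
            hits.append(
                VariantOverlapHit(
                    variant=var,
                    interval_id=iid,
                    n_samples_lcr=int(row_sums.get(iid, 0)),
                    gene_ids=genes,
                )
            )
    return hits


def hits_to_frame(hits: Sequence[VariantOverlapHit]) -> pd.DataFrame:
    """Flatten overlap hits to a VCF-like table."""
    rows = []
    for h in hits:
        rows.append(
            {
                "chrom": h.variant.chrom,
                "pos": h.variant.pos,
                "ref": h.variant.ref,
                "alt": h.variant.alt,
                "gene": ",".join(h.gene_ids),
                "interval_id": h.interval_id,
                "n_samples_lcr": h.n_samples_lcr,
                "significance": h.variant.clinical_significance,
            }
        )
    cols = ["chrom", "pos", "ref", "alt", "gene", "interval_id", "n_samples_lcr", "significance"]
    return pd.DataFrame(rows, columns=cols)
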