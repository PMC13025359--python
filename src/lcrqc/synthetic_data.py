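"""Synthetic multi-batch, multi-assay depth cohorts with known truth.

The generator emulates the structure of a clinical ES/GS depth dataset:

* a shared CDS-like target design (intervals laid out along chromosomes),
* per-batch global mean depth (defaults mirror four exome runs at
  229x / 117x / 117x / 126x with 10 samples each),
* batch- or assay-specific *planted* systematic dropout: a chosen set of
  intervals whose expected depth is multiplied by a severe factor
  (default 0.05), the ground truth that batch z-score detection must
  recover,
* optional GC-dependent coverage depression: a piecewise-linear factor
  penalising intervals with GC outside [0.3, 0.6], with assay-specific
  slopes (hybridisation capture suffers more at GC extremes than
  PCR-free genome libraries),
* per-sample multiplicative lognormal noise on interval depth (depth is
  positive and right-skewed; default sigma 0.2).

Expected per-interval depth in a cohort is

    batch_mean_doc * gc_factor(GC_i) * dropout_factor_i

and each sample realises it times ``exp(N(0, sigma))``. All randomness
flows from a single seeded :class:`numpy.random.Generator`; identical
configuration (including the seed) yields byte-identical output files.

A companion generator emits a matching annotation bundle — synthetic
gene model (intervals grouped into multi-exon genes), OMIM-/SysNDD-like
gene lists, a pathogenic-variant VCF planted inside dropout intervals,
and a FASTA whose per-interval GC matches the ground truth — all in the
exact dialects the readers consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    DepthProfile,
    Gene,
    GeneList,
    GeneModel,
    TargetInterval,
    TargetIntervalSet,
    Transcript,
    VariantRecord,
    make_interval_id,
)


@dataclass(frozen=True)
class GcEffect:
    """Piecewise-linear depth depression outside a GC comfort zone.

    factor(gc) = 1 inside [low_bound, high_bound]; outside it falls
    linearly with the given slope per unit GC, floored at ``floor``.
    """

    low_bound: float = 0.3
    high_bound: float = 0.6
    slope_low: float = 0.0
    slope_high: float = 0.0
    floor: float = 0.02

    def factor(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        low_pen = self.slope_low * np.maximum(0.0, self.low_bound - gc)
        high_pen = self.slope_high * np.maximum(0.0, gc - self.high_bound)
        return np.clip(1.0 - low_pen - high_pen, self.floor, 1.0)


#: ES-like capture: strong low-GC and high-GC depression.
ES_GC_EFFECT = GcEffect(slope_low=8.0, slope_high=5.0)
#: GS-like PCR-free libraries: milder, symmetric depression.
GS_GC_EFFECT = GcEffect(slope_low=3.0, slope_high=3.0)
NO_GC_EFFECT = GcEffect()


@dataclass(frozen=True)
class BatchSpec:
    """One sequencing run: its samples, global depth and planted dropout."""

    batch_id: str
    n_samples: int
    mean_doc: float
    assay: str = "ES"
    n_planted: int = 200
    dropout_factor: float = 0.05
    sample_ids: tuple[str, ...] | None = None

    def resolved_sample_ids(self) -> tuple[str, ...]:
        if self.sample_ids is not None:
            if len(self.sample_ids) != self.n_samples:
                raise ValidationError(
                    f"batch {self.batch_id}: {len(self.sample_ids)} sample_ids "
                    f"for n_samples={self.n_samples}"
                )
            return self.sample_ids
        return tuple(f"{self.batch_id}_s{i + 1:02d}" for i in range(self.n_samples))


def _default_batches() -> tuple[BatchSpec, ...]:
    means = (229.0, 117.0, 117.0, 126.0)
    return tuple(
        BatchSpec(batch_id=f"batch{i + 1}", n_samples=10, mean_doc=m)
        for i, m in enumerate(means)
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated cohort; the seed determines
    everything."""

    n_intervals: int = 10_000
    n_chromosomes: int = 22
    length_log_mean: float = math.log(140.0)
    length_log_sigma: float = 0.45
    length_min: int = 50
    length_max: int = 2_000
    gap_bp: int = 200
    batches: tuple[BatchSpec, ...] = field(default_factory=_default_batches)
    n_planted_shared: int = 0  # intervals low in every cohort
    sigma: float = 0.2
    gc_alpha: float = 8.1
    gc_beta: float = 9.9
    gc_effects: Mapping[str, GcEffect] = field(
        default_factory=lambda: {"ES": NO_GC_EFFECT, "GS": NO_GC_EFFECT}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.batches:
            if b.mean_doc <= 0:
                raise ValidationError(f"batch {b.batch_id}: mean_doc must be positive")
            if not 0 <= b.dropout_factor <= 1:
                raise ValidationError(f"batch {b.batch_id}: dropout_factor outside [0,1]")
        total_planted = self.n_planted_shared + sum(b.n_planted for b in self.batches)
        if total_planted > self.n_intervals:
            raise ValidationError(
                f"planted intervals ({total_planted}) exceed n_intervals ({self.n_intervals})"
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for truth-based evaluation."""

    planted_by_batch: dict[str, frozenset[str]]  # includes the shared set
    shared_planted: frozenset[str]
    gc: dict[str, float]
    expected_depth: dict[str, pd.Series]  # batch_id -> pre-noise depth

    def expected_lcrs(self, batch_id: str, threshold_x: float = 20.0) -> frozenset[str]:
        """Intervals whose noise-free expected depth is below threshold."""
        exp = self.expected_depth[batch_id]
        return frozenset(exp.index[exp < threshold_x])


@dataclass
class SimulatedCohort:
    config: SimConfig
    universe: TargetIntervalSet
    profiles: list[DepthProfile]
    truth: GroundTruth

    def profiles_for(self, batch_id: str | None = None, assay: str | None = None) -> list[DepthProfile]:
        out = []
        for p in self.profiles:
            if batch_id is not None and p.batch_id != batch_id:
                continue
            if assay is not None and p.assay != assay:
                continue
            out.append(p)
        return out

    def manifest(self, depth_dir: str = "depths") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in self.profiles],
                "assay": [p.assay for p in self.profiles],
                "batch_id": [p.batch_id for p in self.profiles],
                "depth_path": [
                    f"{depth_dir}/{p.batch_id}.{p.sample_id}.regions.bed" for p in self.profiles
                ],
            }
        )


def _layout_intervals(config: SimConfig, rng: np.random.Generator) -> TargetIntervalSet:
    lengths = np.exp(
        rng.normal(config.length_log_mean, config.length_log_sigma, config.n_intervals)
    )
    lengths = np.clip(lengths, config.length_min, config.length_max).astype(int)
    per_chrom = int(np.ceil(config.n_intervals / config.n_chromosomes))
    intervals: list[TargetInterval] = []
    i = 0
    for c in range(config.n_chromosomes):
        pos = 1_000
        for _ in range(per_chrom):
            if i >= config.n_intervals:
                break
            intervals.append(TargetInterval(f"chr{c + 1}", pos, pos + int(lengths[i])))
            pos += int(lengths[i]) + config.gap_bp
            i += 1
    return TargetIntervalSet(intervals, design_label="synthetic_cds")


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the depth cohort described by ``config``."""
    rng = np.random.default_rng(config.seed)
    universe = _layout_intervals(config, rng)
    ids = universe.ids
    n = len(ids)

    gc = rng.beta(config.gc_alpha, config.gc_beta, n)

    # disjoint planted allocation: shared set first, then one slice per batch
    pool = rng.permutation(n)
    cursor = 0
    shared_idx = pool[cursor : cursor + config.n_planted_shared]
    cursor += config.n_planted_shared
    batch_planted_idx: dict[str, np.ndarray] = {}
    for b in config.batches:
        batch_planted_idx[b.batch_id] = pool[cursor : cursor + b.n_planted]
        cursor += b.n_planted

    id_arr = np.asarray(ids)
    shared_ids = frozenset(id_arr[shared_idx])
    profiles: list[DepthProfile] = []
    planted_by_batch: dict[str, frozenset[str]] = {}
    expected_by_batch: dict[str, pd.Series] = {}

    for b in config.batches:
        effect = config.gc_effects.get(b.assay, NO_GC_EFFECT)
        expected = b.mean_doc * effect.factor(gc)
        dropout = np.ones(n)
        own = batch_planted_idx[b.batch_id]
        dropout[own] = b.dropout_factor
        dropout[shared_idx] = b.dropout_factor
        expected = expected * dropout
        planted_by_batch[b.batch_id] = frozenset(id_arr[own]) | shared_ids
        expected_by_batch[b.batch_id] = pd.Series(expected, index=ids)

        for sid in b.resolved_sample_ids():
            noise = (
                np.exp(rng.normal(0.0, config.sigma, n)) if config.sigma > 0 else np.ones(n)
            )
            profiles.append(
                DepthProfile(
                    sample_id=sid,
                    assay=b.assay,
                    batch_id=b.batch_id,
                    depths=pd.Series(expected * noise, index=ids, name=sid),
                )
            )

    truth = GroundTruth(
        planted_by_batch=planted_by_batch,
        shared_planted=shared_ids,
        gc={iid: float(g) for iid, g in zip(ids, gc)},
        expected_depth=expected_by_batch,
    )
    return SimulatedCohort(config=config, universe=universe, profiles=profiles, truth=truth)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    """Write target BED, per-sample depth BEDs, manifest TSV and a
    ground-truth JSON; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "depths").mkdir(parents=True, exist_ok=True)
    cohort.universe.to_bed(outdir / "targets.bed")

    coords = {iv.interval_id: iv for iv in cohort.universe}
    for prof in cohort.profiles:
        path = outdir / "depths" / f"{prof.batch_id}.{prof.sample_id}.regions.bed"
        with open(path, "w") as fh:
            for iid in cohort.universe.ids:
                iv = coords[iid]
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{prof.depths[iid]:.4f}\n")

    manifest = cohort.manifest()
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)

    truth = cohort.truth
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "planted_by_batch": {b: sorted(s) for b, s in truth.planted_by_batch.items()},
                "shared_planted": sorted(truth.shared_planted),
                "gc": truth.gc,
            },
            fh,
            indent=0,
        )
    return manifest_path


# ---------------------------------------------------------------------------
# Scenario factories (the study conditions each analysis is exercised under)
# ---------------------------------------------------------------------------

def batch_effect_scenario(seed: int = 0) -> SimConfig:
    """Four exome batches (229/117/117/126x, 10 samples each) with 200
    planted systematic-dropout intervals per batch at severity 0.05."""
    return SimConfig(seed=seed)


def paired_assay_scenario(seed: int = 0, n_pairs: int = 14) -> SimConfig:
    """A paired ES/GS cohort: the same donors sequenced by exome (225x)
    and genome (64.4x), with disjoint assay-specific planted dropout
    (250 ES / 160 GS intervals), 20 intervals low in both, and
    assay-specific GC depression."""
    donors = tuple(f"P{i + 1:02d}" for i in range(n_pairs))
    return SimConfig(
        batches=(
            BatchSpec("ES_run", n_pairs, 225.0, assay="ES", n_planted=250, sample_ids=donors),
            BatchSpec("GS_run", n_pairs, 64.4, assay="GS", n_planted=160, sample_ids=donors),
        ),
        n_planted_shared=20,
        gc_effects={"ES": ES_GC_EFFECT, "GS": GS_GC_EFFECT},
        seed=seed,
    )


def gc_effect_scenario(seed: int = 0) -> tuple[SimConfig, str]:
    """A single strongly GC-biased exome batch with no planted dropout;
    the expected direction of the called-LCR median GC relative to
    non-LCR intervals is 'low' (low-GC depression dominates)."""
    cfg = SimConfig(
        batches=(BatchSpec("gc_batch", 8, 100.0, n_planted=0),),
        gc_effects={"ES": ES_GC_EFFECT},
        seed=seed,
    )
    return cfg, "low"


def simulate_gc_categories(
    n_per_category: int = 500,
    medians: Mapping[str, float] = None,
    concentration: float = 30.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Beta-distributed GC values for the three LCR categories, centred
    on configurable medians (defaults 0.33 ES-only / 0.43 GS-only /
    0.37 shared)."""
    if medians is None:
        medians = {"ES_only": 0.33, "GS_only": 0.43, "shared": 0.37}
    rng = np.random.default_rng(seed)
    out = {}
    for cat, m in medians.items():
        a = m * concentration
        b = (1.0 - m) * concentration
        out[cat] = rng.beta(a, b, n_per_category)
    return out


# ---------------------------------------------------------------------------
# Annotation bundle (gene model, lists, variants, FASTA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationConfig:
    exons_per_gene: tuple[int, int] = (2, 6)  # inclusive range
    second_transcript_fraction: float = 0.1
    omim_fraction: float = 0.30
    sysndd_fraction: float = 0.15
    evidence_levels: tuple[str, ...] = ("definitive", "moderate", "limited")
    evidence_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    n_pathogenic_variants: int = 30
    n_benign_variants: int = 5
    background_gc: float = 0.42
    seed: int | None = None  # defaults to cohort seed + 1


@dataclass
class SimulatedAnnotation:
    model: GeneModel
    gene_lists: list[GeneList]
    variants: list[VariantRecord]  # pathogenic and benign, all planted
    sequences: dict[str, str]
    variant_target_intervals: dict[str, str]  # variant key -> interval_id


def _draw_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    is_gc = rng.random(length) < gc
    pick = rng.random(length) < 0.5
    bases = np.where(is_gc, np.where(pick, "G", "C"), np.where(pick, "A", "T"))
    return bases


def simulate_gene_annotation(
    cohort: SimulatedCohort, config: AnnotationConfig = AnnotationConfig()
) -> SimulatedAnnotation:
    """Build a gene model, gene lists, variants and genome sequence
    consistent with a simulated cohort.

    Consecutive target intervals on one chromosome are grouped into
    multi-exon genes (the intervals become CDS segments); a fraction of
    genes get a second, shorter transcript so canonical-transcript
    selection is exercised. Pathogenic-labelled variants are planted at
    the midpoint of planted-dropout intervals; benign-labelled ones in
    unplanted intervals.
    """
    seed = config.seed if config.seed is not None else cohort.config.seed + 1
    rng = np.random.default_rng(seed)
    intervals = list(cohort.universe)

    # --- genes -----------------------------------------------------------
    genes: dict[str, Gene] = {}
    by_chrom: dict[str, list[TargetInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    gnum = 0
    lo, hi = config.exons_per_gene
    for chrom in sorted(by_chrom, key=_chrom_key):
        ivs = by_chrom[chrom]
        i = 0
        while i < len(ivs):
            k = int(rng.integers(lo, hi + 1))
            segs = tuple((iv.start, iv.end) for iv in ivs[i : i + k])
            i += k
            gnum += 1
            gid = f"GENE{gnum:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            txs = [Transcript(f"{gid}.t1", segs, strand)]
            if len(segs) > 1 and rng.random() < config.second_transcript_fraction:
                txs.append(Transcript(f"{gid}.t2", segs[:-1], strand))
            genes[gid] = Gene(
                gene_id=gid, gene_name=gid, chrom=chrom, strand=strand,
                transcripts=tuple(txs),
            )
    model = GeneModel(genes=genes)

    # --- gene lists ------------------------------------------------------
    names = sorted(g.gene_name for g in genes.values())
    n_omim = max(1, int(round(config.omim_fraction * len(names))))
    n_sysndd = max(1, int(round(config.sysndd_fraction * len(names))))
    omim_genes = sorted(rng.choice(names, size=n_omim, replace=False))
    sysndd_genes = sorted(rng.choice(names, size=n_sysndd, replace=False))
    evid = rng.choice(config.evidence_levels, size=n_sysndd, p=config.evidence_probs)
    gene_lists = [
        GeneList("OMIM", {g: None for g in omim_genes}),
        GeneList("SysNDD", dict(zip(sysndd_genes, evid))),
    ]

    # --- sequences (per-interval GC from ground truth) -------------------
    sequences: dict[str, str] = {}
    for chrom, ivs in by_chrom.items():
        total = ivs[-1].end + cohort.config.gap_bp
        arr = _draw_bases(rng, total, config.background_gc)
        for iv in ivs:
            arr[iv.start : iv.end] = _draw_bases(
                rng, iv.length, cohort.truth.gc[iv.interval_id]
            )
        sequences[chrom] = "".join(arr)

    # --- variants --------------------------------------------------------
    planted_union = sorted(set().union(*cohort.truth.planted_by_batch.values()))
    unplanted = [iv.interval_id for iv in intervals if iv.interval_id not in set(planted_union)]
    variants: list[VariantRecord] = []
    target_map: dict[str, str] = {}
    coords = {iv.interval_id: iv for iv in intervals}

    def plant(interval_ids: Sequence[str], n: int, labels: Sequence[str]) -> None:
        if not interval_ids or n == 0:
            return
        chosen = rng.choice(np.asarray(interval_ids), size=min(n, len(interval_ids)), replace=False)
        for iid in chosen:
            iv = coords[str(iid)]
            pos0 = (iv.start + iv.end) // 2
            ref = sequences[iv.chrom][pos0]
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            label = str(labels[int(rng.integers(0, len(labels)))])
            var = VariantRecord(
                chrom=iv.chrom, pos=pos0 + 1, ref=ref, alt=alt,
                clinical_significance=label,
                variant_label=f"{iv.chrom}:{pos0 + 1}{ref}>{alt}",
            )
            variants.append(var)
            target_map[var.variant_label] = str(iid)

    plant(
        planted_union,
        config.n_pathogenic_variants,
        ["Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic"],
    )
    plant(unplanted, config.n_benign_variants, ["Benign", "Uncertain_significance"])

    return SimulatedAnnotation(
        model=model,
        gene_lists=gene_lists,
        variants=variants,
        sequences=sequences,
        variant_target_intervals=target_map,
    )


def write_annotation(ann: SimulatedAnnotation, outdir: str | Path) -> dict[str, Path]:
    """Write GTF, gene-list TSVs, VCF and FASTA; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "genes.gtf",
        "omim": outdir / "omim.tsv",
        "sysndd": outdir / "sysndd.tsv",
        "vcf": outdir / "variants.vcf",
        "fasta": outdir / "genome.fa",
    }

    with open(paths["gtf"], "w") as fh:
        for gid in sorted(ann.model.genes):
            gene = ann.model.genes[gid]
            g_start = min(s for tx in gene.transcripts for s, _ in tx.cds)
            g_end = max(e for tx in gene.transcripts for _, e in tx.cds)
            attrs = f'gene_id "{gid}"; gene_name "{gene.gene_name}";'
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{g_start + 1}\t{g_end}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                t_attrs = attrs + f' transcript_id "{tx.transcript_id}";'
                t_start = min(s for s, _ in tx.cds)
                t_end = max(e for _, e in tx.cds)
                fh.write(
                    f"{gene.chrom}\tsim\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                    f"{gene.strand}\t.\t{t_attrs}\n"
                )
                for s, e in tx.cds:
                    fh.write(
                        f"{gene.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t{t_attrs}\n"
                    )

    for key, gl in (("omim", ann.gene_lists[0]), ("sysndd", ann.gene_lists[1])):
        with open(paths[key], "w") as fh:
            if key == "sysndd":
                fh.write("gene_symbol\tevidence\n")
                for g in sorted(gl.entries):
                    fh.write(f"{g}\t{gl.entries[g]}\n")
            else:
                fh.write("gene_symbol\n")
                for g in sorted(gl.entries):
                    fh.write(f"{g}\n")

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=CLNSIG,Number=.,Type=String,'
            'Description="Clinical significance">\n'
        )
        for chrom in sorted(ann.sequences, key=_chrom_key):
            fh.write(f"##contig=<ID={chrom},length={len(ann.sequences[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for var in sorted(ann.variants, key=lambda v: (_chrom_key(v.chrom), v.pos)):
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.variant_label}\t{var.ref}\t{var.alt}"
                f"\t.\t.\tCLNSIG={var.clinical_significance}\n"
            )

    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(ann.sequences, key=_chrom_key):
            fh.write(f">{chrom}\n")
            seq = ann.sequences[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return paths


def _chrom_key(chrom: str):
    tail = chrom.removeprefix("chr")
    return (0, int(tail)) if tail.isdigit() else (1, tail)
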