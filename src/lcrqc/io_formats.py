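"""Readers and writers for the external formats the pipeline consumes.

Every coordinate that enters the package is normalised to a single
convention: 0-based half-open, the BED convention. GTF input (1-based
inclusive) is shifted on read; VCF positions are shifted where they are
compared against intervals. The join key across samples is the literal
string ``"chrom:start-end"`` in internal coordinates (``interval_id``),
because every sample in a cohort is evaluated on the same target design
and identity must therefore be exact-coordinate.

Formats handled here:

* mosdepth-style per-interval mean-depth BED (one file per sample),
* target design BED (BED3+),
* a GTF subset with ``gene`` / ``transcript`` / ``CDS`` records,
* VCF 4.x with a clinical-significance INFO field,
* disease-gene lists as TSV (optionally carrying an evidence tier),
* a cohort manifest TSV (``sample_id  assay  batch_id  depth_path``),
* FASTA for per-interval GC content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .errors import FormatError, ValidationError

VALID_ASSAYS = ("ES", "GS")

_INTERVAL_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def make_interval_id(chrom: str, start: int, end: int) -> str:
    """Stable string key for an interval in internal 0-based half-open
    coordinates."""
    return f"{chrom}:{start}-{end}"


def parse_interval_id(interval_id: str) -> tuple[str, int, int]:
    """Invert :func:`make_interval_id`."""
    m = _INTERVAL_ID_RE.match(interval_id)
    if m is None:
        raise ValidationError(f"malformed interval_id {interval_id!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


@dataclass(frozen=True, order=True)
class TargetInterval:
    """One target region (typically a CDS interval) in 0-based half-open
    coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def interval_id(self) -> str:
        return make_interval_id(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


class TargetIntervalSet:
    """A sorted, de-duplicated collection of target intervals.

    This is the shared universe all samples of a cohort are evaluated on.
    Iteration order is (chrom, start, end).
    """

    def __init__(self, intervals: Iterable[TargetInterval], design_label: str = "design"):
        uniq = sorted(set(intervals))
        self.intervals: list[TargetInterval] = uniq
        self.design_label = design_label
        self._ids = [iv.interval_id for iv in uniq]
        self._id_set = frozenset(self._ids)

    @property
    def ids(self) -> list[str]:
        """interval_ids in sorted interval order."""
        return list(self._ids)

    @property
    def id_set(self) -> frozenset[str]:
        return self._id_set

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __contains__(self, interval_id: str) -> bool:
        return interval_id in self._id_set

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetIntervalSet) and self.intervals == other.intervals

    def build_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.interval_id)
        return trees

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


@dataclass
class DepthProfile:
    """Per-interval mean depth of coverage for one sample.

    ``depths`` is indexed by interval_id; values are mean DoC in x.
    """

    sample_id: str
    assay: str
    depths: pd.Series
    batch_id: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValidationError(
                f"sample {self.sample_id}: assay must be one of {VALID_ASSAYS}, got {self.assay!r}"
            )
        if (self.depths < 0).any():
            bad = self.depths.index[self.depths < 0][0]
            raise ValidationError(f"sample {self.sample_id}: negative depth at {bad}")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    cds: tuple[tuple[int, int], ...]  # genomic (start, end), sorted by start
    strand: str

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def cds_5prime_first(self) -> tuple[tuple[int, int], ...]:
        """CDS segments ordered 5' -> 3' in transcript orientation."""
        return self.cds if self.strand == "+" else tuple(reversed(self.cds))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass
class GeneModel:
    """Gene/transcript/CDS structure parsed from a GTF subset."""

    genes: dict[str, Gene]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    clinical_significance: str
    variant_label: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("variant ref/alt must be non-empty")

    @property
    def pos0(self) -> int:
        """Position in internal 0-based coordinates."""
        return self.pos - 1


@dataclass
class GeneList:
    """A disease-gene list keyed by gene symbol, optionally with an
    evidence tier per gene (e.g. definitive / moderate / limited)."""

    list_name: str
    entries: dict[str, str | None]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"gene list {self.list_name!r} is empty")

    def filtered(self, evidence_filter: set[str] | None) -> set[str]:
        """Gene symbols passing the evidence filter (all genes when the
        list carries no evidence or no filter is given)."""
        if evidence_filter is None:
            return set(self.entries)
        accepted = {e.lower() for e in evidence_filter}
        return {
            g
            for g, ev in self.entries.items()
            if ev is None or ev.lower() in accepted
        }


# ---------------------------------------------------------------------------
# Depth / target BED readers
# ---------------------------------------------------------------------------

def _parse_bed_row(line: str, lineno: int, path: str) -> tuple[str, int, int, list[str]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end <= start ({chrom}:{start}-{end})")
    return chrom, start, end, fields[3:]


def read_depth_bed(
    path: str | Path,
    sample_id: str,
    assay: str,
    batch_id: str | None = None,
) -> DepthProfile:
    """Read a mosdepth-regions-style BED of per-interval mean depths.

    With 4 columns, column 4 is the depth; with >= 5 columns, column 4 is
    a region name and the depth is the last numeric column.
    """
    path = str(path)
    ids: list[str] = []
    depths: list[float] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, rest = _parse_bed_row(line, lineno, path)
            if not rest:
                raise FormatError(f"{path}:{lineno}: missing depth column")
            try:
                depth = float(rest[-1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric depth {rest[-1]!r}") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            iid = make_interval_id(chrom, start, end)
            if iid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate interval {iid}")
            seen.add(iid)
            ids.append(iid)
            depths.append(depth)
    if not ids:
        raise FormatError(f"{path}: no intervals")
    return DepthProfile(
        sample_id=sample_id,
        assay=assay,
        batch_id=batch_id,
        depths=pd.Series(depths, index=ids, name=sample_id, dtype=float),
    )


def read_target_bed(path: str | Path, design_label: str = "design") -> TargetIntervalSet:
    """Read a BED3+ target design into a sorted, de-duplicated set."""
    path = str(path)
    intervals: list[TargetInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _ = _parse_bed_row(line, lineno, path)
            intervals.append(TargetInterval(chrom, start, end))
    if not intervals:
        raise FormatError(f"{path}: no intervals")
    return TargetIntervalSet(intervals, design_label=design_label)


# ---------------------------------------------------------------------------
# Gene model (GTF subset)
# ---------------------------------------------------------------------------

def read_gene_model(path: str | Path) -> GeneModel:
    """Parse a GTF subset (gene / transcript / CDS records) into a
    :class:`GeneModel`, converting coordinates to 0-based half-open.

    Parsing is delegated to :mod:`gffutils`; only gene, transcript and
    CDS features are consumed. CDS records must carry ``gene_id`` and
    ``transcript_id`` attributes.
    """
    import gffutils

    path = str(path)
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise FormatError(f"{path}: GTF parse failure: {exc}") from exc

    gene_meta: dict[str, dict] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    tx_info: dict[str, tuple[str, str, str]] = {}  # tx -> (gene_id, chrom, strand)

    def _attr(feat, key):
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    for feat in db.all_features():
        if feat.featuretype not in ("gene", "transcript", "CDS"):
            continue
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: {feat.featuretype} at {feat.seqid}:{feat.start}: "
                f"unknown strand {feat.strand!r}"
            )
        gid = _attr(feat, "gene_id")
        if gid is None:
            raise FormatError(f"{path}: {feat.featuretype} record missing gene_id")
        meta = gene_meta.setdefault(
            gid,
            {"gene_name": _attr(feat, "gene_name") or gid,
             "chrom": feat.seqid, "strand": feat.strand},
        )
        if _attr(feat, "gene_name"):
            meta["gene_name"] = _attr(feat, "gene_name")
        if feat.featuretype == "gene":
            continue
        tid = _attr(feat, "transcript_id")
        if tid is None:
            raise FormatError(f"{path}: {feat.featuretype} record missing transcript_id")
        tx_info.setdefault(tid, (gid, feat.seqid, feat.strand))
        if feat.featuretype == "CDS":
            # GTF is 1-based inclusive -> internal 0-based half-open
            tx_cds.setdefault(tid, []).append((feat.start - 1, feat.end))

    genes: dict[str, Gene] = {}
    by_gene: dict[str, list[Transcript]] = {}
    for tid, segs in tx_cds.items():
        gid, chrom, strand = tx_info[tid]
        segs_sorted = tuple(sorted(segs))
        for (s1, e1), (s2, _e2) in zip(segs_sorted, segs_sorted[1:]):
            if s2 < e1:
                raise FormatError(f"{path}: transcript {tid} has overlapping CDS segments")
        by_gene.setdefault(gid, []).append(Transcript(tid, segs_sorted, strand))
    for gid, txs in by_gene.items():
        meta = gene_meta[gid]
        genes[gid] = Gene(
            gene_id=gid,
            gene_name=meta["gene_name"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            transcripts=tuple(sorted(txs, key=lambda t: t.transcript_id)),
        )
    if not genes:
        raise FormatError(f"{path}: no transcripts with CDS found")
    return GeneModel(genes=genes)


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

def _significance_tokens(label: str) -> set[str]:
    """Normalise a (possibly compound) clinical-significance label to a
    token set: split on '/', '|' and ',', lowercase, spaces->underscores."""
    parts = re.split(r"[/|,]", label)
    return {p.strip().lower().replace(" ", "_") for p in parts if p.strip()}


def read_variants_vcf(
    path: str | Path,
    significance_filter: Iterable[str],
    significance_field: str = "CLNSIG",
) -> list[VariantRecord]:
    """Read a VCF keeping only records whose clinical significance matches
    the filter.

    Matching is token-based and case-insensitive: compound ClinVar labels
    like ``Pathogenic/Likely_pathogenic`` match either token. An empty
    filter returns no records.
    """
    accepted = {t for lab in significance_filter for t in _significance_tokens(lab)}
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if significance_field not in rec.info:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{significance_field}"
                )
            raw = rec.info[significance_field]
            label = ",".join(raw) if isinstance(raw, tuple) else str(raw)
            if not accepted or not (_significance_tokens(label) & accepted):
                continue
            alts = rec.alts or ()
            for alt in alts:
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        clinical_significance=label,
                        variant_label=rec.id or "",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Gene lists and manifest
# ---------------------------------------------------------------------------

def read_gene_list(
    path: str | Path,
    list_name: str,
    symbol_column: str = "gene_symbol",
    evidence_column: str | None = None,
) -> GeneList:
    """Read a TSV gene list. When ``evidence_column`` is given, the tier
    is stored per gene and usable for evidence filtering."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if symbol_column not in df.columns:
        raise FormatError(f"{path}: missing column {symbol_column!r}")
    if evidence_column is not None and evidence_column not in df.columns:
        raise FormatError(f"{path}: missing column {evidence_column!r}")
    entries: dict[str, str | None] = {}
    for _, row in df.iterrows():
        sym = row[symbol_column]
        if sym in entries:
            raise FormatError(f"{path}: duplicate gene symbol {sym!r}")
        entries[sym] = row[evidence_column] if evidence_column else None
    return GeneList(list_name=list_name, entries=entries)


MANIFEST_COLUMNS = ["sample_id", "assay", "batch_id", "depth_path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest TSV (sample_id, assay, batch_id, depth_path)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    dup = df.duplicated(subset=["sample_id", "assay"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (sample_id, assay) rows in manifest")
    return df[MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]]


def load_profiles(manifest: pd.DataFrame, base_dir: str | Path | None = None) -> list[DepthProfile]:
    """Load every depth profile referenced by a manifest."""
    base = Path(base_dir) if base_dir is not None else None
    profiles = []
    for _, row in manifest.iterrows():
        p = Path(row["depth_path"])
        if base is not None and not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ValidationError(f"sample {row['sample_id']}: depth file not found: {p}")
        batch = row["batch_id"] if pd.notna(row["batch_id"]) else None
        profiles.append(read_depth_bed(p, row["sample_id"], row["assay"], batch))
    return profiles


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def compute_gc(
    fasta_path: str | Path, intervals: TargetIntervalSet
) -> dict[str, float | None]:
    """Per-interval GC fraction from a FASTA.

    GC = (G+C)/(non-N length); case-insensitive. All-N intervals map to
    ``None`` (flagged missing rather than silently 0).
    """
    fasta = Fasta(str(fasta_path))
    missing_chroms = sorted({iv.chrom for iv in intervals} - set(fasta.keys()))
    if missing_chroms:
        raise ValidationError(f"chromosomes absent from FASTA: {missing_chroms}")
    out: dict[str, float | None] = {}
    for iv in intervals:
        seq = str(fasta[iv.chrom][iv.start : iv.end]).upper()
        denom = len(seq) - seq.count("N")
        out[iv.interval_id] = (seq.count("G") + seq.count("C")) / denom if denom else None
    return out
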