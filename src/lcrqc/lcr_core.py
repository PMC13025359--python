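"""Low-coverage-region calling.

An interval is a low-coverage region (LCR) for a sample when its mean
depth of coverage is strictly below the threshold (default 20x, the
conventional minimum for reliable germline heterozygous/homozygous
variant detection). A mean depth of exactly 20.0 is adequate coverage.

Intervals missing from a sample's profile are an error, never imputed as
depth 0 — zero-fill would manufacture LCRs, and a cohort is by
construction evaluated on one shared target design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    DepthProfile,
    TargetIntervalSet,
    parse_interval_id,
)

DEFAULT_THRESHOLD_X = 20.0
#: Sensitivity-analysis thresholds (primary first).
THRESHOLD_GRID = (20.0, 10.0, 30.0)


@dataclass(frozen=True)
class LcrCallSet:
    """The intervals flagged low-coverage for one sample at one threshold."""

    sample_id: str
    assay: str
    threshold_x: float
    lcr_ids: frozenset[str]
    universe_ids: frozenset[str]
    batch_id: str | None = None

    def __post_init__(self) -> None:
        if not self.lcr_ids <= self.universe_ids:
            stray = next(iter(self.lcr_ids - self.universe_ids))
            raise ValidationError(f"LCR id {stray} outside the evaluated universe")

    @property
    def universe_size(self) -> int:
        return len(self.universe_ids)


@dataclass
class BinaryLcrMatrix:
    """0/1 presence matrix: rows are interval_ids (sorted), columns are
    samples (manifest order). ``sample_meta`` carries assay and batch per
    sample_id."""

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    threshold_x: float

    @property
    def interval_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def columns_for(self, assay: str | None = None, batch_id: str | None = None) -> list[str]:
        """Sample columns matching an assay and/or batch filter."""
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if assay is not None:
            mask &= meta["assay"] == assay
        if batch_id is not None:
            mask &= meta["batch_id"] == batch_id
        return list(meta.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="interval_id")


def call_lcrs(
    profile: DepthProfile,
    universe: TargetIntervalSet,
    threshold_x: float = DEFAULT_THRESHOLD_X,
) -> LcrCallSet:
    """Flag every universe interval whose mean depth is strictly below
    ``threshold_x``."""
    if threshold_x <= 0:
        raise ValidationError(f"threshold_x must be positive, got {threshold_x}")
    missing = [i for i in universe.ids if i not in profile.depths.index]
    if missing:
        head = ", ".join(missing[:5])
        raise ValidationError(
            f"sample {profile.sample_id}: {len(missing)} universe intervals "
            f"missing from profile (first: {head})"
        )
    depths = profile.depths.loc[universe.ids]
    lcr = frozenset(depths.index[depths < threshold_x])
    return LcrCallSet(
        sample_id=profile.sample_id,
        assay=profile.assay,
        batch_id=profile.batch_id,
        threshold_x=threshold_x,
        lcr_ids=lcr,
        universe_ids=universe.id_set,
    )


def restrict_to_design(callset: LcrCallSet, design: TargetIntervalSet) -> LcrCallSet:
    """Restrict a call set to intervals overlapping (>= 1 bp) the design.

    Interval coordinates are recovered from the interval_id key, so the
    call set itself carries enough information for the overlap test.
    """
    if len(design) == 0:
        raise ValidationError("design is empty")
    trees = design.build_trees()

    def overlaps(interval_id: str) -> bool:
        chrom, start, end = parse_interval_id(interval_id)
        tree = trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    new_universe = frozenset(i for i in callset.universe_ids if overlaps(i))
    if not new_universe:
        raise ValidationError("design disjoint from universe")
    return replace(
        callset,
        lcr_ids=callset.lcr_ids & new_universe,
        universe_ids=new_universe,
    )


def lcr_fraction(callset: LcrCallSet) -> float:
    """Percent of evaluated intervals flagged as LCR."""
    if callset.universe_size == 0:
        raise ValidationError("universe is empty")
    return 100.0 * len(callset.lcr_ids) / callset.universe_size


def build_binary_matrix(callsets: Sequence[LcrCallSet]) -> BinaryLcrMatrix:
    """Assemble per-sample call sets into the cohort 0/1 matrix.

    All call sets must share one universe and one threshold. Row order is
    sorted interval_id; column order follows the input (manifest) order.
    """
    if not callsets:
        raise ValidationError("no call sets given")
    first = callsets[0]
    for cs in callsets[1:]:
        if cs.universe_ids != first.universe_ids:
            discordant = sorted(cs.universe_ids ^ first.universe_ids)[0]
            raise ValidationError(
                f"universes differ between {first.sample_id} and {cs.sample_id} "
                f"(first discordant interval: {discordant})"
            )
        if cs.threshold_x != first.threshold_x:
            raise ValidationError(
                f"thresholds differ: {first.threshold_x} vs {cs.threshold_x} "
                f"({cs.sample_id})"
            )
    rows = sorted(first.universe_ids)
    cols = [cs.sample_id for cs in callsets]
    if len(set(cols)) != len(cols):
        # a donor sequenced by both assays appears once per assay
        cols = [f"{cs.sample_id}.{cs.assay}" for cs in callsets]
    if len(set(cols)) != len(cols):
        raise ValidationError("duplicate (sample_id, assay) among call sets")
    mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
    row_index = {iid: r for r, iid in enumerate(rows)}
    for c, cs in enumerate(callsets):
        for iid in cs.lcr_ids:
            mat[row_index[iid], c] = 1
    meta = pd.DataFrame(
        {
            "sample_id": [cs.sample_id for cs in callsets],
            "assay": [cs.assay for cs in callsets],
            "batch_id": [cs.batch_id for cs in callsets],
        },
        index=pd.Index(cols, name="column"),
    )
    return BinaryLcrMatrix(
        data=pd.DataFrame(mat, index=pd.Index(rows, name="interval_id"), columns=cols),
        sample_meta=meta,
        threshold_x=first.threshold_x,
    )


def write_callset_bed(
    callset: LcrCallSet, profile: DepthProfile, path: str | Path
) -> None:
    """Export one call set as BED5 (chrom, start, end, sample_id, mean depth)."""
    rows = []
    for iid in sorted(callset.lcr_ids):
        chrom, start, end = parse_interval_id(iid)
        rows.append((chrom, start, end, callset.sample_id, profile.depths[iid]))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, sid, depth in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{sid}\t{depth:.2f}\n")
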