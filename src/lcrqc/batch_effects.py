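"""Batch-level systematic low-coverage detection.

Within a sequencing batch, depths are first capped at the LCR threshold
(any value >= 20x becomes 20x) so that the analysis is sensitive only to
undercoverage, never to how far above threshold well-covered intervals
sit. Capped depths are averaged across the batch's samples per interval,
and the resulting per-interval batch means are standardized into
z-scores. Intervals with z below the cutoff (default -1.96) are flagged
as systematic LCRs (sLCRs): intervals consistently undercovered across
the whole batch.

Standardization population
--------------------------
The per-interval capped batch means are standardized against the mean
and SD (n-1 denominator) of those means taken across *all intervals*
(``mode="interval_means"``, the default). A per-interval across-sample
z-score cannot flag an interval that is uniformly low in every sample of
the batch — yet those are exactly the systematic LCRs of interest — so
the across-interval reading is the self-consistent one. An alternative
``mode="pooled"`` standardizes the same batch means against the mean/SD
of all capped sample-by-interval depths pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import DepthProfile, TargetIntervalSet
from .lcr_core import BinaryLcrMatrix, DEFAULT_THRESHOLD_X

DEFAULT_Z_CUTOFF = -1.96
#: Sensitivity-analysis cutoffs (primary in the middle).
Z_CUTOFF_GRID = (-1.64, -1.96, -2.58)


def cap_depth(depth, threshold_x: float = DEFAULT_THRESHOLD_X):
    """Truncate depth(s) at the threshold: min(depth, threshold).

    Idempotent; accepts scalars or arrays.
    """
    if threshold_x <= 0:
        raise ValidationError(f"threshold_x must be positive, got {threshold_x}")
    return np.minimum(depth, threshold_x)


@dataclass
class BatchZScoreTable:
    """Capped-depth z-scores for one batch.

    ``table`` is indexed by interval_id with columns
    ``capped_batch_mean``, ``z`` and ``is_slcr``.
    """

    batch_id: str
    table: pd.DataFrame
    threshold_x: float
    z_cutoff: float
    n_samples: int

    @property
    def slcr_ids(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_slcr"]])

    @property
    def universe_ids(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def at_cutoff(self, z_cutoff: float) -> "BatchZScoreTable":
        """Re-flag sLCRs at a different cutoff without recomputing z."""
        tbl = self.table.copy()
        tbl["is_slcr"] = tbl["z"] < z_cutoff
        return BatchZScoreTable(
            batch_id=self.batch_id,
            table=tbl,
            threshold_x=self.threshold_x,
            z_cutoff=z_cutoff,
            n_samples=self.n_samples,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="interval_id")


def batch_zscores(
    profiles: Sequence[DepthProfile],
    universe: TargetIntervalSet,
    threshold_x: float = DEFAULT_THRESHOLD_X,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    mode: str = "interval_means",
) -> BatchZScoreTable:
    """Compute capped-depth z-scores and systematic-LCR flags for one batch."""
    if len(profiles) < 2:
        raise ValidationError("batch z-scores need >=2 samples")
    batch_ids = {p.batch_id for p in profiles}
    if len(batch_ids) != 1:
        raise ValidationError(f"profiles span multiple batches: {sorted(map(str, batch_ids))}")
    (batch_id,) = batch_ids
    if mode not in ("interval_means", "pooled"):
        raise ValidationError(f"unknown standardization mode {mode!r}")

    ids = universe.ids
    depth_mat = np.empty((len(ids), len(profiles)))
    for c, prof in enumerate(profiles):
        missing = set(ids) - set(prof.depths.index)
        if missing:
            raise ValidationError(
                f"sample {prof.sample_id}: {len(missing)} universe intervals missing"
            )
        depth_mat[:, c] = prof.depths.loc[ids].to_numpy()

    capped = cap_depth(depth_mat, threshold_x)
    batch_mean = capped.mean(axis=1)

    ref = batch_mean if mode == "interval_means" else capped.ravel()
    mu, sd = ref.mean(), ref.std(ddof=1)
    if sd == 0:
        raise ValidationError(
            f"degenerate batch {batch_id}: zero variance in capped batch means"
        )
    z = (batch_mean - mu) / sd

    table = pd.DataFrame(
        {
            "capped_batch_mean": batch_mean,
            "z": z,
            "is_slcr": z < z_cutoff,
        },
        index=pd.Index(ids, name="interval_id"),
    )
    return BatchZScoreTable(
        batch_id=str(batch_id),
        table=table,
        threshold_x=threshold_x,
        z_cutoff=z_cutoff,
        n_samples=len(profiles),
    )


@dataclass(frozen=True)
class ConsistencyReport:
    """Intra-batch LCR consistency: how many intervals have the same
    status (all-LCR or all-adequately-covered) across every sample of
    the batch."""

    batch_id: str
    n_consistent: int
    n_inconsistent: int

    @property
    def n_total(self) -> int:
        return self.n_consistent + self.n_inconsistent

    @property
    def percent_consistent(self) -> float:
        return percent_consistent(self.n_consistent, self.n_total, rounded=False)

    @property
    def percent_consistent_rounded(self) -> float:
        """Percent rounded to the nearest 0.5 point (report granularity)."""
        return percent_consistent(self.n_consistent, self.n_total, rounded=True)


def percent_consistent(n_consistent: int, n_total: int, rounded: bool = True) -> float:
    """100 * consistent / total, optionally rounded to the nearest 0.5."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    pct = 100.0 * n_consistent / n_total
    return round(pct * 2) / 2 if rounded else pct


def intra_batch_consistency(matrix: BinaryLcrMatrix, batch_id: str) -> ConsistencyReport:
    """Classify every interval of one batch as consistent (row all-0 or
    all-1 across the batch's samples) or inconsistent."""
    cols = matrix.columns_for(batch_id=batch_id)
    if len(cols) < 2:
        raise ValidationError(
            f"batch {batch_id}: consistency undefined with {len(cols)} sample(s)"
        )
    sub = matrix.data[cols].to_numpy()
    row_sums = sub.sum(axis=1)
    consistent = (row_sums == 0) | (row_sums == len(cols))
    return ConsistencyReport(
        batch_id=batch_id,
        n_consistent=int(consistent.sum()),
        n_inconsistent=int((~consistent).sum()),
    )


def consistency_table(matrix: BinaryLcrMatrix, batch_ids: Iterable[str]) -> pd.DataFrame:
    """Per-batch consistency report as a table (batch, percent,
    consistent, inconsistent, total)."""
    rows = []
    for b in batch_ids:
        rep = intra_batch_consistency(matrix, b)
        rows.append(
            {
                "batch": b,
                "percent_consistent": rep.percent_consistent_rounded,
                "consistent": rep.n_consistent,
                "inconsistent": rep.n_inconsistent,
                "total": rep.n_total,
            }
        )
    return pd.DataFrame(rows)


def inter_batch_venn(tables: Sequence[BatchZScoreTable]) -> dict[tuple[str, ...], int]:
    """Exact Venn decomposition of the batches' systematic-LCR sets.

    Keys are sorted batch-id tuples; the value counts intervals that are
    systematic in exactly those batches. Counts are disjoint and sum to
    the size of the union.
    """
    if len(tables) < 2:
        raise ValidationError("Venn decomposition needs >=2 batches")
    universes = {t.universe_ids for t in tables}
    if len(universes) != 1:
        raise ValidationError("batch z-score tables have differing universes")
    membership: dict[str, frozenset[str]] = {t.batch_id: t.slcr_ids for t in tables}
    if len(membership) != len(tables):
        raise ValidationError("duplicate batch_id among tables")
    union = set().union(*membership.values())
    counts: dict[tuple[str, ...], int] = {}
    batch_order = sorted(membership)
    for iid in union:
        key = tuple(b for b in batch_order if iid in membership[b])
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class ZScoreContrasts:
    """Kruskal–Wallis plus BH-adjusted pairwise rank-sum contrasts of the
    batches' sLCR-associated z-score distributions."""

    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame  # batch_a, batch_b, statistic, p_raw, p_bh
    excluded_batches: list[str] = field(default_factory=list)


def batch_zscore_contrasts(tables: Sequence[BatchZScoreTable]) -> ZScoreContrasts:
    """Test whether the z-score distributions of each batch's systematic
    LCRs differ across batches.

    Batches contributing fewer than 2 sLCR z-scores are excluded with a
    warning. Pairwise tests are two-sided Wilcoxon rank-sum
    (Mann–Whitney) with Benjamini–Hochberg adjustment.
    """
    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for t in tables:
        zs = t.table.loc[t.table["is_slcr"], "z"].to_numpy()
        if zs.size < 2:
            excluded.append(t.batch_id)
            warnings.warn(
                f"batch {t.batch_id}: <2 sLCR z-scores, excluded from contrasts",
                stacklevel=2,
            )
            continue
        groups[t.batch_id] = zs
    if len(groups) < 2:
        raise ValidationError("need >=2 batches with sLCR z-scores")

    kw = stats.kruskal(*groups.values())
    kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    if not np.isfinite(kw_p) and kw_stat <= 1e-9:
        # identical rank distributions: statistic rounds to <=0, p is 1
        kw_stat, kw_p = max(kw_stat, 0.0), 1.0
    rows = []
    for a, b in combinations(sorted(groups), 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"batch_a": a, "batch_b": b, "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_bh"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    return ZScoreContrasts(
        kruskal_stat=kw_stat,
        kruskal_p=kw_p,
        pairwise=pairwise,
        excluded_batches=excluded,
    )
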