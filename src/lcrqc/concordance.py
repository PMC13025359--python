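"""Exome-vs-genome concordance of low-coverage profiles.

For each donor sequenced by both assays, concordance between the two LCR
sets is the Jaccard coefficient |ES ∩ GS| / |ES ∪ GS|: 1 means the
assays flag identical intervals, values near 0 mean the assays fail in
largely different places. Cohort-level structure is examined with a PCA
of the binary interval × sample matrix, where samples are observations
and intervals are (centered, unscaled) features.

Statistical contracts
---------------------
* one-sample Wilcoxon signed-rank of per-donor Jaccard values against 1
  (one-sided, "less": are the profiles systematically discordant?),
  exact distribution when n <= 25 and no zero differences;
* paired Wilcoxon signed-rank of per-donor ES-only vs GS-only counts;
* Spearman rank correlation between those counts;
* Brown–Forsythe (median-centered Levene) test of count variance
  between assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ValidationError
from .lcr_core import BinaryLcrMatrix, LcrCallSet


def jaccard(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 when both sets are empty (no discordance
    exists between two empty low-coverage profiles)."""
    union = len(set_a | set_b)
    if union == 0:
        return 1.0
    return len(set_a & set_b) / union


@dataclass(frozen=True)
class PairedSampleConcordance:
    """ES/GS LCR overlap for one donor."""

    sample_id: str
    n_es_only: int
    n_gs_only: int
    n_shared: int
    jaccard: float


@dataclass
class ConcordanceSummary:
    """Cohort-level ES-vs-GS concordance report."""

    pairs: list[PairedSampleConcordance]
    median_jaccard: float
    wilcoxon_vs_one_p: float | None
    paired_wilcoxon_es_vs_gs_p: float | None
    spearman_rho: float
    levene_p: float
    pooled_n_es_only: int
    pooled_n_gs_only: int
    pooled_n_shared: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": p.sample_id,
                    "n_es_only": p.n_es_only,
                    "n_gs_only": p.n_gs_only,
                    "n_shared": p.n_shared,
                    "jaccard": p.jaccard,
                }
                for p in self.pairs
            ]
        )


def paired_concordance(es: LcrCallSet, gs: LcrCallSet) -> PairedSampleConcordance:
    """Three-way partition (ES-only / GS-only / shared) of one donor's
    LCR union, plus the Jaccard coefficient."""
    if es.sample_id != gs.sample_id:
        raise ValidationError(
            f"paired call sets must share sample_id ({es.sample_id} vs {gs.sample_id})"
        )
    if es.universe_ids != gs.universe_ids:
        raise ValidationError(f"sample {es.sample_id}: ES and GS universes differ")
    shared = es.lcr_ids & gs.lcr_ids
    return PairedSampleConcordance(
        sample_id=es.sample_id,
        n_es_only=len(es.lcr_ids - gs.lcr_ids),
        n_gs_only=len(gs.lcr_ids - es.lcr_ids),
        n_shared=len(shared),
        jaccard=jaccard(es.lcr_ids, gs.lcr_ids),
    )


def _wilcoxon(diffs: np.ndarray, alternative: str) -> float | None:
    """Wilcoxon signed-rank p-value; None when every difference is zero
    (the test is not applicable). Exact distribution for n <= 25 with no
    zeros, normal approximation with continuity correction otherwise."""
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return None
    method = "exact" if diffs.size <= 25 and nonzero.size == diffs.size else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diffs, alternative=alternative, method=method, correction=True)
    return float(res.pvalue)


def cohort_concordance(
    es_callsets: Mapping[str, LcrCallSet],
    gs_callsets: Mapping[str, LcrCallSet],
) -> ConcordanceSummary:
    """Per-donor concordance plus cohort statistics for a paired cohort.

    ``es_callsets`` / ``gs_callsets`` map sample_id to that donor's call
    set in each assay; donors present in both maps are paired.
    """
    shared_ids = [sid for sid in es_callsets if sid in gs_callsets]
    if len(shared_ids) < 2:
        raise ValidationError(f"need >=2 paired samples, found {len(shared_ids)}")
    pairs = [paired_concordance(es_callsets[sid], gs_callsets[sid]) for sid in shared_ids]

    jac = np.array([p.jaccard for p in pairs])
    es_counts = np.array([p.n_es_only for p in pairs], dtype=float)
    gs_counts = np.array([p.n_gs_only for p in pairs], dtype=float)

    # pooled partition over unique intervals across the whole cohort
    es_union: set[str] = set()
    gs_union: set[str] = set()
    for sid in shared_ids:
        es_union |= es_callsets[sid].lcr_ids
        gs_union |= gs_callsets[sid].lcr_ids

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(es_counts, gs_counts).statistic
        levene_p = stats.levene(es_counts, gs_counts, center="median").pvalue

    return ConcordanceSummary(
        pairs=pairs,
        median_jaccard=float(np.median(jac)),
        wilcoxon_vs_one_p=_wilcoxon(jac - 1.0, alternative="less"),
        paired_wilcoxon_es_vs_gs_p=_wilcoxon(es_counts - gs_counts, alternative="two-sided"),
        spearman_rho=float(rho) if np.isfinite(rho) else float("nan"),
        levene_p=float(levene_p),
        pooled_n_es_only=len(es_union - gs_union),
        pooled_n_gs_only=len(gs_union - es_union),
        pooled_n_shared=len(es_union & gs_union),
    )


def lcr_pca(matrix: BinaryLcrMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the principal components of the binary LCR
    matrix.

    Samples are observations, intervals are features; the matrix is
    column-centered (per interval) and not scaled. Returns per-sample
    coordinates (with assay/batch metadata) and the explained-variance
    fractions. Component signs are arbitrary.
    """
    X = matrix.data.to_numpy(dtype=float).T  # samples x intervals
    if X.shape[0] < 3:
        raise ValidationError(f"PCA needs >=3 samples, got {X.shape[0]}")
    if (X.var(axis=0) > 0).sum() < 2:
        raise ValidationError("no LCR variability: fewer than 2 variable intervals")
    k = min(n_components, X.shape[0] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    df = pd.DataFrame(
        coords,
        index=matrix.data.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    df.insert(0, "sample_id", matrix.sample_meta["sample_id"].values)
    df.insert(1, "assay", matrix.sample_meta["assay"].values)
    df.insert(2, "batch_id", matrix.sample_meta["batch_id"].values)
    df.index.name = "column"
    return df, pca.explained_variance_ratio_
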