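"""Mutation Enrichment Gene set Analysis (MEGA).

Given a gene set X and per-sample gene-level mutation counts for two cohorts
A and B, the per-sample burden is the total number of mutations in genes of
X. The burden distributions D_A and D_B are compared with a one-tailed
Wilcoxon rank-sum test (alternative: A enriched); across many gene sets the
p-values are Benjamini-Hochberg adjusted. When cohort sizes are very
unbalanced a bootstrap repeatedly down-samples the larger cohort (random
sampling with replacement) to the size of the smaller one and reports the
proportion of iterations reaching p < alpha.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import GeneSet, ValidationError, Variant
from .stats import bh_adjust, wilcoxon_rank_sum_one_tailed


@dataclass(frozen=True)
class SampleMutationProfile:
    """Per-gene mutation counts for one sample."""

    sample_id: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, n in self.counts.items():
            if n < 0 or n != int(n):
                raise ValidationError(
                    f"count for {gene} in {self.sample_id} must be a "
                    f"non-negative integer, got {n}"
                )

    @classmethod
    def from_variants(
        cls, sample_id: str, variants: Iterable[Variant]
    ) -> "SampleMutationProfile":
        """Count qualifying variants per gene (one variant = one mutation)."""
        counts: dict[str, int] = {}
        for v in variants:
            counts[v.gene] = counts.get(v.gene, 0) + 1
        return cls(sample_id=sample_id, counts=counts)


@dataclass(frozen=True)
class MegaResult:
    gene_set: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    p_value: float
    q_value: Optional[float] = None
    bootstrap_proportion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.q_value is not None and self.q_value < self.p_value - 1e-12:
            raise ValidationError("BH-adjusted q cannot be below p")
        if self.bootstrap_proportion is not None and not (
            0.0 <= self.bootstrap_proportion <= 1.0
        ):
            raise ValidationError("bootstrap proportion outside [0,1]")


def geneset_burden(gene_set: GeneSet, profile: SampleMutationProfile) -> int:
    """Total mutations of one sample within the genes of a set."""
    return sum(profile.counts.get(g, 0) for g in gene_set.members)


def burden_distribution(
    gene_set: GeneSet, cohort: Sequence[SampleMutationProfile]
) -> np.ndarray:
    """Per-sample burden vector (D_A or D_B) for a cohort."""
    return np.array([geneset_burden(gene_set, p) for p in cohort], dtype=float)


def mega_test(
    gene_set: GeneSet,
    cohort_a: Sequence[SampleMutationProfile],
    cohort_b: Sequence[SampleMutationProfile],
) -> float:
    """One-tailed p-value for cohort A being burden-enriched in the set."""
    if not cohort_a or not cohort_b:
        raise ValidationError("both cohorts must be non-empty")
    d_a = burden_distribution(gene_set, cohort_a)
    d_b = burden_distribution(gene_set, cohort_b)
    return wilcoxon_rank_sum_one_tailed(d_a, d_b).p_value


def mega_scan(
    gene_sets: Sequence[GeneSet],
    cohort_a: Sequence[SampleMutationProfile],
    cohort_b: Sequence[SampleMutationProfile],
) -> list[MegaResult]:
    """MEGA over many gene sets with BH correction across all of them."""
    if not gene_sets:
        raise ValidationError("at least one gene set is required")
    results = []
    for gs in gene_sets:
        d_a = burden_distribution(gs, cohort_a)
        d_b = burden_distribution(gs, cohort_b)
        p = wilcoxon_rank_sum_one_tailed(d_a, d_b).p_value
        results.append(
            MegaResult(
                gene_set=gs.name,
                n_a=len(cohort_a),
                n_b=len(cohort_b),
                median_a=float(np.median(d_a)),
                median_b=float(np.median(d_b)),
                p_value=p,
            )
        )
    qs = bh_adjust([r.p_value for r in results])
    return [
        MegaResult(
            gene_set=r.gene_set,
            n_a=r.n_a,
            n_b=r.n_b,
            median_a=r.median_a,
            median_b=r.median_b,
            p_value=r.p_value,
            q_value=float(q),
        )
        for r, q in zip(results, qs)
    ]


def mega_bootstrap(
    gene_set: GeneSet,
    cohort_a: Sequence[SampleMutationProfile],
    cohort_b: Sequence[SampleMutationProfile],
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Down-sampling bootstrap controlling for unequal cohort sizes.

    At each of ``n_iter`` iterations the larger cohort is resampled with
    replacement down to the size of the smaller one (the smaller cohort is
    held fixed) and the one-tailed test is repeated; the returned proportion
    is the fraction of iterations with p < ``alpha``. With equal cohort
    sizes there is nothing to down-sample and the indicator of the single
    test's significance is returned.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if not cohort_a or not cohort_b:
        raise ValidationError("both cohorts must be non-empty")
    d_a = burden_distribution(gene_set, cohort_a)
    d_b = burden_distribution(gene_set, cohort_b)
    if d_a.size == d_b.size:
        return float(wilcoxon_rank_sum_one_tailed(d_a, d_b).p_value < alpha)
    rng = np.random.default_rng(seed)
    if d_a.size > d_b.size:
        larger, smaller, a_is_larger = d_a, d_b, True
    else:
        larger, smaller, a_is_larger = d_b, d_a, False
    hits = 0
    for _ in range(n_iter):
        resampled = rng.choice(larger, size=smaller.size, replace=True)
        if a_is_larger:
            p = wilcoxon_rank_sum_one_tailed(resampled, smaller).p_value
        else:
            p = wilcoxon_rank_sum_one_tailed(smaller, resampled).p_value
        hits += p < alpha
    return hits / n_iter
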