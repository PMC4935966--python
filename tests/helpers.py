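"""Shared test helpers: record factories and brute-force statistical oracles.

The oracles are deliberately independent of the library implementations:
permutation enumeration for the rank-sum test, exact-integer hypergeometric
sums for Fisher's test, the literal step-up formula for BH, and per-base
counting for interval overlap.
"""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from syclone.model import Effect, PredictorCall, Variant, VariantKind


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    kind=VariantKind.SNV,
    effect=Effect.NONSYNONYMOUS,
    gene="TP53",
    alt_reads=50,
    total_reads=100,
    frac_plus=0.5,
    frac_minus=0.5,
    predictor_calls=(PredictorCall.MISSING,) * 5,
    maf_panels=(None, None),
):
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        kind=kind,
        effect=effect,
        gene=gene,
        alt_reads=alt_reads,
        total_reads=total_reads,
        frac_plus=frac_plus,
        frac_minus=frac_minus,
        predictor_calls=predictor_calls,
        maf_panels=maf_panels,
    )


def ranksum_enumeration_p(a, b) -> float:
    """Exact one-tailed rank-sum p (a greater) by permutation enumeration."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n, total = len(a), len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1  # tie-free data assumed
    w_obs = ranks[:n].sum()
    count = hits = 0
    for idx in itertools.combinations(range(total), n):
        hits += ranks[list(idx)].sum() >= w_obs
        count += 1
    return hits / count


def fisher_enumeration_p(table, alternative="two_sided") -> float:
    """Fisher 2x2 p by exact-integer hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    denom = comb(n, col1)
    probs = {
        k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
        for k in range(lo, hi + 1)
    }
    if alternative == "greater":
        p = sum(v for k, v in probs.items() if k >= a)
    else:
        p_obs = probs[a]
        p = sum(v for v in probs.values() if v <= p_obs)
    return float(min(p, 1))


def bh_step_up(p_values) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def per_base_overlap_fraction(gene_start, gene_end, regions) -> float:
    """Fraction of gene bases covered by any region, counted base by base."""
    covered = np.zeros(gene_end - gene_start, dtype=bool)
    for start, end in regions:
        for pos in range(max(start, gene_start), min(end, gene_end)):
            covered[pos - gene_start] = True
    return covered.mean()
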