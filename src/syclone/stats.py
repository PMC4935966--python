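"""Statistical primitives shared by the burden and expression analyses.

Three operations: a one-tailed Wilcoxon rank-sum test, Fisher's exact test on
a 2x2 table, and Benjamini-Hochberg FDR adjustment. Policy (exact versus
approximate branches, tie handling, continuity correction) is fixed here so
every caller tests the same hypothesis the same way.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined sample size at or below which the tie-free exact null is used
EXACT_SWITCHOVER = 20
#: Monte Carlo resamples for the tied-data permutation null
PERMUTATION_RESAMPLES = 9_999


def _permutation_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Monte Carlo permutation p-value of the rank-sum statistic.

    With ties the rank-sum null is discrete and the normal approximation is
    slightly liberal in the upper tail, so the null is sampled directly: the
    pooled mid-ranks are reassigned to the two groups uniformly at random.
    The (1 + hits) / (1 + resamples) estimator keeps the test valid. The
    generator is seeded from the pooled data, so equal inputs always give
    equal p-values.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    observed = ranks[: a.size].sum()
    # seed and resampling depend only on the sorted per-group values, so the
    # p-value is invariant to sample order within each cohort
    seed = np.random.SeedSequence(
        entropy=(
            zlib.crc32(np.sort(a).tobytes()),
            zlib.crc32(np.sort(b).tobytes()),
        )
    )
    rng = np.random.default_rng(seed)
    sorted_ranks = np.sort(ranks)
    idx = np.argsort(
        rng.random((PERMUTATION_RESAMPLES, pooled.size)), axis=1
    )[:, : a.size]
    perm = sorted_ranks[idx].sum(axis=1)
    hits = int((perm >= observed - 1e-9).sum())
    return (1 + hits) / (1 + PERMUTATION_RESAMPLES)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    alternative: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def wilcoxon_rank_sum_one_tailed(a, b) -> TestResult:
    """One-tailed Wilcoxon rank-sum test of ``a`` stochastically greater than ``b``.

    The exact permutation null is used when the combined sample size is at
    most ``EXACT_SWITCHOVER`` and the pooled data are tie-free; tie-free
    larger samples use a normal approximation with continuity correction.
    Tied data (where the normal approximation is slightly liberal in the
    upper tail) use a seeded Monte Carlo permutation null. Pooled data with
    zero rank variance (everything tied) carry no evidence in either
    direction and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        # degenerate: every observation tied across both samples
        return TestResult(
            statistic=float(a.size * b.size / 2),
            p_value=1.0,
            method="degenerate",
            alternative="greater",
        )
    if not ties and pooled.size <= EXACT_SWITCHOVER:
        res = sps.mannwhitneyu(a, b, alternative="greater", method="exact")
        p_value, method = float(res.pvalue), "exact"
        statistic = float(res.statistic)
    elif ties:
        p_value, method = _permutation_rank_sum_p(a, b), "permutation"
        statistic = float(
            sps.mannwhitneyu(a, b, alternative="greater").statistic
        )
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="greater", method="asymptotic", use_continuity=True
        )
        p_value, method = float(res.pvalue), "normal_approx"
        statistic = float(res.statistic)
    return TestResult(
        statistic=statistic,
        p_value=min(p_value, 1.0),
        method=method,
        alternative="greater",
    )


def fisher_exact_2x2(table, alternative: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    ``alternative`` is ``"two_sided"`` (tables as or less probable than the
    observed one under the hypergeometric null) or ``"greater"`` (enrichment
    of the top-left cell).
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if tab.sum() == 0:
        raise ValueError("table must contain at least one observation")
    alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    odds, p = sps.fisher_exact(tab.astype(int), alternative=alt)
    return TestResult(
        statistic=float(odds) if np.isfinite(odds) else float("inf"),
        p_value=float(min(p, 1.0)),
        method="fisher_exact",
        alternative=alternative,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
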