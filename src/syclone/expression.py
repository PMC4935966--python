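"""Expression-class assignment and per-gene-set class-fraction enrichment.

Each gene in each sample is placed in one of four classes from the sample's
own TPM distribution: not expressed (TPM < 0.1, taking precedence), highly
expressed (above the 75th percentile), lowly expressed (below the 25th) or
medium. For a gene set, the pooled (gene, sample) pairs in a class are
compared between two cohorts with Fisher's exact test; a bootstrap
repeatedly selects a size-matched subset of the larger cohort to control for
sample-size imbalance.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GeneSet, ValidationError
from .stats import bh_adjust, fisher_exact_2x2

#: TPM below which a gene counts as not expressed in a sample
NOT_EXPRESSED_TPM = 0.1
PERCENTILE_LOW = 25.0
PERCENTILE_HIGH = 75.0


class ExpressionClass(str, enum.Enum):
    NOT_EXPRESSED = "not_expressed"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True)
class ClassEnrichmentResult:
    gene_set: str
    expression_class: ExpressionClass
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: A, B; cols: in-class, not
    p_value: float
    q_value: Optional[float] = None
    bootstrap_proportion: Optional[float] = None


def tpm_from_scaled_estimates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert per-sample scaled-estimate values (summing to ~1) to TPM."""
    if matrix.unit == "TPM":
        return matrix
    return ExpressionMatrix(matrix.values * 1e6, unit="TPM")


def classify_expression_sample(tpms: Sequence[float]) -> list[ExpressionClass]:
    """Four-class expression labels for one sample's TPM vector.

    Percentiles are computed over the sample's full gene distribution
    (including genes later labelled not expressed); a gene is high/low only
    when strictly above/below the 75th/25th percentile, and the TPM < 0.1
    rule overrides the percentile classes.
    """
    x = np.asarray(tpms, dtype=float)
    if x.size < 4:
        raise ValidationError("need at least four genes to form quartiles")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValidationError("TPM values must be finite and >= 0")
    lo, hi = np.percentile(x, [PERCENTILE_LOW, PERCENTILE_HIGH])
    # np.full would coerce the str-enum fill value to a plain string
    labels = np.empty(x.size, dtype=object)
    labels[:] = ExpressionClass.MEDIUM
    labels[x > hi] = ExpressionClass.HIGH
    labels[x < lo] = ExpressionClass.LOW
    labels[x < NOT_EXPRESSED_TPM] = ExpressionClass.NOT_EXPRESSED
    return list(labels)


def classify_expression_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene x sample DataFrame of :class:`ExpressionClass` labels."""
    m = tpm_from_scaled_estimates(matrix)
    data = {
        sample: classify_expression_sample(m.values[sample].to_numpy())
        for sample in m.samples
    }
    return pd.DataFrame(data, index=m.genes)


def _class_counts(
    labels: pd.DataFrame, genes: Sequence[str], cls: ExpressionClass
) -> tuple[int, int]:
    sub = labels.loc[list(genes)]
    in_class = int((sub == cls).to_numpy().sum())
    return in_class, sub.size - in_class


def class_fraction_test(
    gene_set: GeneSet,
    labels_a: pd.DataFrame,
    labels_b: pd.DataFrame,
    cls: ExpressionClass,
    alternative: str = "two_sided",
) -> ClassEnrichmentResult:
    """Fisher's exact test comparing a class fraction between two cohorts.

    (gene, sample) pairs within the set are pooled across samples into a 2x2
    table (cohort x in-class/other), matching a cumulative-proportion
    comparison. Both label matrices must cover the same gene universe.
    """
    genes = sorted(g for g in gene_set.members if g in labels_a.index)
    if not genes:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no genes in the expression universe"
        )
    if not labels_a.index.equals(labels_b.index):
        raise ValidationError("cohorts must be labelled over the same gene universe")
    a_in, a_out = _class_counts(labels_a, genes, cls)
    b_in, b_out = _class_counts(labels_b, genes, cls)
    table = ((a_in, a_out), (b_in, b_out))
    p = fisher_exact_2x2(table, alternative=alternative).p_value
    return ClassEnrichmentResult(
        gene_set=gene_set.name, expression_class=cls, table=table, p_value=p
    )


def class_fraction_scan(
    gene_sets: Sequence[GeneSet],
    labels_a: pd.DataFrame,
    labels_b: pd.DataFrame,
    cls: ExpressionClass,
    alternative: str = "two_sided",
) -> list[ClassEnrichmentResult]:
    """Per-set class-fraction tests with BH correction across the sets."""
    if not gene_sets:
        raise ValidationError("at least one gene set is required")
    results = [
        class_fraction_test(gs, labels_a, labels_b, cls, alternative)
        for gs in gene_sets
    ]
    qs = bh_adjust([r.p_value for r in results])
    return [
        ClassEnrichmentResult(
            gene_set=r.gene_set,
            expression_class=r.expression_class,
            table=r.table,
            p_value=r.p_value,
            q_value=float(q),
        )
        for r, q in zip(results, qs)
    ]


def expression_bootstrap(
    gene_set: GeneSet,
    labels_a: pd.DataFrame,
    labels_b: pd.DataFrame,
    cls: ExpressionClass,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    alternative: str = "two_sided",
) -> float:
    """Size-matched bootstrap: repeatedly select |A| samples from the larger
    cohort B (without replacement within an iteration), re-run the class
    fraction test, and return the fraction of iterations with p < alpha."""
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    n_a, n_b = labels_a.shape[1], labels_b.shape[1]
    if n_b <= n_a:
        raise ValidationError("cohort B must be larger than cohort A")
    rng = np.random.default_rng(seed)
    cols = np.asarray(labels_b.columns)
    hits = 0
    for _ in range(n_iter):
        chosen = rng.choice(cols, size=n_a, replace=False)
        p = class_fraction_test(
            gene_set, labels_a, labels_b[chosen], cls, alternative
        ).p_value
        hits += p < alpha
    return hits / n_iter
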