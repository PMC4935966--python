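"""Synthetic-data generators with known ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes, so recovery can be scored automatically:

* multi-clone tumours — read counts of a heterozygous diploid mutation in a
  clone of cellular prevalence c at purity tc follow
  alt ~ Binomial(total, c*tc/2) with total ~ Poisson(depth);
* CNV segments — heterozygous-SNP allele frequencies mix normal cells
  (balanced), unaffected cancer cells (balanced) and affected cancer cells
  (allele ratio set by the copy number), with weights (1-tc), tc*(1-c),
  tc*c;
* cohort mutation profiles — per-sample per-gene counts are Poisson, with
  the rate multiplied in enriched sets for cohort A only. The default
  configuration reproduces the studied burden regime: 33 versus 406
  samples with mean per-sample burdens of 1.0 versus 0.3 in the enriched
  set;
* expression matrices — log-normal baseline TPM, with a chosen fraction of
  each suppressed set's genes forced below the 0.1 TPM "not expressed"
  cutoff in cohort A only (defaults emulate the observed 10% versus 3%
  not-expressed fractions).

One global integer seed drives named substreams, so adding a generator
never perturbs the output of another.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mega import SampleMutationProfile
from .model import (
    CNVSegment,
    Effect,
    ExpressionMatrix,
    GeneSet,
    TumourSample,
    ValidationError,
    Variant,
    VariantKind,
)

# Default study conditions for the cohort generators
MEGA_N_A = 33
MEGA_N_B = 406
MEGA_MEAN_BURDEN_A = 1.0
MEGA_MEAN_BURDEN_B = 0.3
EXPR_N_A = 14
EXPR_N_B = 193
#: log-normal baseline giving ~3% of genes below 0.1 TPM per sample
EXPR_LOG_MEAN = 1.5
EXPR_LOG_SD = 2.0
EXPR_SUPPRESSION_FRACTION = 0.10


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named, order-independent substream of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(stream.encode())))
    )


@dataclass(frozen=True)
class CloneSpec:
    """Ground-truth clone: cellular prevalence and private mutation count."""

    prevalence: float
    n_mutations: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValidationError(
                f"clone prevalence must be in [0,1], got {self.prevalence}"
            )
        if self.n_mutations < 0:
            raise ValidationError("mutation count must be >= 0")


def simulate_tumour(
    clones: Sequence[CloneSpec],
    tc: float,
    depth: float,
    seed: int,
    sample_id: str = "sim",
    chrom: str = "chr1",
) -> tuple[TumourSample, dict]:
    """Simulate one tumour's diploid heterozygous mutations.

    Returns the sample and a ground-truth record mapping every variant to
    the prevalence of its clone.
    """
    if not (0.0 < tc <= 1.0):
        raise ValidationError(f"purity must be in (0,1], got {tc}")
    if depth < 1:
        raise ValidationError("mean depth must be >= 1")
    rng = _rng(seed, f"tumour:{sample_id}")
    variants: list[Variant] = []
    truth_prevalence: list[float] = []
    pos = 0
    for clone in clones:
        p_alt = clone.prevalence * tc / 2.0
        for _ in range(clone.n_mutations):
            pos += 1000
            total = max(int(rng.poisson(depth)), 1)
            alt = int(rng.binomial(total, p_alt))
            if alt > 0:
                plus = int(rng.binomial(alt, 0.5))
                frac_plus = plus / alt
            else:
                frac_plus = 0.5
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=pos,
                    ref="A",
                    alt="T",
                    kind=VariantKind.SNV,
                    effect=Effect.NONSYNONYMOUS,
                    gene=f"G{pos // 1000:05d}",
                    alt_reads=alt,
                    total_reads=total,
                    frac_plus=frac_plus,
                    frac_minus=1.0 - frac_plus,
                )
            )
            truth_prevalence.append(clone.prevalence)
    sample = TumourSample(id=sample_id, tumour_content=tc, variants=variants)
    truth = {
        "sample_id": sample_id,
        "tumour_content": tc,
        "depth": depth,
        "clones": [
            {"prevalence": c.prevalence, "n_mutations": c.n_mutations}
            for c in clones
        ],
        "variant_prevalence": truth_prevalence,
    }
    return sample, truth


def simulate_cnv_segment(
    copy_number: int,
    clonality: float,
    tc: float,
    n_snps: int,
    depth: float,
    seed: int,
    chrom: str = "chr1",
    start: int = 0,
    end: int = 1_000_000,
    reliability: float = 95.0,
) -> tuple[CNVSegment, dict]:
    """Simulate the heterozygous-SNP allele frequencies of one CNV segment.

    Each SNP's expected tumour B-allele frequency mixes normal cells
    (1 B of 2 alleles), unaffected cancer cells (1 of 2) and affected cancer
    cells, whose B-copy count depends on which haplotype the copy-number
    change hit (chosen at random per SNP). A balanced diploid segment with
    positive clonality has no allelic imbalance to simulate and is rejected.
    """
    if copy_number == 2 and clonality > 0:
        raise ValidationError(
            "copy number 2 with positive clonality has no allelic imbalance"
        )
    if not (0.0 <= clonality <= 1.0):
        raise ValidationError(f"clonality must be in [0,1], got {clonality}")
    if not (0.0 < tc <= 1.0):
        raise ValidationError(f"purity must be in (0,1], got {tc}")
    if n_snps < 1:
        raise ValidationError("need at least one heterozygous SNP")
    rng = _rng(seed, f"cnv:{chrom}:{start}-{end}")
    w_normal, w_wt, w_mut = 1.0 - tc, tc * (1.0 - clonality), tc * clonality
    afs = []
    for _ in range(n_snps):
        b_hit = rng.random() < 0.5  # which haplotype the CNV affected
        if copy_number > 2:
            b_copies = copy_number - 1 if b_hit else 1
        elif copy_number == 1:
            b_copies = 0 if b_hit else 1
        elif copy_number == 0:
            b_copies = 0
        else:  # copy_number == 2, clonality == 0
            b_copies = 1
        num = w_normal * 1 + w_wt * 1 + w_mut * b_copies
        den = w_normal * 2 + w_wt * 2 + w_mut * copy_number
        p = num / den if den > 0 else 0.5
        total = max(int(rng.poisson(depth)), 1)
        afs.append(int(rng.binomial(total, p)) / total)
    seg = CNVSegment(
        chrom=chrom,
        start=start,
        end=end,
        copy_number=copy_number,
        reliability=reliability,
        het_snp_afs=tuple(afs),
    )
    truth = {
        "copy_number": copy_number,
        "clonality": clonality,
        "tumour_content": tc,
        "n_snps": n_snps,
        "depth": depth,
    }
    return seg, truth


# ---------------------------------------------------------------------------
# Cohort burden profiles


@dataclass(frozen=True)
class CohortSimConfig:
    """Ground-truth configuration for two cohorts of mutation profiles.

    With the defaults, a 20-gene set at per-gene rate 0.015 has mean
    per-sample burden 0.3; the enrichment multiplier 10/3 raises cohort A's
    burden in enriched sets to 1.0.
    """

    n_a: int = MEGA_N_A
    n_b: int = MEGA_N_B
    n_genes: int = 1000
    gene_sets: tuple[GeneSet, ...] = ()
    background_rate: float = 0.015
    enriched_multiplier: float = MEGA_MEAN_BURDEN_A / MEGA_MEAN_BURDEN_B
    enriched_sets: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValidationError("background rate must be >= 0")
        if self.enriched_multiplier < 1:
            raise ValidationError("enrichment multiplier must be >= 1")
        names = {gs.name for gs in self.gene_sets}
        unknown = set(self.enriched_sets) - names
        if unknown:
            raise ValidationError(f"enriched sets not defined: {sorted(unknown)}")


def make_disjoint_gene_sets(
    n_sets: int, set_size: int, n_genes: int, prefix: str = "SET"
) -> tuple[list[GeneSet], list[str]]:
    """Disjoint consecutive-block gene sets over a synthetic gene universe."""
    if n_sets * set_size > n_genes:
        raise ValidationError("gene universe too small for the requested sets")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    sets = [
        GeneSet.from_iterable(
            f"{prefix}{k:03d}", genes[k * set_size : (k + 1) * set_size]
        )
        for k in range(n_sets)
    ]
    return sets, genes


def simulate_mega_cohorts(
    cfg: CohortSimConfig,
) -> tuple[list[SampleMutationProfile], list[SampleMutationProfile], dict]:
    """Simulate per-sample gene-level mutation counts for two cohorts.

    Per-gene counts are Poisson(background rate), with the rate multiplied
    by the enrichment multiplier in enriched sets for cohort A only.
    """
    rng = _rng(cfg.seed, "mega-cohorts")
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    rates = np.full(cfg.n_genes, cfg.background_rate)
    gene_index = {g: i for i, g in enumerate(genes)}
    enriched_rates = rates.copy()
    for gs in cfg.gene_sets:
        if gs.name in cfg.enriched_sets:
            for g in gs.members:
                if g in gene_index:
                    enriched_rates[gene_index[g]] = (
                        cfg.background_rate * cfg.enriched_multiplier
                    )

    def _draw(n: int, rate_vec: np.ndarray, prefix: str) -> list[SampleMutationProfile]:
        profiles = []
        for i in range(n):
            counts = rng.poisson(rate_vec)
            nz = np.nonzero(counts)[0]
            profiles.append(
                SampleMutationProfile(
                    sample_id=f"{prefix}{i:04d}",
                    counts={genes[j]: int(counts[j]) for j in nz},
                )
            )
        return profiles

    cohort_a = _draw(cfg.n_a, enriched_rates, "A")
    cohort_b = _draw(cfg.n_b, rates, "B")
    truth = {
        "enriched_sets": list(cfg.enriched_sets),
        "background_rate": cfg.background_rate,
        "enriched_multiplier": cfg.enriched_multiplier,
        "n_a": cfg.n_a,
        "n_b": cfg.n_b,
    }
    return cohort_a, cohort_b, truth


# ---------------------------------------------------------------------------
# Expression matrices


def simulate_expression_cohorts(
    n_a: int = EXPR_N_A,
    n_b: int = EXPR_N_B,
    n_genes: int = 2000,
    suppressed_sets: Sequence[GeneSet] = (),
    suppression_fraction: float = EXPR_SUPPRESSION_FRACTION,
    seed: int = 0,
    gene_names: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Simulate TPM matrices with gene sets suppressed in cohort A.

    Baseline values are log-normal (about 3% of genes per sample fall below
    the 0.1 TPM cutoff). For each suppressed set, a random
    ``suppression_fraction`` of its genes is forced below 0.1 TPM in every
    cohort-A sample. Matrices are in TPM units directly; no per-sample
    renormalisation is applied since the class labels depend only on ranks
    and the absolute 0.1 cutoff.
    """
    if not (0.0 <= suppression_fraction <= 1.0):
        raise ValidationError("suppression fraction must be in [0,1]")
    rng = _rng(seed, "expression")
    if gene_names is None:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    else:
        genes = list(gene_names)
        n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    def _baseline(n: int, prefix: str) -> pd.DataFrame:
        vals = rng.lognormal(EXPR_LOG_MEAN, EXPR_LOG_SD, size=(n_genes, n))
        return pd.DataFrame(
            vals, index=genes, columns=[f"{prefix}{i:04d}" for i in range(n)]
        )

    mat_a = _baseline(n_a, "A")
    mat_b = _baseline(n_b, "B")
    suppressed_genes: dict[str, list[str]] = {}
    for gs in suppressed_sets:
        members = sorted(g for g in gs.members if g in gene_index)
        k = int(round(suppression_fraction * len(members)))
        chosen = list(rng.choice(members, size=k, replace=False)) if k else []
        suppressed_genes[gs.name] = chosen
        for g in chosen:
            mat_a.iloc[gene_index[g], :] = rng.uniform(0.0, 0.09, size=n_a)
    truth = {
        "suppressed_genes": suppressed_genes,
        "suppression_fraction": suppression_fraction,
        "n_a": n_a,
        "n_b": n_b,
    }
    return (
        ExpressionMatrix(mat_a, unit="TPM"),
        ExpressionMatrix(mat_b, unit="TPM"),
        truth,
    )
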