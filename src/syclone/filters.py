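"""Variant filters: tumour/normal read-support rules, replicate-round
merging, somatic subtraction, and the rare-damaging germline chain.

Thresholds default to the study values (10 supporting reads and VAF >= 5% in
tumours, two supporting reads in normals, 1% of supporting reads on each
strand, heterozygous/homozygous VAF windows for germline SNPs, population MAF
< 1%) and are exposed through :class:`FilterConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import Effect, PredictorCall, ValidationError, Variant

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class FilterConfig:
    tumour_min_alt_reads: int = 10
    tumour_min_vaf: float = 0.05
    normal_min_alt_reads: int = 2
    min_strand_fraction: float = 0.01
    germline_min_alt_reads: int = 10
    het_vaf_window: tuple[float, float] = (0.40, 0.60)
    hom_vaf_threshold: float = 0.90
    rare_maf_threshold: float = 0.01
    damaging_min_votes: int = 4
    #: treat a missing predictor call as an abstention, shrinking the
    #: denominator, instead of the default conservative non-damaging vote
    missing_predictor_abstains: bool = False
    cohort_artifact_fraction: float = 0.5
    #: require the >50% carrier fraction in every cohort separately instead
    #: of over the pooled samples
    cohort_artifact_per_cohort: bool = False


DEFAULT_CONFIG = FilterConfig()


@dataclass(frozen=True)
class FilterDecision:
    """Audit record for one variant against one rule chain."""

    key: VariantKey
    passed: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValidationError("passed must hold iff no rule failed")


def _strand_ok(v: Variant, cfg: FilterConfig) -> bool:
    if v.frac_plus is None or v.frac_minus is None:
        return False
    return min(v.frac_plus, v.frac_minus) >= cfg.min_strand_fraction


def pass_tumour_filters(v: Variant, cfg: FilterConfig = DEFAULT_CONFIG) -> FilterDecision:
    """Tumour call filter: >=10 supporting reads, VAF >=5%, >=1% of
    supporting reads on each strand."""
    failed = []
    if v.alt_reads < cfg.tumour_min_alt_reads:
        failed.append("min_alt_reads")
    if v.allele_frequency < cfg.tumour_min_vaf:  # raises on zero coverage
        failed.append("min_vaf")
    if not _strand_ok(v, cfg):
        failed.append("strand_balance")
    return FilterDecision(v.key, not failed, tuple(failed))


def pass_normal_filters(v: Variant, cfg: FilterConfig = DEFAULT_CONFIG) -> FilterDecision:
    """Matched-normal call filter: >=2 supporting reads, strand rule."""
    if v.total_reads == 0:
        raise ValidationError("allele frequency undefined with zero coverage")
    failed = []
    if v.alt_reads < cfg.normal_min_alt_reads:
        failed.append("min_alt_reads")
    if not _strand_ok(v, cfg):
        failed.append("strand_balance")
    return FilterDecision(v.key, not failed, tuple(failed))


def merge_sequencing_rounds(
    round1: Iterable[Variant], round2: Iterable[Variant], mode: str
) -> list[Variant]:
    """Merge two independent sequencing rounds of the same sample.

    Tumour rounds are intersected (a call must replicate); normal rounds are
    unioned (germline calls from either round are kept). Read counts of the
    merged record are taken from round1 where a variant occurs in both.
    """
    if mode not in ("tumour", "normal"):
        raise ValueError(f"mode must be 'tumour' or 'normal', got {mode!r}")
    r1 = list(round1)
    keys1 = {v.key for v in r1}
    keys2 = {v.key for v in round2}
    if mode == "tumour":
        return [v for v in r1 if v.key in keys2]
    extra = [v for v in round2 if v.key not in keys1]
    return r1 + extra


def subtract_germline(
    tumour: Iterable[Variant], normal: Iterable[Variant]
) -> list[Variant]:
    """Somatic calls: tumour variants absent from the matched normal."""
    normal_keys = {v.key for v in normal}
    return [v for v in tumour if v.key not in normal_keys]


def pass_germline_snp_filters(
    v: Variant, cfg: FilterConfig = DEFAULT_CONFIG
) -> FilterDecision:
    """Germline SNP filter: read support, strand rule, and a VAF compatible
    with a heterozygous (40-60%) or homozygous (>90%) genotype."""
    failed = []
    if v.alt_reads < cfg.germline_min_alt_reads:
        failed.append("min_alt_reads")
    f = v.allele_frequency
    lo, hi = cfg.het_vaf_window
    if not (lo <= f <= hi or f > cfg.hom_vaf_threshold):
        failed.append("genotype_vaf_window")
    if not _strand_ok(v, cfg):
        failed.append("strand_balance")
    return FilterDecision(v.key, not failed, tuple(failed))


def is_damaging(v: Variant, cfg: FilterConfig = DEFAULT_CONFIG) -> bool:
    """Damaging rule: stopgain/stoploss always; missense when at least four
    of the five predictors call it damaging.

    With ``missing_predictor_abstains`` the vote threshold scales with the
    number of available calls (ceil of 4/5 of them); by default a missing
    call counts as a non-damaging vote out of a fixed denominator of five.
    """
    if v.effect in (Effect.STOPGAIN, Effect.STOPLOSS):
        return True
    if v.effect is not Effect.NONSYNONYMOUS:
        return False
    damaging = sum(c is PredictorCall.DAMAGING for c in v.predictor_calls)
    if cfg.missing_predictor_abstains:
        available = sum(c is not PredictorCall.MISSING for c in v.predictor_calls)
        if available == 0:
            return False
        needed = -(-cfg.damaging_min_votes * available // 5)  # ceil
        return damaging >= needed
    return damaging >= cfg.damaging_min_votes


def is_rare(v: Variant, threshold: float | None = None,
            cfg: FilterConfig = DEFAULT_CONFIG) -> bool:
    """Rare rule: unobserved in every population panel, or every available
    panel MAF strictly below the threshold (default 1%)."""
    thr = cfg.rare_maf_threshold if threshold is None else threshold
    return all(maf is None or maf < thr for maf in v.maf_panels)


def cohort_artifact_filter(
    snps_by_sample: Mapping[str, Mapping[str, Iterable[VariantKey]]],
    panel_presence: Mapping[VariantKey, bool],
    cfg: FilterConfig = DEFAULT_CONFIG,
) -> set[VariantKey]:
    """Remove likely alignment artifacts: variant keys never seen in the
    population panels yet carried by more than half the samples.

    ``snps_by_sample`` maps cohort -> sample -> carried variant keys. The
    carrier fraction is computed over the pooled samples of all cohorts by
    default, or within every cohort separately with
    ``cohort_artifact_per_cohort``. Keys with ``panel_presence`` true are
    exempt (a variant seen in the general population is not an artifact).
    Returns the retained keys.
    """
    if not snps_by_sample or any(not c for c in snps_by_sample.values()):
        raise ValueError("every cohort must contain at least one sample")
    carriers: dict[VariantKey, dict[str, int]] = {}
    cohort_sizes = {c: len(samples) for c, samples in snps_by_sample.items()}
    all_keys: set[VariantKey] = set()
    for cohort, samples in snps_by_sample.items():
        for sample_keys in samples.values():
            for key in set(sample_keys):
                all_keys.add(key)
                carriers.setdefault(key, {}).setdefault(cohort, 0)
                carriers[key][cohort] += 1
    total = sum(cohort_sizes.values())
    retained: set[VariantKey] = set()
    for key in all_keys:
        if panel_presence.get(key, False):
            retained.add(key)
            continue
        per_cohort = carriers[key]
        if cfg.cohort_artifact_per_cohort:
            artifact = all(
                per_cohort.get(c, 0) / n > cfg.cohort_artifact_fraction
                for c, n in cohort_sizes.items()
            )
        else:
            artifact = sum(per_cohort.values()) / total > cfg.cohort_artifact_fraction
        if not artifact:
            retained.add(key)
    return retained


def rare_damaging_chain(
    variants: Iterable[Variant], cfg: FilterConfig = DEFAULT_CONFIG
) -> list[Variant]:
    """Full per-sample rare-damaging-SNP chain: germline call filter, then
    the damaging rule, then the population-rarity rule.

    The cross-cohort artifact filter operates on cohorts, not single
    samples, and is applied separately via :func:`cohort_artifact_filter`.
    """
    return [
        v
        for v in variants
        if pass_germline_snp_filters(v, cfg).passed
        and is_damaging(v, cfg)
        and is_rare(v, cfg=cfg)
    ]
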