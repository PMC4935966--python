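"""Copy-number post-processing: high-confidence aberrant regions, the
gene-level >=80% overlap rule, and putative-driver classification.

A segment is a high-confidence aberration when its copy number differs from
the diploid two, its reliability score exceeds 75%, and the allele
frequencies of its heterozygous SNPs depart from the normal distribution
expected of a balanced region (allelic imbalance). A gene is amplified or
deleted when at least 80% of its length is covered by aberrant regions of
that one direction.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .model import CNVSegment, GeneModel, GeneRole, TumourSample, ValidationError

#: minimum aberration reliability score (percent) for a confident call
RELIABILITY_THRESHOLD = 75.0
#: minimum fraction of a gene's length inside aberrant regions
OVERLAP_THRESHOLD = 0.8
#: minimum heterozygous SNPs for the normality screen
MIN_HET_SNPS = 3


class CNVStatus(str, enum.Enum):
    AMPLIFIED = "amplified"
    DELETED = "deleted"
    NEUTRAL = "neutral"


class DriverEvidence(str, enum.Enum):
    NONSILENT_MUTATION = "nonsilent_mutation"
    ONCOGENE_AMPLIFIED = "oncogene_amplified"
    TSG_DELETED = "tsg_deleted"


@dataclass(frozen=True)
class GeneCNVStatus:
    gene: str
    status: CNVStatus
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.status is not CNVStatus.NEUTRAL and self.overlap_fraction < OVERLAP_THRESHOLD:
            raise ValidationError(
                "non-neutral status requires overlap fraction >= 0.8"
            )


@dataclass(frozen=True)
class DriverCall:
    gene: str
    evidence: frozenset[DriverEvidence]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValidationError("a driver call needs at least one evidence type")


def is_high_confidence_region(
    seg: CNVSegment, alpha: float = 0.05
) -> bool:
    """Whether a segment qualifies as a high-confidence aberrant region.

    Requires copy number != 2, reliability > 75%, and a Shapiro-Wilk test
    rejecting normality of the heterozygous-SNP allele frequencies at
    ``alpha``. Segments with fewer than three SNPs (or constant AFs, where
    the test is undefined) fail the screen.
    """
    if seg.copy_number == 2 or seg.reliability <= RELIABILITY_THRESHOLD:
        return False
    afs = np.asarray(seg.het_snp_afs, dtype=float)
    if afs.size < MIN_HET_SNPS or np.ptp(afs) == 0.0:
        return False
    _, p = sps.shapiro(afs)
    return bool(p < alpha)


def _union_coverage(gene: GeneModel, regions: Iterable[CNVSegment]) -> int:
    """Bases of the gene covered by the union of the given regions."""
    clipped = []
    for r in regions:
        if r.chrom != gene.chrom:
            continue
        s, e = max(r.start, gene.start), min(r.end, gene.end)
        if s < e:
            clipped.append((s, e))
    if not clipped:
        return 0
    clipped.sort()
    covered = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered


def gene_cnv_status(gene: GeneModel, regions: Sequence[CNVSegment]) -> GeneCNVStatus:
    """Classify a gene from its overlap with high-confidence aberrant regions.

    Amplification (copy number > 2) and deletion (< 2) coverage accumulate
    separately, each as union coverage over possibly disjoint regions; the
    gene is called in a direction when that direction alone covers >= 80% of
    its length. If both directions qualify the larger fraction wins (ties go
    to amplification).
    """
    if gene.length == 0:
        raise ValidationError(f"gene {gene.symbol} has zero length")
    amp = _union_coverage(gene, (r for r in regions if r.copy_number > 2)) / gene.length
    dele = _union_coverage(gene, (r for r in regions if r.copy_number < 2)) / gene.length
    if amp >= OVERLAP_THRESHOLD and amp >= dele:
        return GeneCNVStatus(gene.symbol, CNVStatus.AMPLIFIED, amp)
    if dele >= OVERLAP_THRESHOLD:
        return GeneCNVStatus(gene.symbol, CNVStatus.DELETED, dele)
    return GeneCNVStatus(gene.symbol, CNVStatus.NEUTRAL, max(amp, dele))


def _in_recurrent_region(
    gene: GeneModel, recurrent_regions: Sequence[tuple[str, int, int]]
) -> bool:
    mid = gene.midpoint
    return any(
        chrom == gene.chrom and start <= mid < end
        for chrom, start, end in recurrent_regions
    )


def classify_putative_drivers(
    sample: TumourSample,
    cancer_genes: Sequence[GeneModel],
    recurrent_regions: Sequence[tuple[str, int, int]] = (),
    alpha: float = 0.05,
) -> list[DriverCall]:
    """Putative driver alterations in known cancer genes.

    A cancer gene is a putative driver when it (1) carries at least one
    nonsilent somatic mutation, or (2) is an oncogene amplified inside a
    recurrently modified region, or (3) a tumour suppressor deleted inside
    one. Recurrent-region membership is decided by the gene midpoint.
    """
    high_conf = [s for s in sample.segments if is_high_confidence_region(s, alpha)]
    mutated_genes = {v.gene for v in sample.variants if v.is_nonsilent}
    calls: list[DriverCall] = []
    for gene in cancer_genes:
        evidence: set[DriverEvidence] = set()
        if gene.symbol in mutated_genes:
            evidence.add(DriverEvidence.NONSILENT_MUTATION)
        status = gene_cnv_status(gene, high_conf).status
        if _in_recurrent_region(gene, recurrent_regions):
            if gene.role is GeneRole.ONCOGENE and status is CNVStatus.AMPLIFIED:
                evidence.add(DriverEvidence.ONCOGENE_AMPLIFIED)
            if gene.role is GeneRole.TUMOUR_SUPPRESSOR and status is CNVStatus.DELETED:
                evidence.add(DriverEvidence.TSG_DELETED)
        if evidence:
            calls.append(DriverCall(gene.symbol, frozenset(evidence)))
    return calls
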