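"""Tumour-content-corrected clonality and clone-composition classification.

The clonality of an alteration is the fraction of cancer cells carrying it.
For a heterozygous point mutation in a diploid region the raw allele
frequency f is first corrected for tumour content tc (f' = min(f/tc, 1)),
removing the wild-type alleles contributed by normal cells, and the
clonality is twice the corrected frequency (two alleles per cell). Corrected
frequencies above 1/2 (almost clonal) are treated as a mutation present on
one allele of every cancer cell plus a second-allele component: the allele
clonalities are (1, 2f' - 1) and the reported clonality saturates at 1,
which keeps the estimate continuous at f' = 1/2.

For a copy-number region the allelic imbalance of heterozygous SNPs is used
instead: the median SNP allele frequency is corrected to
f~' = 1/2 + (median - 1/2)/tc and clonality is twice its absolute deviation
from the balanced 1/2.

Tumours are labelled monoclonal, biclonal or polyclonal from the clonality
histogram of their somatic alterations (bins > 0.80, 0.35-0.80, < 0.35): the
largest bin wins, ties resolved toward the less clonal label.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .cnv import is_high_confidence_region
from .model import CNVSegment, TumourSample, ValidationError, Variant

#: clonality bin edges: low < LOW_EDGE <= mid <= HIGH_EDGE < high
LOW_EDGE = 0.35
HIGH_EDGE = 0.80


class AlterationType(str, enum.Enum):
    SNV = "SNV"
    INDEL = "InDel"
    AMPLIFICATION = "amplification"
    DELETION = "deletion"


class CloneLabel(str, enum.Enum):
    MONOCLONAL = "monoclonal"
    BICLONAL = "biclonal"
    POLYCLONAL = "polyclonal"


@dataclass(frozen=True)
class ClonalityEstimate:
    alteration_id: str
    alteration_type: AlterationType
    f: float
    f_corrected: float
    c: float
    allele_clonalities: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0):
            raise ValidationError(f"clonality {self.c} outside [0,1]")


@dataclass(frozen=True)
class ClonalityDensity:
    """Gaussian-kernel clonality density on [0,1] and per-bin expected counts."""

    grid: np.ndarray
    density: np.ndarray
    n: int
    bin_edges: tuple[float, ...]
    expected_counts: np.ndarray


@dataclass(frozen=True)
class CloneCompositionCall:
    low: int
    mid: int
    high: int
    label: CloneLabel

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.low, self.mid, self.high)


# ---------------------------------------------------------------------------
# Point mutations


def select_diploid_mutations(
    sample: TumourSample, alpha: float = 0.05, prescreened: bool = False
) -> list[Variant]:
    """Mutations usable for clonality: those outside amplified/deleted regions.

    CNVs change the allele-to-cell ratio, so only mutations in diploid
    territory obey the doubling rule. Aberrant regions are the sample
    segments passing the high-confidence screen (or all segments when
    ``prescreened``).
    """
    regions = [
        s
        for s in sample.segments
        if prescreened or is_high_confidence_region(s, alpha)
    ]
    return [
        v
        for v in sample.variants
        if not any(r.contains(v.chrom, v.pos) for r in regions)
    ]


def correct_allele_frequency(f: float, tc: float) -> float:
    """Remove the normal-cell wild-type contribution: f' = min(f/tc, 1)."""
    if not (0.0 < tc <= 1.0):
        raise ValidationError(f"tumour content must be in (0,1], got {tc}")
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"allele frequency {f} outside [0,1]")
    return min(f / tc, 1.0)


def mutation_clonality(
    f_corrected: float,
) -> tuple[float, Optional[tuple[float, float]]]:
    """Clonality of a point mutation from its corrected allele frequency.

    Returns ``(c, allele_clonalities)``; the allele pair is populated only in
    the almost-clonal branch f' > 1/2, as (1, 2f' - 1).
    """
    if not (0.0 <= f_corrected <= 1.0):
        raise ValidationError(f"corrected frequency {f_corrected} outside [0,1]")
    if f_corrected <= 0.5:
        return 2.0 * f_corrected, None
    c1, c2 = 1.0, 2.0 * f_corrected - 1.0
    return min(2.0 * f_corrected, 1.0), (c1, c2)


def estimate_mutation_clonalities(
    sample: TumourSample, alpha: float = 0.05, prescreened: bool = False
) -> list[ClonalityEstimate]:
    """Clonality estimates for all diploid-region SNVs/InDels of a sample."""
    estimates = []
    for v in select_diploid_mutations(sample, alpha=alpha, prescreened=prescreened):
        f = v.allele_frequency
        fc = correct_allele_frequency(f, sample.tumour_content)
        c, alleles = mutation_clonality(fc)
        atype = AlterationType.SNV if v.kind.value == "SNV" else AlterationType.INDEL
        estimates.append(
            ClonalityEstimate(
                alteration_id=f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
                alteration_type=atype,
                f=f,
                f_corrected=fc,
                c=c,
                allele_clonalities=alleles,
            )
        )
    return estimates


# ---------------------------------------------------------------------------
# Copy-number regions


def region_median_het_af(seg: CNVSegment, fold: bool = True) -> float:
    """Median tumour allele frequency of the segment's heterozygous SNPs.

    By default frequencies are mirrored about 1/2 first (mirrored-BAF
    convention): which of the two alleles a platform reports is arbitrary,
    so raw AFs of an imbalanced region form two clusters symmetric about
    1/2 and their plain median is unstable. Mirroring collapses the
    clusters; the downstream clonality depends only on |median - 1/2|, which
    mirroring leaves meaningful. ``fold=False`` gives the plain median.
    """
    if not seg.het_snp_afs:
        raise ValidationError("segment has no heterozygous-SNP allele frequencies")
    afs = np.asarray(seg.het_snp_afs, dtype=float)
    if fold:
        afs = np.maximum(afs, 1.0 - afs)
    return float(np.median(afs))


def cnv_clonality(median_af: float, tc: float) -> float:
    """Clonality of a CNV region from its median het-SNP allele frequency.

    The deviation of the median from the balanced 1/2 is scaled by 1/tc
    (normal cells are balanced and dilute the imbalance), then doubled:
    c = min(2 |f~' - 1/2|, 1) with f~' = 1/2 + (median - 1/2)/tc clipped to
    [0,1]. A balanced region gives c = 0 at any purity.
    """
    if not (0.0 < tc <= 1.0):
        raise ValidationError(f"tumour content must be in (0,1], got {tc}")
    if not (0.0 <= median_af <= 1.0):
        raise ValidationError(f"median AF {median_af} outside [0,1]")
    f_corr = min(max(0.5 + (median_af - 0.5) / tc, 0.0), 1.0)
    return min(2.0 * abs(f_corr - 0.5), 1.0)


def estimate_cnv_clonalities(
    sample: TumourSample, alpha: float = 0.05, prescreened: bool = False
) -> list[ClonalityEstimate]:
    """Clonality estimates for the sample's high-confidence CNV regions."""
    estimates = []
    for i, seg in enumerate(sample.segments):
        if not seg.het_snp_afs:
            continue
        if not prescreened and not is_high_confidence_region(seg, alpha):
            continue
        med = region_median_het_af(seg)
        c = cnv_clonality(med, sample.tumour_content)
        f_corr = min(max(0.5 + (med - 0.5) / sample.tumour_content, 0.0), 1.0)
        atype = (
            AlterationType.AMPLIFICATION
            if seg.copy_number > 2
            else AlterationType.DELETION
        )
        estimates.append(
            ClonalityEstimate(
                alteration_id=f"{seg.chrom}:{seg.start}-{seg.end}:{i}",
                alteration_type=atype,
                f=med,
                f_corrected=f_corr,
                c=c,
            )
        )
    return estimates


# ---------------------------------------------------------------------------
# Density and classification


def _nrd0_bandwidth(x: np.ndarray) -> float:
    """Normal-reference (Silverman) bandwidth, robust variant."""
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * x.size ** (-0.2)


def clonality_density(
    cs: Iterable[float],
    grid_size: int = 512,
    bandwidth: Optional[float] = None,
    bin_edges: Sequence[float] = (0.0, LOW_EDGE, HIGH_EDGE, 1.0),
) -> ClonalityDensity:
    """Gaussian-kernel density of clonality values on [0,1].

    The kernel density is evaluated on a regular grid and renormalised to
    integrate to one over [0,1] (trapezoid rule), so the expected count in a
    clonality interval I is E(I) = P(I) * n and the bin expectations sum to
    n. ``bandwidth`` overrides the normal-reference default.
    """
    x = np.asarray(list(cs), dtype=float)
    if x.size < 2:
        raise ValidationError("density estimation needs at least two values")
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("clonality values must lie in [0,1]")
    h = _nrd0_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    grid = np.linspace(0.0, 1.0, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    rho = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    total = np.trapezoid(rho, grid)
    rho = rho / total
    edges = np.asarray(bin_edges, dtype=float)
    expected = np.empty(edges.size - 1)
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        mask = (grid >= lo) & (grid <= hi)
        gx, gy = grid[mask], rho[mask]
        # extend to the exact edges by linear interpolation
        if gx.size == 0 or gx[0] > lo:
            gx = np.insert(gx, 0, lo)
            gy = np.insert(gy, 0, np.interp(lo, grid, rho))
        if gx[-1] < hi:
            gx = np.append(gx, hi)
            gy = np.append(gy, np.interp(hi, grid, rho))
        expected[i] = np.trapezoid(gy, gx) * x.size
    # exact partition: rescale so bin expectations sum to n
    expected *= x.size / expected.sum()
    return ClonalityDensity(
        grid=grid,
        density=rho,
        n=x.size,
        bin_edges=tuple(edges),
        expected_counts=expected,
    )


def classify_clone_composition(
    estimates: Sequence[ClonalityEstimate] | Sequence[float],
) -> CloneCompositionCall:
    """Label a tumour from the clonality histogram of its alterations.

    Bins: low c < 0.35, mid 0.35 <= c <= 0.80, high c > 0.80 (both edges
    belong to the mid bin). The largest bin decides the label; ties resolve
    toward the less clonal label (polyclonal over biclonal over monoclonal).
    """
    if len(estimates) == 0:
        raise ValidationError("cannot classify an empty set of alterations")
    cs = np.asarray(
        [e.c if isinstance(e, ClonalityEstimate) else float(e) for e in estimates]
    )
    low = int(np.sum(cs < LOW_EDGE))
    high = int(np.sum(cs > HIGH_EDGE))
    mid = cs.size - low - high
    # order: least clonal first, so argmax-with-ties picks the less clonal
    counts = {
        CloneLabel.POLYCLONAL: low,
        CloneLabel.BICLONAL: mid,
        CloneLabel.MONOCLONAL: high,
    }
    label = max(counts, key=lambda k: (counts[k], -list(counts).index(k)))
    return CloneCompositionCall(low=low, mid=mid, high=high, label=label)
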