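"""Core domain types shared by the whole pipeline.

Coordinate conventions: point alterations (variants) carry 1-based positions
(VCF convention); genomic intervals (CNV segments, gene models) are 0-based
half-open (BED convention). Converters for other dialects live in
:mod:`syclone.io`.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PREDICTORS = ("sift", "polyphen2", "mutation_taster", "mutation_assessor", "lrt")


class VariantKind(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class Effect(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT = "frameshift"
    NONFRAMESHIFT = "nonframeshift"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class PredictorCall(str, enum.Enum):
    """Tri-state in-silico damaging prediction for a missense variant."""

    DAMAGING = "D"
    BENIGN = "B"
    MISSING = "."


class GeneRole(str, enum.Enum):
    ONCOGENE = "oncogene"
    TUMOUR_SUPPRESSOR = "tumour_suppressor"
    OTHER = "other"
    UNKNOWN = "unknown"


NONSILENT_EFFECTS = frozenset(
    {
        Effect.NONSYNONYMOUS,
        Effect.STOPGAIN,
        Effect.STOPLOSS,
        Effect.FRAMESHIFT,
        Effect.NONFRAMESHIFT,
        Effect.SPLICING,
    }
)


class ValidationError(ValueError):
    """A record violates one of the domain invariants."""


@dataclass(frozen=True)
class Variant:
    """One SNV or InDel with its read support and annotations.

    ``frac_plus``/``frac_minus`` are the fractions of *supporting* (mutated)
    reads mapping on each DNA strand; they sum to 1 when both are present.
    ``predictor_calls`` holds the five damaging-predictor calls (SIFT,
    PolyPhen2, MutationTaster, MutationAssessor, LRT); ``maf_panels`` up to
    two population minor-allele frequencies, ``None`` meaning the variant was
    not observed in that panel.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    kind: VariantKind
    effect: Effect
    gene: str
    alt_reads: int
    total_reads: int
    frac_plus: Optional[float] = None
    frac_minus: Optional[float] = None
    predictor_calls: tuple[PredictorCall, ...] = (PredictorCall.MISSING,) * 5
    maf_panels: tuple[Optional[float], Optional[float]] = (None, None)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValidationError(
                f"need 0 <= alt_reads <= total_reads, got "
                f"{self.alt_reads}/{self.total_reads} at {self.chrom}:{self.pos}"
            )
        if len(self.predictor_calls) != 5:
            raise ValidationError("exactly five predictor calls are required")
        for fr in (self.frac_plus, self.frac_minus):
            if fr is not None and not (0.0 <= fr <= 1.0):
                raise ValidationError(f"strand fraction {fr} outside [0,1]")
        if (
            self.frac_plus is not None
            and self.frac_minus is not None
            and not math.isclose(self.frac_plus + self.frac_minus, 1.0, abs_tol=1e-6)
        ):
            raise ValidationError("frac_plus + frac_minus must equal 1")
        for maf in self.maf_panels:
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise ValidationError(f"population MAF {maf} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key (chrom, pos, ref, alt) used for set operations."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_frequency(self) -> float:
        """Raw VAF: mutated reads over total reads at the site."""
        if self.total_reads == 0:
            raise ValidationError(
                f"allele frequency undefined with zero coverage at "
                f"{self.chrom}:{self.pos}"
            )
        return self.alt_reads / self.total_reads

    @property
    def is_nonsilent(self) -> bool:
        return self.effect in NONSILENT_EFFECTS


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number segment with the tumour AFs of its heterozygous SNPs."""

    chrom: str
    start: int  # 0-based, half-open
    end: int
    copy_number: int
    reliability: float  # aberration reliability score, percent
    het_snp_afs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment start must be < end, got [{self.start},{self.end})"
            )
        if self.copy_number < 0:
            raise ValidationError("copy number must be non-negative")
        if not (0.0 <= self.reliability <= 100.0):
            raise ValidationError(
                f"reliability {self.reliability} outside [0,100]"
            )
        for af in self.het_snp_afs:
            if not (0.0 <= af <= 1.0):
                raise ValidationError(f"het-SNP AF {af} outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Whether the 1-based point position falls inside the segment."""
        return chrom == self.chrom and self.start < pos_1based <= self.end


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    role: GeneRole = GeneRole.UNKNOWN

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")
        if self.start >= self.end:
            raise ValidationError(
                f"gene start must be < end, got [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols (e.g. one KEGG pathway)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    @classmethod
    def from_iterable(cls, name: str, genes: Sequence[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(genes))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class TumourSample:
    """One tumour: purity, its variants and its copy-number segments."""

    id: str
    tumour_content: float
    variants: list[Variant] = field(default_factory=list)
    segments: list[CNVSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.tumour_content <= 1.0):
            raise ValidationError(
                f"tumour content must be in (0,1], got {self.tumour_content}"
            )


class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    ``unit`` is either ``"scaled_estimate"`` (per-sample values summing to
    ~1, as distributed for RNASeqV2 level-3 data) or ``"TPM"``.
    """

    def __init__(self, values: pd.DataFrame, unit: str = "TPM") -> None:
        if unit not in ("TPM", "scaled_estimate"):
            raise ValidationError(f"unknown expression unit {unit!r}")
        if values.index.has_duplicates:
            raise ValidationError("duplicate gene symbols in expression matrix")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValidationError("expression values must be finite and >= 0")
        self.values = values.astype(float)
        self.unit = unit

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, unit={self.unit})"
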