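"""Readers and writers for the plain-text formats the pipeline touches.

Formats: GMT gene sets (MSigDB dialect), a documented TSV variant table,
SEG-like TSV copy-number tables, BED gene models and TSV expression matrices.
All tables are tab-separated with a header (except GMT/BED, which have none).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .model import (
    CNVSegment,
    Effect,
    ExpressionMatrix,
    GeneModel,
    GeneRole,
    GeneSet,
    PredictorCall,
    ValidationError,
    Variant,
    VariantKind,
    PREDICTORS,
)

PathLike = Union[str, Path]

VARIANT_REQUIRED_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "kind",
    "effect",
    "gene",
    "alt_reads",
    "total_reads",
    "frac_plus",
    "frac_minus",
)
VARIANT_MAF_COLUMNS = ("maf_panel1", "maf_panel2")
SEGMENT_COLUMNS = ("chrom", "start", "end", "copy_number", "reliability", "het_snp_afs")

MISSING = "."


class ParseError(ValueError):
    """A file could not be parsed into valid records."""


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: PathLike) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...).

    Duplicate member symbols within a set are de-duplicated; a duplicate set
    name across lines is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name = fields[0]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            members = [g for g in fields[2:] if g]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet.from_iterable(name, members))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Variant tables


def _parse_optional_float(cell: object) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    if isinstance(cell, str):
        cell = cell.strip()
        if cell in ("", MISSING, "NA", "nan"):
            return None
    return float(cell)


def read_variant_table(path: PathLike) -> list[Variant]:
    """Read the documented TSV variant table into validated records.

    Required columns: chrom, pos, ref, alt, kind, effect, gene, alt_reads,
    total_reads, frac_plus, frac_minus. Optional: one column per predictor
    (sift, polyphen2, mutation_taster, mutation_assessor, lrt; values D/B/.)
    and maf_panel1/maf_panel2. Missing cells are written as ".".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    variants: list[Variant] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            calls = []
            for p in PREDICTORS:
                cell = row_d.get(p, MISSING).strip() or MISSING
                calls.append(PredictorCall(cell))
            variants.append(
                Variant(
                    chrom=row_d["chrom"],
                    pos=int(row_d["pos"]),
                    ref=row_d["ref"],
                    alt=row_d["alt"],
                    kind=VariantKind(row_d["kind"]),
                    effect=Effect(row_d["effect"]),
                    gene=row_d["gene"],
                    alt_reads=int(row_d["alt_reads"]),
                    total_reads=int(row_d["total_reads"]),
                    frac_plus=_parse_optional_float(row_d["frac_plus"]),
                    frac_minus=_parse_optional_float(row_d["frac_minus"]),
                    predictor_calls=tuple(calls),
                    maf_panels=(
                        _parse_optional_float(row_d.get("maf_panel1", MISSING)),
                        _parse_optional_float(row_d.get("maf_panel2", MISSING)),
                    ),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}: line {idx}: {exc}") from exc
    return variants


def write_variant_table(variants: Iterable[Variant], path: PathLike) -> None:
    cols = list(VARIANT_REQUIRED_COLUMNS) + list(PREDICTORS) + list(VARIANT_MAF_COLUMNS)
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "kind": v.kind.value,
                "effect": v.effect.value,
                "gene": v.gene,
                "alt_reads": v.alt_reads,
                "total_reads": v.total_reads,
                "frac_plus": MISSING if v.frac_plus is None else repr(v.frac_plus),
                "frac_minus": MISSING if v.frac_minus is None else repr(v.frac_minus),
                **{p: c.value for p, c in zip(PREDICTORS, v.predictor_calls)},
                "maf_panel1": MISSING if v.maf_panels[0] is None else repr(v.maf_panels[0]),
                "maf_panel2": MISSING if v.maf_panels[1] is None else repr(v.maf_panels[1]),
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG-like copy-number tables


def read_segments(path: PathLike, dialect: str = "bed") -> list[CNVSegment]:
    """Read a SEG-like TSV of copy-number segments.

    Columns: chrom, start, end, copy_number, reliability, het_snp_afs
    (semicolon-separated allele frequencies, "." for none).

    ``dialect`` names the coordinate convention of the *file*: ``"bed"``
    (0-based half-open, the internal convention) or ``"one_based_closed"``
    (1-based inclusive, as in many SEG exports); the latter is converted on
    the way in.
    """
    if dialect not in ("bed", "one_based_closed"):
        raise ParseError(f"unknown segment dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    segments: list[CNVSegment] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            start, end = int(row_d["start"]), int(row_d["end"])
            if dialect == "one_based_closed":
                start, end = start - 1, end
            afs_cell = row_d["het_snp_afs"].strip()
            afs: tuple[float, ...]
            if afs_cell in ("", MISSING):
                afs = ()
            else:
                afs = tuple(float(x) for x in afs_cell.split(";"))
            segments.append(
                CNVSegment(
                    chrom=row_d["chrom"],
                    start=start,
                    end=end,
                    copy_number=int(row_d["copy_number"]),
                    reliability=float(row_d["reliability"]),
                    het_snp_afs=afs,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}: line {idx}: {exc}") from exc
    return segments


def write_segments(
    segments: Iterable[CNVSegment], path: PathLike, dialect: str = "bed"
) -> None:
    if dialect not in ("bed", "one_based_closed"):
        raise ParseError(f"unknown segment dialect {dialect!r}")
    rows = []
    for s in segments:
        start, end = s.start, s.end
        if dialect == "one_based_closed":
            start, end = start + 1, end
        rows.append(
            {
                "chrom": s.chrom,
                "start": start,
                "end": end,
                "copy_number": s.copy_number,
                "reliability": repr(s.reliability),
                "het_snp_afs": ";".join(repr(a) for a in s.het_snp_afs) or MISSING,
            }
        )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED gene models


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene models from BED (chrom, start, end, symbol[, role])."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: BED gene model needs >=4 columns"
                )
            role = GeneRole.UNKNOWN
            if len(fields) >= 5 and fields[4] not in ("", MISSING):
                try:
                    role = GeneRole(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: unknown gene role {fields[4]!r}"
                    ) from exc
            try:
                genes.append(
                    GeneModel(
                        symbol=fields[3],
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        role=role,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t{g.role.value}\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_matrix(path: PathLike, unit: str = "TPM") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Run summaries


def write_run_summary(summary: dict, path: PathLike) -> None:
    """Write a JSON run summary (counts, parameters, outcomes)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
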