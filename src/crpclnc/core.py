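"""Domain types and file I/O shared by every pipeline stage.

All genomic coordinates are held internally as 0-based half-open intervals.
GTF (1-based, fully closed) is converted on read and write; BED is native.
The transcription start site (TSS) of a gene is strand-aware: ``start`` on
the "+" strand, ``end - 1`` on the "-" strand.

Gene annotations from the three source databases (RefSeq, GENCODE, NONCODE)
are merged into a single GTF whose attributes carry a ``database`` tag; the
tag governs the expression-filter threshold applied downstream (RPKM > 5 for
RefSeq, > 1 for GENCODE/NONCODE).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")
DATABASES = ("RefSeq", "GENCODE", "NONCODE")
BIOTYPES = ("coding", "noncoding")

COHORT_GROUPS = ("benign", "pca", "crpc")


class PipelineError(Exception):
    """Base class for all pipeline errors."""


class ParseError(PipelineError):
    """A file violated its format; message names the offending line."""


class ValidationError(PipelineError):
    """Semantically invalid input (coordinates, labels, universes)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS, exon structure, biotype and database tag.

    Exon lengths (not genomic span) define the length used for RPKM.
    """

    gene_id: str
    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str
    database: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.gene_id}: gene strand must be '+' or '-'"
            )
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.gene_id}: unknown biotype {self.biotype!r}"
            )
        if self.database not in DATABASES:
            raise ValidationError(
                f"{self.gene_id}: unknown database {self.database!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene has no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValidationError(
                    f"{self.gene_id}: exon on different chrom/strand"
                )
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(
                    f"{self.gene_id}: exon {ex.start}-{ex.end} outside gene "
                    f"interval {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        object.__setattr__(self, "exons", tuple(self.exons))

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def exonic_length(self) -> int:
        """Summed exon length in bp; the gene length used for RPKM."""
        return sum(ex.length for ex in self.exons)

    def flipped(self) -> "GeneModel":
        """The same model with the strand reversed (used in symmetry tests)."""
        flip = {"+": "-", "-": "+"}[self.interval.strand]
        return GeneModel(
            gene_id=self.gene_id,
            name=self.name,
            interval=replace(self.interval, strand=flip),
            exons=tuple(replace(ex, strand=flip) for ex in self.exons),
            biotype=self.biotype,
            database=self.database,
        )


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.score) or self.score < 0:
            raise ValidationError(f"peak score must be finite and >= 0")


@dataclass(frozen=True)
class PeakSet:
    """ChIP-seq peaks for one cell line / condition. Peaks are unstranded."""

    peaks: tuple[Peak, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.peaks, key=lambda p: (p.interval.chrom, p.interval.start))
        )
        object.__setattr__(self, "peaks", ordered)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SampleSheet:
    """sample_id -> (group label, library size) for one matrix."""

    entries: Mapping[str, tuple[str, int]]
    declared_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for sid, (group, lib) in self.entries.items():
            if self.declared_groups is not None and group not in self.declared_groups:
                raise ValidationError(
                    f"sample {sid}: group {group!r} not in declared set "
                    f"{self.declared_groups}"
                )
            if not (isinstance(lib, (int, np.integer)) and lib > 0):
                raise ValidationError(
                    f"sample {sid}: library size must be a positive integer"
                )
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries)

    def group_of(self, sample_id: str) -> str:
        return self.entries[sample_id][0]

    def library_size(self, sample_id: str) -> int:
        return self.entries[sample_id][1]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, (g, _) in self.entries.items() if g == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for _, (g, _) in self.entries.items():
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of counts or RPKM backed by a DataFrame."""

    values: pd.DataFrame
    unit: str  # "count" | "rpkm"

    def __post_init__(self) -> None:
        if self.unit not in ("count", "rpkm"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicated gene_id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("matrix contains NaN cells")
        if (arr < 0).any():
            raise ValidationError("matrix contains negative cells")
        if not np.isfinite(arr).all():
            raise ValidationError("matrix contains non-finite cells")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class Thresholds:
    """All tunable cut-offs of the discovery workflow.

    rpkm_min: per-database expression filter on the CRPC-group mean.
    alpha: significance level of the Mann-Whitney tests (no multiple-testing
        correction by default, matching the single P < 0.05 criterion).
    window_target_bp: peak-to-TSS window for protein-coding AR-target calling.
    window_lnc_bp: peak-to-TSS window for lncRNA candidate selection.
    fold_induced / fold_repressed: strict fold-change cut-offs on the
        pseudocounted mean ratio.
    """

    rpkm_min: Mapping[str, float] = field(
        default_factory=lambda: {"RefSeq": 5.0, "GENCODE": 1.0, "NONCODE": 1.0}
    )
    alpha: float = 0.05
    window_target_bp: int = 50_000
    window_lnc_bp: int = 10_000
    fold_induced: float = 1.5
    fold_repressed: float = 0.8
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if not (0 < self.fold_repressed < 1 < self.fold_induced):
            raise ValidationError("require fold_repressed < 1 < fold_induced")
        if self.window_target_bp <= 0 or self.window_lnc_bp <= 0:
            raise ValidationError("windows must be positive")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        for db, v in self.rpkm_min.items():
            if db not in DATABASES:
                raise ValidationError(f"unknown database {db!r} in rpkm_min")
            if v <= 0:
                raise ValidationError("rpkm_min values must be positive")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if "gene_id" not in attrs:
        raise ParseError(f"line {lineno}: missing gene_id attribute")
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a merged annotation GTF into :class:`GeneModel` objects.

    The GTF must carry ``gene`` and ``exon`` features whose attributes
    include ``gene_id``, ``biotype`` (coding/noncoding) and ``database``
    (RefSeq/GENCODE/NONCODE). Coordinates are converted from 1-based
    inclusive to the internal 0-based half-open convention. Models are
    returned sorted by (chrom, start, gene_id).
    """
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates")
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"line {lineno}: invalid 1-based coordinates {start1}-{end1}"
                )
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: invalid strand {strand!r}")
            if feature not in ("gene", "exon"):
                continue
            attrs = _parse_attributes(attr_s, lineno)
            gid = attrs["gene_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "gene":
                if gid in gene_rows:
                    raise ParseError(f"line {lineno}: duplicate gene_id {gid!r}")
                for key in ("biotype", "database"):
                    if key not in attrs:
                        raise ParseError(
                            f"line {lineno}: missing {key} attribute for {gid!r}"
                        )
                gene_rows[gid] = {
                    "interval": iv,
                    "name": attrs.get("gene_name", gid),
                    "biotype": attrs["biotype"],
                    "database": attrs["database"],
                }
            else:
                exon_rows.setdefault(gid, []).append(iv)
    models: list[GeneModel] = []
    for gid, row in gene_rows.items():
        exons = exon_rows.get(gid)
        if not exons:
            raise ValidationError(f"gene {gid!r} has no exon features")
        exons = sorted(exons, key=lambda e: e.start)
        models.append(
            GeneModel(
                gene_id=gid,
                name=row["name"],
                interval=row["interval"],
                exons=tuple(exons),
                biotype=row["biotype"],
                database=row["database"],
            )
        )
    orphans = set(exon_rows) - set(gene_rows)
    if orphans:
        raise ValidationError(
            f"exon features without gene feature: {sorted(orphans)[:5]}"
        )
    models.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return models


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive), inverse of read_gtf."""
    ordered = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    with open(path, "w") as fh:
        for g in ordered:
            iv = g.interval
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                f'biotype "{g.biotype}"; database "{g.database}";'
            )
            fh.write(
                f"{iv.chrom}\tcrpclnc\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{iv.chrom}\tcrpclnc\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, source_label: str = "") -> PeakSet:
    """Read a BED3+ peak file (0-based half-open; optional 5th column score)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates")
            if start < 0:
                raise ValidationError(f"line {lineno}: negative coordinate")
            if start >= end:
                raise ValidationError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            score = 0.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric score")
            peaks.append(Peak(GenomicInterval(chrom, start, end, "."), score))
    label = source_label or Path(path).stem
    return PeakSet(peaks=tuple(peaks), source_label=label)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{peaks.source_label or 'peak'}_{i + 1}\t{p.score:g}\n"
            )


# ---------------------------------------------------------------------------
# TSV matrices and sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(
    path: str | Path, declared_groups: tuple[str, ...] | None = None
) -> SampleSheet:
    """Read a sample sheet TSV with columns sample_id, group, library_size."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group", "library_size"):
        if col not in df.columns:
            raise ParseError(f"sample sheet {path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"sample sheet {path}: duplicated sample_id")
    entries = {
        row.sample_id: (row.group, int(row.library_size))
        for row in df.itertuples()
    }
    return SampleSheet(entries=entries, declared_groups=declared_groups)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tlibrary_size\n")
        for sid, (group, lib) in sheet.entries.items():
            fh.write(f"{sid}\t{group}\t{lib}\n")


def read_matrix(
    path: str | Path, sheet: SampleSheet, unit: str = "count"
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene_id) aligned to a sheet."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"matrix {path}: duplicated gene_id {dup!r}")
    matrix_samples = list(df.columns)
    sheet_samples = sheet.sample_ids
    extra = [s for s in matrix_samples if s not in sheet.entries]
    if extra:
        raise ValidationError(
            f"matrix {path}: sample {extra[0]!r} absent from sample sheet"
        )
    missing = [s for s in sheet_samples if s not in matrix_samples]
    if missing:
        raise ValidationError(
            f"matrix {path}: sheet sample {missing[0]!r} missing from matrix"
        )
    df = df[sheet_samples]
    return ExpressionMatrix(values=df, unit=unit)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    if matrix.unit == "count":
        df = df.astype(int)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.6g")
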