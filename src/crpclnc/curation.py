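"""Curation of bona fide lncRNAs and their genomic context.

Many database-registered lncRNAs simply re-annotate exons of protein-coding
genes; in stranded RNA-seq such transcripts cannot be distinguished from
the coding mRNA, so any candidate whose exon overlaps a same-strand coding
exon is excluded. Because the libraries are directional, opposite-strand
exon overlap IS distinguishable and never triggers exclusion.

Kept candidates are classified by genomic context:

* antisense  - the candidate's gene body overlaps a coding gene on the
  opposite strand;
* intergenic - no coding gene-body overlap on either strand;
* other      - same-strand gene-body overlap without exonic overlap
  (sense/intronic/overlapping transcripts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .core import GeneModel, ValidationError


@dataclass(frozen=True)
class OverlapEvidence:
    coding_gene_id: str
    same_strand: bool
    overlap_bp: int
    exonic: bool


@dataclass(frozen=True)
class LncContextCall:
    gene_id: str
    verdict: str  # kept | excluded_exonic
    context: str | None  # antisense | intergenic | other (kept only)
    evidence: tuple[OverlapEvidence, ...]


class _CodingIndex:
    """Interval-tree index over coding gene bodies and exons."""

    def __init__(self, coding: Sequence[GeneModel]):
        self.bodies: dict[str, IntervalTree] = {}
        self.exons: dict[tuple[str, str], IntervalTree] = {}
        for g in coding:
            if g.biotype != "coding":
                raise ValidationError(
                    f"{g.gene_id}: coding index given a non-coding gene"
                )
            iv = g.interval
            self.bodies.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, g
            )
            key = (iv.chrom, iv.strand)
            tree = self.exons.setdefault(key, IntervalTree())
            for ex in g.exons:
                tree.addi(ex.start, ex.end, g)

    def body_hits(self, gene: GeneModel) -> list[GeneModel]:
        tree = self.bodies.get(gene.interval.chrom)
        if tree is None:
            return []
        hits = {h.data.gene_id: h.data
                for h in tree.overlap(gene.interval.start, gene.interval.end)}
        return [hits[k] for k in sorted(hits)]

    def exonic_overlap_bp(self, gene: GeneModel) -> dict[str, int]:
        """Same-strand coding-exon overlap bp, summed per coding gene."""
        tree = self.exons.get((gene.interval.chrom, gene.interval.strand))
        out: dict[str, int] = {}
        if tree is None:
            return out
        for ex in gene.exons:
            for h in tree.overlap(ex.start, ex.end):
                bp = min(ex.end, h.end) - max(ex.start, h.begin)
                if bp > 0:
                    out[h.data.gene_id] = out.get(h.data.gene_id, 0) + bp
        return out


def _curate_one(
    candidate: GeneModel,
    index: _CodingIndex,
    min_overlap_fraction: float,
) -> LncContextCall:
    if candidate.biotype != "noncoding":
        raise ValidationError(
            f"{candidate.gene_id}: curation candidate must be noncoding"
        )
    exon_bp = index.exonic_overlap_bp(candidate)
    body_hits = index.body_hits(candidate)

    evidence = []
    for g in body_hits:
        evidence.append(
            OverlapEvidence(
                coding_gene_id=g.gene_id,
                same_strand=g.interval.strand == candidate.interval.strand,
                overlap_bp=candidate.interval.overlap_bp(g.interval),
                exonic=g.gene_id in exon_bp,
            )
        )
    evidence = tuple(evidence)

    # exclusion: same-strand exonic overlap of at least 1 bp (or the
    # configured fraction of the candidate's exonic length, if larger)
    min_bp = max(1, int(min_overlap_fraction * candidate.exonic_length))
    if any(bp >= min_bp for bp in exon_bp.values()):
        return LncContextCall(candidate.gene_id, "excluded_exonic", None, evidence)

    opposite = any(not e.same_strand for e in evidence)
    if opposite:
        context = "antisense"
    elif not evidence:
        context = "intergenic"
    else:
        context = "other"
    return LncContextCall(candidate.gene_id, "kept", context, evidence)


def curate_lnc(
    candidate: GeneModel,
    coding: Sequence[GeneModel],
    min_overlap_fraction: float = 0.0,
) -> LncContextCall:
    """Curate a single noncoding candidate against the coding annotation."""
    return _curate_one(candidate, _CodingIndex(coding), min_overlap_fraction)


def curate_all(
    candidates: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    min_overlap_fraction: float = 0.0,
) -> tuple[list[LncContextCall], Counter]:
    """Curate every candidate; returns calls plus verdict/context counts.

    Summary keys are ``excluded_exonic`` and the three kept contexts.
    """
    index = _CodingIndex(coding)
    calls = [_curate_one(c, index, min_overlap_fraction) for c in candidates]
    summary: Counter = Counter()
    for call in calls:
        summary[call.context if call.verdict == "kept" else "excluded_exonic"] += 1
    return calls, summary
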