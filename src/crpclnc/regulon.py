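"""AR regulon integration: ChIP-seq binding, fold-change calls, candidate funnel.

A gene is AR-bound when an AR ChIP-seq peak lies within a window of its TSS
(50 kb for protein-coding AR-target calling, 10 kb for lncRNA candidate
selection). Distance is interval-to-point: 0 when the TSS falls inside the
peak, otherwise the distance to the nearer peak edge. By default each peak
is first assigned to its closest-TSS gene(s) (all ties) and only an
assigned peak can bind a gene; ``require_closest=False`` relaxes to a pure
window criterion.

Regulation is called from pseudocounted mean-RPKM fold changes between two
conditions. For the androgen contrast (DHT vs vehicle) fold > 1.5 means
androgen-induced and fold < 0.8 androgen-repressed; for the knockdown
contrast (siAR vs siControl) the reading inverts: fold < 0.8 means the gene
is AR-induced, fold > 1.5 AR-repressed. The stored ``call`` is always the
direction of AR/androgen regulation of the gene (induced/repressed).

AR-target genes are those both bound (50 kb) and regulated; the lncRNA
funnel then narrows curated CRPC-upregulated lncRNAs to those with any
regulation call and AR binding within 10 kb of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    SampleSheet,
    Thresholds,
    ValidationError,
)

CONTRASTS = {
    # contrast -> (control label, treated label)
    "DHT_vs_vehicle": ("vehicle", "DHT"),
    "siAR_vs_siControl": ("siControl", "siAR"),
}

# conventional contrast per prostate cancer model cell line: the androgen-
# dependent lines are assayed by DHT stimulation, the CRPC model (which
# expresses the ligand-independent AR-V7 variant) by AR knockdown
CONTRAST_OF_LINE_DEFAULT = {
    "LNCaP": "DHT_vs_vehicle",
    "VCaP": "DHT_vs_vehicle",
    "22Rv1": "siAR_vs_siControl",
}


@dataclass(frozen=True)
class BindingCall:
    gene_id: str
    bound: bool
    nearest_peak_distance_bp: int | None
    supporting_peaks: tuple[int, ...]
    window_bp: int


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    cell_line: str
    contrast: str
    fold: float
    call: str  # induced | repressed | unchanged (direction of AR regulation)
    ar_target: bool | None = None

    @property
    def regulated(self) -> bool:
        return self.call != "unchanged"


def peak_tss_distance(peak_start: int, peak_end: int, tss: int) -> int:
    """Distance between a peak interval and a TSS point (0 if inside)."""
    if peak_start <= tss < peak_end:
        return 0
    return min(abs(peak_start - tss), abs(peak_end - 1 - tss))


def assign_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    window_bp: int,
    require_closest: bool = True,
) -> list[BindingCall]:
    """Assign peaks to genes by TSS proximity and call binding per gene.

    Each peak is assigned to the gene(s) whose TSS is nearest (all genes
    tied at the minimum distance). A gene is bound iff some assigned peak
    (or, with ``require_closest=False``, any peak) lies within
    ``window_bp`` of its TSS. Returns one call per input gene, in order.
    """
    if not genes:
        raise ValidationError("assign_peaks: empty gene list")
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")

    n_genes = len(genes)
    nearest = [None] * n_genes
    supporting: list[list[int]] = [[] for _ in range(n_genes)]

    gene_idx_by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        gene_idx_by_chrom.setdefault(g.interval.chrom, []).append(i)

    peak_idx_by_chrom: dict[str, list[int]] = {}
    for j, p in enumerate(peaks.peaks):
        peak_idx_by_chrom.setdefault(p.interval.chrom, []).append(j)

    for chrom, gidx in gene_idx_by_chrom.items():
        pidx = peak_idx_by_chrom.get(chrom)
        if not pidx:
            continue
        tss = np.array([genes[i].tss for i in gidx], dtype=np.int64)
        starts = np.array([peaks.peaks[j].interval.start for j in pidx], dtype=np.int64)
        ends = np.array([peaks.peaks[j].interval.end for j in pidx], dtype=np.int64)
        # distance matrix peaks x genes
        inside = (starts[:, None] <= tss[None, :]) & (tss[None, :] < ends[:, None])
        edge = np.minimum(
            np.abs(starts[:, None] - tss[None, :]),
            np.abs(ends[:, None] - 1 - tss[None, :]),
        )
        dist = np.where(inside, 0, edge)

        col_min = dist.min(axis=0)  # nearest peak per gene
        for k, i in enumerate(gidx):
            nearest[i] = int(col_min[k])

        if require_closest:
            row_min = dist.min(axis=1)  # closest TSS per peak
            assigned = dist == row_min[:, None]
            eligible = assigned & (dist <= window_bp)
        else:
            eligible = dist <= window_bp
        pj, gk = np.nonzero(eligible)
        for r, k in zip(pj, gk):
            supporting[gidx[k]].append(pidx[r])

    calls: list[BindingCall] = []
    for i, g in enumerate(genes):
        sup = tuple(sorted(supporting[i]))
        calls.append(
            BindingCall(
                gene_id=g.gene_id,
                bound=bool(sup),
                nearest_peak_distance_bp=nearest[i],
                supporting_peaks=sup,
                window_bp=window_bp,
            )
        )
    return calls


def call_regulation(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    contrast: str,
    cell_line: str = "",
    thresholds: Thresholds = Thresholds(),
) -> list[RegulationCall]:
    """Call AR/androgen regulation from a two-condition expression matrix.

    fold = (mean(treated) + eps) / (mean(control) + eps). For the DHT
    contrast fold > fold_induced calls the gene androgen-induced and
    fold < fold_repressed androgen-repressed; for the siAR contrast the
    interpretation is inverted (knockdown of the regulator). Inequalities
    are strict.
    """
    if contrast not in CONTRASTS:
        raise ValidationError(f"unknown contrast {contrast!r}")
    control_label, treated_label = CONTRASTS[contrast]
    control = sheet.samples_in(control_label)
    treated = sheet.samples_in(treated_label)
    if not control or not treated:
        missing = control_label if not control else treated_label
        raise ValidationError(
            f"contrast {contrast}: missing condition {missing!r}"
        )
    eps = thresholds.pseudocount
    ctrl_mean = expr.values[control].mean(axis=1).to_numpy(dtype=float)
    trt_mean = expr.values[treated].mean(axis=1).to_numpy(dtype=float)
    fold = (trt_mean + eps) / (ctrl_mean + eps)

    calls: list[RegulationCall] = []
    for gid, f in zip(expr.genes, fold):
        if contrast == "DHT_vs_vehicle":
            if f > thresholds.fold_induced:
                call = "induced"
            elif f < thresholds.fold_repressed:
                call = "repressed"
            else:
                call = "unchanged"
        else:  # siAR_vs_siControl: knockdown inverts the reading
            if f < thresholds.fold_repressed:
                call = "induced"
            elif f > thresholds.fold_induced:
                call = "repressed"
            else:
                call = "unchanged"
        calls.append(
            RegulationCall(
                gene_id=gid,
                cell_line=cell_line,
                contrast=contrast,
                fold=float(f),
                call=call,
            )
        )
    return calls


@dataclass
class ARTargetSets:
    """Per-cell-line AR-target gene sets plus the groupings reported."""

    per_cell_line: dict[str, set[str]]
    lncap_vcap: set[str] = field(default_factory=set)
    r22rv1: set[str] = field(default_factory=set)


def ar_target_genes(
    binding: Sequence[BindingCall],
    regulation: Mapping[str, Sequence[RegulationCall]],
) -> ARTargetSets:
    """AR-target genes: bound within the target window AND regulated.

    ``regulation`` maps cell-line label -> regulation calls over the same
    gene universe as ``binding``. Emits the per-cell-line sets plus the
    LNCaP∩VCaP intersection and the 22Rv1 set when those lines are present.
    """
    universe = {b.gene_id for b in binding}
    bound = {b.gene_id for b in binding if b.bound}
    per: dict[str, set[str]] = {}
    for cell_line, calls in regulation.items():
        call_universe = {c.gene_id for c in calls}
        if call_universe != universe:
            raise ValidationError(
                f"cell line {cell_line}: regulation universe does not match "
                "binding universe"
            )
        per[cell_line] = {c.gene_id for c in calls if c.regulated} & bound
    sets = ARTargetSets(per_cell_line=per)
    if "LNCaP" in per and "VCaP" in per:
        sets.lncap_vcap = per["LNCaP"] & per["VCaP"]
    if "22Rv1" in per:
        sets.r22rv1 = per["22Rv1"]
    return sets


@dataclass(frozen=True)
class CandidateRow:
    """One row of the final candidate report."""

    gene_id: str
    location: str  # chrN:start-end, 1-based inclusive for display
    annotation: str
    mean_rpkm: Mapping[str, float]  # tissue group -> mean RPKM


@dataclass
class FunnelReport:
    stage_counts: dict[str, int]
    rows: list[CandidateRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.rows, start=1):
            rec = {"no": i, "gene_id": r.gene_id, "location": r.location,
                   "annotation": r.annotation}
            for grp, v in r.mean_rpkm.items():
                rec[f"mean_rpkm_{grp}"] = v
            recs.append(rec)
        return pd.DataFrame(recs)


def location_string(gene: GeneModel) -> str:
    iv = gene.interval
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


def crpc_lnc_funnel(
    candidates: Sequence[GeneModel],
    regulation: Iterable[Sequence[RegulationCall]],
    binding: Sequence[BindingCall],
    rpkm: ExpressionMatrix | None = None,
    sheet: SampleSheet | None = None,
) -> FunnelReport:
    """Narrow curated CRPC-upregulated lncRNAs to AR-bound regulated ones.

    Stages: curated candidates -> subset with any regulation call other
    than unchanged (union over the supplied call sets, e.g. the 22Rv1 siAR
    contrast and the androgen contrasts) -> subset with AR binding within
    the lncRNA window of the TSS (``binding`` must have been computed at
    that window). Stage sets are nested by construction. Candidate rows
    carry location, annotation and per-group mean RPKM, filled when
    a cohort matrix and sheet are supplied.
    """
    cand_ids = [g.gene_id for g in candidates]
    regulated_ids: set[str] = set()
    for calls in regulation:
        regulated_ids |= {c.gene_id for c in calls if c.regulated}
    bound_ids = {b.gene_id for b in binding if b.bound}

    stage1 = cand_ids
    stage2 = [gid for gid in stage1 if gid in regulated_ids]
    stage3 = [gid for gid in stage2 if gid in bound_ids]

    means = None
    if rpkm is not None and sheet is not None:
        from .expression import group_means

        means = group_means(rpkm, sheet)

    by_id = {g.gene_id: g for g in candidates}
    rows = []
    for gid in stage3:
        g = by_id[gid]
        if means is not None and gid in means.index:
            mean_rpkm = {grp: float(means.loc[gid, grp]) for grp in means.columns}
        else:
            mean_rpkm = {}
        rows.append(
            CandidateRow(
                gene_id=gid,
                location=location_string(g),
                annotation=g.name,
                mean_rpkm=mean_rpkm,
            )
        )
    return FunnelReport(
        stage_counts={
            "curated": len(stage1),
            "regulated": len(stage2),
            "bound_within_window": len(stage3),
        },
        rows=rows,
    )
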