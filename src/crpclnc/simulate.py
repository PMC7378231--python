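"""Seeded generator of annotation + expression + peak fixtures with ground truth.

The generator emulates the study design end to end so every downstream
stage is testable without any download:

* a three-group tissue cohort (benign n=6, localized cancer "pca" n=8,
  CRPC n=6) of negative-binomial counts with planted Type_A / Type_B
  up-regulation;
* cell-line condition matrices (LNCaP/VCaP vehicle vs DHT, 22Rv1
  siControl vs siAR) with planted fold factors;
* AR ChIP-seq peaks planted at exact distances from designated TSSs, plus
  decoy peaks far from every TSS;
* a lncRNA annotation with antisense, intergenic and exonic-decoy
  transcripts (decoys duplicate a coding gene's exons on the same strand
  and must be excluded by curation).

Counts are negative binomial with gene mean = RPKM_target * length_kb *
library_size / 1e6 and a common dispersion, so the RPKM stage is genuinely
exercised. In ``separation="complete"`` mode planted effects are
rejection-sampled until the realized data satisfy the planted truth
exactly (order condition for up-genes, fold-threshold side for regulated
genes, in-band folds and non-significance for null genes); this makes
perfect recovery of the planted labels a property of the fixture, not of
luck. ``separation="noisy"`` draws once with no rejection and is the mode
for null-calibration experiments.

Genomic layout guarantees that every planted peak has its target gene's
TSS as the unique nearest TSS and that no other TSS lies within the
binding window of the peak, so bound/unbound ground truth is unambiguous.
Planted-bound lncRNAs are therefore intergenic: an antisense lncRNA shares
its host's TSS neighborhood and cannot own an exclusive peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    PipelineError,
    SampleSheet,
    Thresholds,
    write_bed,
    write_gtf,
    write_matrix,
    write_sample_sheet,
)
from .expression import mann_whitney
from .regulon import (
    CONTRAST_OF_LINE_DEFAULT as CONTRAST_OF_LINE,
    BindingCall,
    RegulationCall,
    assign_peaks,
)

CELL_LINES = ("LNCaP", "VCaP", "22Rv1")
CONDITIONS_OF_LINE = {
    "LNCaP": ("vehicle", "DHT"),
    "VCaP": ("vehicle", "DHT"),
    "22Rv1": ("siControl", "siAR"),
}


class GenerationError(PipelineError):
    """The requested configuration cannot be placed/realized."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic fixture.

    Defaults mirror the cohort design (6/8/6), the two binding windows
    (50 kb targets, 10 kb lncRNA candidates) and the fold thresholds; the
    noise model (negative binomial, dispersion 0.1) and effect sizes are
    the generator's own calibration, surfaced here rather than hard-coded.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000

    n_coding: int = 300
    n_lnc_antisense: int = 30
    n_lnc_intergenic: int = 30
    n_lnc_exonic_decoy: int = 20

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"benign": 6, "pca": 8, "crpc": 6}
    )

    # planted differential-expression classes
    n_type_a_coding: int = 40
    n_type_b_coding: int = 24
    n_type_a_lnc: int = 10
    n_type_b_lnc: int = 6

    # planted AR binding / regulation (coding)
    n_ar_target: int = 40  # bound inside window AND regulated
    n_bound_unregulated: int = 10  # bound inside window, no regulation
    n_bound_outside: int = 10  # peak outside window, regulated
    peak_offset_inside: int = 49_000
    peak_offset_outside: int = 51_000

    # planted lncRNA regulation/binding (for the candidate funnel)
    n_lnc_regulated: int = 12
    n_lnc_bound: int = 8  # within the lncRNA window
    n_lnc_bound_far: int = 2  # regulated, peak outside the lncRNA window
    lnc_peak_offset_inside: int = 5_000
    lnc_peak_offset_outside: int = 12_000

    n_decoy_peaks: int = 20

    window_target_bp: int = 50_000
    window_lnc_bp: int = 10_000

    separation: str = "complete"  # complete | noisy
    dispersion: float = 0.1
    fold_factor: float = 3.0  # planted regulation magnitude (and its inverse)
    n_condition_replicates: int = 2
    max_rejection_tries: int = 2000

    def validate(self) -> None:
        if self.separation not in ("complete", "noisy"):
            raise GenerationError(f"unknown separation mode {self.separation!r}")
        if self.dispersion <= 0 or self.fold_factor <= 1:
            raise GenerationError("dispersion must be > 0 and fold_factor > 1")
        n_special = self.n_ar_target + self.n_bound_unregulated + self.n_bound_outside
        if self.n_type_a_coding + self.n_type_b_coding > self.n_coding:
            raise GenerationError("planted coding classes exceed n_coding")
        if n_special > self.n_coding:
            raise GenerationError("planted AR genes exceed n_coding")
        up_lnc = self.n_type_a_lnc + self.n_type_b_lnc
        bound_total = self.n_lnc_bound + self.n_lnc_bound_far
        if bound_total > self.n_lnc_regulated:
            raise GenerationError("bound lncRNAs exceed regulated lncRNAs")
        if self.n_lnc_regulated > up_lnc:
            raise GenerationError("regulated lncRNAs exceed planted up-lncRNAs")
        if bound_total > self.n_lnc_intergenic:
            raise GenerationError("bound lncRNAs exceed intergenic lncRNAs")
        if up_lnc - bound_total > self.n_lnc_antisense:
            raise GenerationError("unbound up-lncRNAs exceed antisense lncRNAs")
        n_hosts = self.n_lnc_antisense + self.n_lnc_exonic_decoy
        if n_hosts > self.n_coding - n_special:
            raise GenerationError(
                "not enough non-special coding genes to host antisense/decoy lncRNAs"
            )
        for g, n in self.group_sizes.items():
            if n < 2:
                raise GenerationError(f"group {g!r} needs >= 2 samples")


@dataclass
class GroundTruth:
    """Per-gene planted truth: class, lncRNA context, binding, regulation."""

    table: pd.DataFrame  # indexed by gene_id

    def true_class(self, gene_id: str) -> str:
        return self.table.loc[gene_id, "true_class"]

    def genes_of_class(self, klass: str) -> set[str]:
        return set(self.table.index[self.table["true_class"] == klass])

    def bound_genes(self) -> set[str]:
        return set(self.table.index[self.table["ar_bound"] == 1])

    def regulated_genes(self, cell_line: str) -> set[str]:
        col = f"reg_{cell_line}"
        return set(self.table.index[self.table[col] != "none"])

    def context_of(self, gene_id: str) -> str:
        return self.table.loc[gene_id, "lnc_context"]


@dataclass
class SimulationOutput:
    config: SimulationConfig
    outdir: Path
    paths: dict[str, Path]
    ground_truth: GroundTruth
    genes: list[GeneModel]


# ---------------------------------------------------------------------------
# planning helpers
# ---------------------------------------------------------------------------

@dataclass
class _Planned:
    gene_id: str
    category: str  # coding | antisense | intergenic | decoy
    database: str
    true_class: str = "null"  # Type_A | Type_B | null
    expressed: bool = True
    peak_offset: int = -1  # -1: no planted peak
    reg: dict[str, str] = field(default_factory=dict)  # cell line -> call
    host: str | None = None
    model: GeneModel | None = None

    @property
    def biotype(self) -> str:
        return "coding" if self.category == "coding" else "noncoding"

    @property
    def context(self) -> str:
        return {"coding": "coding", "antisense": "antisense",
                "intergenic": "intergenic", "decoy": "exonic_decoy"}[self.category]


def _make_exons(
    rng: np.random.Generator, start: int, strand: str, chrom: str, kind: str
) -> tuple[GenomicInterval, tuple[GenomicInterval, ...]]:
    if kind == "coding":
        n_ex = int(rng.integers(3, 7))
        ex_lens = rng.integers(150, 600, n_ex)
        intron_lens = rng.integers(300, 1200, n_ex - 1)
    else:  # lnc
        n_ex = int(rng.integers(1, 4))
        ex_lens = rng.integers(200, 800, n_ex)
        intron_lens = rng.integers(200, 800, max(0, n_ex - 1))
    exons = []
    pos = start
    for i in range(n_ex):
        exons.append(GenomicInterval(chrom, pos, pos + int(ex_lens[i]), strand))
        pos += int(ex_lens[i])
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    interval = GenomicInterval(chrom, start, pos, strand)
    return interval, tuple(exons)


def _plan_roles(config: SimulationConfig, rng: np.random.Generator) -> list[_Planned]:
    """Assign ids, databases, planted classes, binding offsets, regulation."""
    coding = [
        _Planned(gene_id=f"g{i + 1:04d}", category="coding", database="RefSeq")
        for i in range(config.n_coding)
    ]

    # planted AR binding on coding genes (disjoint special sets)
    n_special = config.n_ar_target + config.n_bound_unregulated + config.n_bound_outside
    special_idx = rng.choice(config.n_coding, size=n_special, replace=False)
    ar_target_idx = special_idx[: config.n_ar_target]
    bound_unreg_idx = special_idx[
        config.n_ar_target : config.n_ar_target + config.n_bound_unregulated
    ]
    bound_out_idx = special_idx[config.n_ar_target + config.n_bound_unregulated :]

    for k, i in enumerate(ar_target_idx):
        coding[i].peak_offset = config.peak_offset_inside
        half = config.n_ar_target // 2
        call = "induced" if k % 2 == 0 else "repressed"
        if k < half:
            coding[i].reg = {"LNCaP": call, "VCaP": call}
        else:
            coding[i].reg = {"22Rv1": call}
    for i in bound_unreg_idx:
        coding[i].peak_offset = config.peak_offset_inside
    for i in bound_out_idx:
        coding[i].peak_offset = config.peak_offset_outside
        coding[i].reg = {"22Rv1": "induced"}

    # planted coding expression classes (may overlap the AR sets)
    class_idx = rng.choice(
        config.n_coding,
        size=config.n_type_a_coding + config.n_type_b_coding,
        replace=False,
    )
    for i in class_idx[: config.n_type_a_coding]:
        coding[i].true_class = "Type_A"
    for i in class_idx[config.n_type_a_coding :]:
        coding[i].true_class = "Type_B"
    # a fraction of null coding genes is lowly expressed (tests the filter)
    for g in coding:
        if g.true_class == "null":
            g.expressed = bool(rng.random() < 0.6)

    # hosts for antisense and exonic-decoy lncRNAs: non-special coding genes
    nonspecial = [i for i in range(config.n_coding) if i not in set(special_idx)]
    host_idx = rng.choice(
        len(nonspecial),
        size=config.n_lnc_antisense + config.n_lnc_exonic_decoy,
        replace=False,
    )
    as_hosts = [coding[nonspecial[j]] for j in host_idx[: config.n_lnc_antisense]]
    decoy_hosts = [coding[nonspecial[j]] for j in host_idx[config.n_lnc_antisense :]]

    def _lnc_db() -> str:
        return str(rng.choice(["RefSeq", "GENCODE", "NONCODE"]))

    antisense = [
        _Planned(
            gene_id=f"as{i + 1:03d}", category="antisense",
            database=_lnc_db(), host=h.gene_id,
        )
        for i, h in enumerate(as_hosts)
    ]
    decoys = [
        _Planned(
            gene_id=f"dx{i + 1:03d}", category="decoy",
            database="NONCODE", host=h.gene_id,
        )
        for i, h in enumerate(decoy_hosts)
    ]
    intergenic = [
        _Planned(gene_id=f"li{i + 1:03d}", category="intergenic", database=_lnc_db())
        for i in range(config.n_lnc_intergenic)
    ]

    # planted up-lncRNAs and their regulation/binding, feeding the funnel:
    #   bound (intergenic, peak inside the lncRNA window)
    #   bound_far (intergenic, peak outside the lncRNA window)
    #   regulated but unbound (antisense)
    #   upregulated but unregulated (antisense)
    bound_total = config.n_lnc_bound + config.n_lnc_bound_far
    inter_pick = rng.choice(config.n_lnc_intergenic, size=bound_total, replace=False)
    up_lnc: list[_Planned] = []
    for k, j in enumerate(inter_pick[: config.n_lnc_bound]):
        g = intergenic[j]
        g.peak_offset = config.lnc_peak_offset_inside
        g.reg = {"22Rv1": "induced" if k % 2 == 0 else "repressed"}
        up_lnc.append(g)
    for j in inter_pick[config.n_lnc_bound :]:
        g = intergenic[j]
        g.peak_offset = config.lnc_peak_offset_outside
        g.reg = {"22Rv1": "induced"}
        up_lnc.append(g)
    n_reg_unbound = config.n_lnc_regulated - bound_total
    n_up_unreg = config.n_type_a_lnc + config.n_type_b_lnc - config.n_lnc_regulated
    as_pick = rng.choice(
        config.n_lnc_antisense, size=n_reg_unbound + n_up_unreg, replace=False
    )
    for k, j in enumerate(as_pick[:n_reg_unbound]):
        g = antisense[j]
        g.reg = (
            {"LNCaP": "induced", "VCaP": "induced"} if k % 2 == 0
            else {"22Rv1": "repressed"}
        )
        up_lnc.append(g)
    for j in as_pick[n_reg_unbound:]:
        up_lnc.append(antisense[j])

    for k, g in enumerate(up_lnc):
        g.true_class = "Type_A" if k < config.n_type_a_lnc else "Type_B"

    # null lncRNAs: half lowly expressed
    for g in antisense + intergenic:
        if g.true_class == "null":
            g.expressed = bool(rng.random() < 0.5)

    return coding + antisense + intergenic + decoys


def _layout(
    config: SimulationConfig,
    rng: np.random.Generator,
    planned: Sequence[_Planned],
) -> list[Peak]:
    """Place genes on chromosomes and return planted + decoy peaks.

    A gene with a planted peak at offset o reserves a downstream clearance
    so that no other TSS lies within the target window of the peak and the
    peak's unique nearest TSS is its own gene.
    """
    margin = 1_000
    window = config.window_target_bp
    coding = [g for g in planned if g.category == "coding"]
    intergenic = [g for g in planned if g.category == "intergenic"]
    by_id = {g.gene_id: g for g in planned}

    as_host_of: dict[str, _Planned] = {}
    decoy_host_of: dict[str, list[_Planned]] = {}
    for g in planned:
        if g.category == "antisense":
            as_host_of[g.host] = g
        elif g.category == "decoy":
            decoy_host_of.setdefault(g.host, []).append(g)

    # deal entries to chromosomes per footprint class (genes with peak
    # clearances are ~20x wider than plain genes), so the load is balanced
    per_chrom: dict[str, list[_Planned]] = {
        f"chr{c + 1}": [] for c in range(config.n_chroms)
    }
    classes = [
        [g for g in coding if g.peak_offset >= 0],
        [g for g in intergenic if g.peak_offset >= 0],
        [g for g in coding if g.peak_offset < 0],
        [g for g in intergenic if g.peak_offset < 0],
    ]
    for members in classes:
        order = rng.permutation(len(members))
        for k, idx in enumerate(order):
            per_chrom[f"chr{k % config.n_chroms + 1}"].append(members[idx])
    for chrom in per_chrom:
        order = rng.permutation(len(per_chrom[chrom]))
        per_chrom[chrom] = [per_chrom[chrom][i] for i in order]

    decoy_per_chrom = {
        f"chr{c + 1}": [
            i for i in range(config.n_decoy_peaks) if i % config.n_chroms == c
        ]
        for c in range(config.n_chroms)
    }

    peaks: list[Peak] = []
    for chrom, chrom_entries in per_chrom.items():
        cursor = 1_000
        for g in chrom_entries:
            strand = str(rng.choice(["+", "-"]))
            kind = "coding" if g.category == "coding" else "lnc"
            # pre-gap: base spacing, widened for intergenic margin / clearance
            pre = 2_000
            if g.category == "intergenic":
                pre = max(pre, config.window_lnc_bp + margin)
            if g.peak_offset >= 0:
                pre = max(pre, window - g.peak_offset + margin)
            start = cursor + pre
            interval, exons = _make_exons(rng, start, strand, chrom, kind)
            g.model = GeneModel(
                gene_id=g.gene_id,
                name=g.gene_id.upper(),
                interval=interval,
                exons=exons,
                biotype=g.biotype,
                database=g.database,
            )
            post = 0
            if g.category == "intergenic":
                post = config.window_lnc_bp + margin
            if g.peak_offset >= 0:
                tss = g.model.tss
                width = int(rng.integers(300, 600))
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, tss + g.peak_offset,
                                        tss + g.peak_offset + width, "."),
                        score=float(np.round(rng.uniform(10, 100), 2)),
                    )
                )
                clearance_end = tss + g.peak_offset + width + window + margin
                post = max(post, clearance_end - interval.end)
            # antisense lncRNA nested inside its host, opposite strand
            if g.gene_id in as_host_of:
                a = as_host_of[g.gene_id]
                flip = "-" if strand == "+" else "+"
                span = interval.end - interval.start
                a_start = start + int(rng.integers(100, max(101, span // 3)))
                a_len = int(
                    min(interval.end - a_start - 100, rng.integers(400, 1500))
                )
                if a_len < 200:
                    a_start = start + 100
                    a_len = min(interval.end - a_start - 100, 400)
                if a_len < 100:
                    raise GenerationError(
                        f"host {g.gene_id} too short for antisense lncRNA"
                    )
                a_iv = GenomicInterval(chrom, a_start, a_start + a_len, flip)
                a.model = GeneModel(
                    gene_id=a.gene_id, name=a.gene_id.upper(),
                    interval=a_iv, exons=(a_iv,),
                    biotype="noncoding", database=a.database,
                )
            # exonic decoys duplicate the host's exons on the same strand
            for d in decoy_host_of.get(g.gene_id, []):
                d.model = GeneModel(
                    gene_id=d.gene_id, name=d.gene_id.upper(),
                    interval=interval, exons=exons,
                    biotype="noncoding", database=d.database,
                )
            cursor = interval.end + post
        # decoy peaks in a gene-free tail, > window from every TSS
        cursor += window + 5_000
        for _ in decoy_per_chrom[chrom]:
            width = int(rng.integers(300, 600))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, cursor, cursor + width, "."),
                    score=float(np.round(rng.uniform(10, 100), 2)),
                )
            )
            cursor += width + 2_000
        if cursor > config.chrom_length_bp:
            raise GenerationError(
                f"{chrom}: layout needs {cursor} bp but chrom_length_bp is "
                f"{config.chrom_length_bp}; increase chromosome length or "
                "reduce gene/peak counts"
            )
    missing = [g.gene_id for g in planned if g.model is None]
    if missing:
        raise GenerationError(f"unplaced genes: {missing[:5]}")
    return peaks


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

_COHORT_TARGETS = {
    # (category, class) -> (benign, pca, crpc) RPKM targets
    ("coding", "Type_A"): (2.5, 3.5, 25.0),
    ("coding", "Type_B"): (2.5, 18.0, 18.0),
    ("lnc", "Type_A"): (0.6, 0.9, 9.0),
    ("lnc", "Type_B"): (0.6, 7.0, 7.0),
}


def _cohort_targets(g: _Planned, rng: np.random.Generator) -> np.ndarray:
    cat = "coding" if g.category == "coding" else "lnc"
    if g.true_class in ("Type_A", "Type_B"):
        return np.array(_COHORT_TARGETS[(cat, g.true_class)])
    if g.category == "coding":
        base = rng.uniform(8, 30) if g.expressed else rng.uniform(0.2, 2.0)
    else:
        base = rng.uniform(2, 10) if g.expressed else rng.uniform(0.05, 0.5)
    return np.array([base, base, base])


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    r = 1.0 / dispersion
    mean = np.maximum(mean, 1e-8)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _draw_cohort_gene(
    g: _Planned,
    targets: np.ndarray,
    groups: Sequence[str],
    libs: np.ndarray,
    length_bp: int,
    config: SimulationConfig,
    thresholds: Thresholds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts for one gene over the cohort; rejection in complete mode."""
    group_order = ["benign", "pca", "crpc"]
    target_per_sample = np.array(
        [targets[group_order.index(grp)] for grp in groups]
    )
    mean = target_per_sample * (length_bp / 1000.0) * libs / 1e6
    is_crpc = np.array([grp == "crpc" for grp in groups])
    is_ben = np.array([grp == "benign" for grp in groups])
    is_pca = np.array([grp == "pca" for grp in groups])
    thr = thresholds.rpkm_min[g.database]
    alpha = thresholds.alpha

    for _ in range(config.max_rejection_tries):
        counts = _nb_counts(rng, mean, config.dispersion)
        if config.separation == "noisy":
            return counts
        rpkm = counts * 1e9 / (length_bp * libs)
        crpc, ben, pca = rpkm[is_crpc], rpkm[is_ben], rpkm[is_pca]
        if g.true_class == "Type_A":
            ok = (
                crpc.min() > max(ben.max(), pca.max())
                and crpc.mean() > thr
            )
        elif g.true_class == "Type_B":
            r = mann_whitney(crpc, pca)
            ok = (
                crpc.min() > ben.max()
                and crpc.mean() > thr
                and not (r.p_value < alpha and r.direction == "up")
            )
        else:
            if crpc.mean() <= thr:
                ok = True
            else:
                r = mann_whitney(crpc, ben)
                ok = not (r.p_value < alpha and r.direction == "up")
        if ok:
            return counts
    raise GenerationError(
        f"{g.gene_id}: could not realize planted class {g.true_class} "
        f"within {config.max_rejection_tries} tries"
    )


def _draw_condition_gene(
    g: _Planned,
    cell_line: str,
    base_rpkm: float,
    libs: np.ndarray,
    n_control: int,
    length_bp: int,
    config: SimulationConfig,
    thresholds: Thresholds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts for one gene in one cell line (control then treated samples)."""
    truth = g.reg.get(cell_line, "none")
    contrast = CONTRAST_OF_LINE[cell_line]
    f = config.fold_factor
    if truth == "none":
        factor = 1.0
    elif contrast == "DHT_vs_vehicle":
        factor = f if truth == "induced" else 1.0 / f
    else:  # siAR: knocking down AR lowers AR-induced genes
        factor = 1.0 / f if truth == "induced" else f
    target = np.full(len(libs), base_rpkm)
    target[n_control:] *= factor
    mean = target * (length_bp / 1000.0) * libs / 1e6
    eps = thresholds.pseudocount

    for _ in range(config.max_rejection_tries):
        counts = _nb_counts(rng, mean, config.dispersion)
        if config.separation == "noisy":
            return counts
        rpkm = counts * 1e9 / (length_bp * libs)
        fold = (rpkm[n_control:].mean() + eps) / (rpkm[:n_control].mean() + eps)
        if contrast == "DHT_vs_vehicle":
            if fold > thresholds.fold_induced:
                call = "induced"
            elif fold < thresholds.fold_repressed:
                call = "repressed"
            else:
                call = "unchanged"
        else:
            if fold < thresholds.fold_repressed:
                call = "induced"
            elif fold > thresholds.fold_induced:
                call = "repressed"
            else:
                call = "unchanged"
        want = "unchanged" if truth == "none" else truth
        if call == want:
            return counts
    raise GenerationError(
        f"{g.gene_id}/{cell_line}: could not realize regulation {truth!r} "
        f"within {config.max_rejection_tries} tries"
    )


# ---------------------------------------------------------------------------
# top-level simulate
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir: str | Path) -> SimulationOutput:
    """Generate the full fixture set under ``outdir``.

    Emits genes.gtf, cohort counts + sample sheet, per-cell-line condition
    counts + sheets, per-cell-line AR peak BEDs, and the ground-truth
    manifest. Identical seed + config give byte-identical outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    thresholds = Thresholds(
        window_target_bp=config.window_target_bp,
        window_lnc_bp=config.window_lnc_bp,
    )

    planned = _plan_roles(config, rng)
    peak_list = _layout(config, rng, planned)
    genes = sorted(
        (g.model for g in planned),
        key=lambda m: (m.interval.chrom, m.interval.start, m.gene_id),
    )
    planned_by_id = {g.gene_id: g for g in planned}
    gene_order = [m.gene_id for m in genes]

    # --- cohort ---
    samples: list[str] = []
    groups: list[str] = []
    for grp in ("benign", "pca", "crpc"):
        for i in range(config.group_sizes[grp]):
            samples.append(f"{grp}_{i + 1}")
            groups.append(grp)
    libs = rng.integers(15_000_000, 30_000_000, size=len(samples))
    cohort_sheet = SampleSheet(
        entries={s: (g, int(l)) for s, g, l in zip(samples, groups, libs)},
        declared_groups=("benign", "pca", "crpc"),
    )
    cohort_rows = []
    cohort_targets: dict[str, np.ndarray] = {}
    for gid in gene_order:
        g = planned_by_id[gid]
        targets = _cohort_targets(g, rng)
        cohort_targets[gid] = targets
        cohort_rows.append(
            _draw_cohort_gene(
                g, targets, groups, libs.astype(float),
                g.model.exonic_length, config, thresholds, rng,
            )
        )
    cohort_counts = ExpressionMatrix(
        values=pd.DataFrame(
            np.array(cohort_rows, dtype=np.int64), index=gene_order, columns=samples
        ),
        unit="count",
    )

    # --- cell-line conditions ---
    nrep = config.n_condition_replicates
    cond_matrices: dict[str, ExpressionMatrix] = {}
    cond_sheets: dict[str, SampleSheet] = {}
    cell_base = {
        gid: float(np.round(rng.uniform(3, 20), 3)) for gid in gene_order
    }
    for line in CELL_LINES:
        control, treated = CONDITIONS_OF_LINE[line]
        line_samples = [f"{line}_{control}_{i + 1}" for i in range(nrep)] + [
            f"{line}_{treated}_{i + 1}" for i in range(nrep)
        ]
        line_groups = [control] * nrep + [treated] * nrep
        line_libs = rng.integers(15_000_000, 30_000_000, size=2 * nrep)
        cond_sheets[line] = SampleSheet(
            entries={
                s: (g, int(l))
                for s, g, l in zip(line_samples, line_groups, line_libs)
            },
            declared_groups=(control, treated),
        )
        rows = []
        for gid in gene_order:
            g = planned_by_id[gid]
            rows.append(
                _draw_condition_gene(
                    g, line, cell_base[gid], line_libs.astype(float), nrep,
                    g.model.exonic_length, config, thresholds, rng,
                )
            )
        cond_matrices[line] = ExpressionMatrix(
            values=pd.DataFrame(
                np.array(rows, dtype=np.int64),
                index=gene_order,
                columns=line_samples,
            ),
            unit="count",
        )

    # --- ground truth ---
    truth_rows = []
    for gid in gene_order:
        g = planned_by_id[gid]
        bound = int(0 <= g.peak_offset <= config.window_target_bp)
        truth_rows.append(
            {
                "gene_id": gid,
                "biotype": g.biotype,
                "database": g.database,
                "true_class": g.true_class,
                "lnc_context": g.context,
                "ar_bound": bound,
                "peak_offset": g.peak_offset,
                "reg_LNCaP": g.reg.get("LNCaP", "none"),
                "reg_VCaP": g.reg.get("VCaP", "none"),
                "reg_22Rv1": g.reg.get("22Rv1", "none"),
            }
        )
    truth_df = pd.DataFrame(truth_rows).set_index("gene_id")

    # --- write everything ---
    paths: dict[str, Path] = {}
    paths["gtf"] = outdir / "genes.gtf"
    write_gtf(genes, paths["gtf"])
    paths["cohort_counts"] = outdir / "cohort_counts.tsv"
    write_matrix(cohort_counts, paths["cohort_counts"])
    paths["cohort_sheet"] = outdir / "cohort_samples.tsv"
    write_sample_sheet(cohort_sheet, paths["cohort_sheet"])
    for line in CELL_LINES:
        paths[f"{line}_counts"] = outdir / f"{line}_counts.tsv"
        write_matrix(cond_matrices[line], paths[f"{line}_counts"])
        paths[f"{line}_sheet"] = outdir / f"{line}_samples.tsv"
        write_sample_sheet(cond_sheets[line], paths[f"{line}_sheet"])
        peakset = PeakSet(peaks=tuple(peak_list), source_label=f"AR_{line}")
        paths[f"{line}_peaks"] = outdir / f"AR_{line}.bed"
        write_bed(peakset, paths[f"{line}_peaks"])
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    truth_df.to_csv(paths["ground_truth"], sep="\t")

    return SimulationOutput(
        config=config,
        outdir=outdir,
        paths=paths,
        ground_truth=GroundTruth(table=truth_df),
        genes=genes,
    )


def load_ground_truth(
    path: str | Path, genes: Sequence[GeneModel] | None = None
) -> GroundTruth:
    """Load the manifest written by :func:`simulate`.

    When ``genes`` is given, the manifest must cover exactly that gene set.
    """
    # na_filter off: "null" is a legitimate class label, not a missing value
    df = pd.read_csv(path, sep="\t", index_col="gene_id", na_filter=False)
    for col in ("ar_bound", "peak_offset"):
        df[col] = df[col].astype(int)
    if df.index.duplicated().any():
        raise PipelineError("ground truth manifest has duplicated gene_ids")
    if genes is not None:
        manifest_ids = set(df.index)
        gtf_ids = {g.gene_id for g in genes}
        if manifest_ids != gtf_ids:
            diff = sorted(manifest_ids ^ gtf_ids)[:5]
            raise PipelineError(
                f"ground truth / annotation gene mismatch, e.g. {diff}"
            )
    return GroundTruth(table=df)


# ---------------------------------------------------------------------------
# focused funnel fixture
# ---------------------------------------------------------------------------

def make_funnel_fixture(
    n_total: int = 163,
    n_regulated: int = 60,
    n_bound: int = 21,
    seed: int = 0,
) -> tuple[list[GeneModel], list[list[RegulationCall]], list[BindingCall]]:
    """A curated-lncRNA set with known funnel structure.

    Builds ``n_total`` intergenic-style lncRNAs of which ``n_regulated``
    carry an AR-regulation call (22Rv1 knockdown contrast) and ``n_bound``
    of those have an AR peak within the 10 kb lncRNA window of the TSS;
    used to check that the funnel reports exactly
    (n_total -> n_regulated -> n_bound).
    """
    if not (0 <= n_bound <= n_regulated <= n_total):
        raise GenerationError("require 0 <= n_bound <= n_regulated <= n_total")
    rng = np.random.default_rng(seed)
    spacing = 40_000
    genes: list[GeneModel] = []
    peaks: list[Peak] = []
    calls: list[RegulationCall] = []
    for i in range(n_total):
        start = 10_000 + i * spacing
        length = int(rng.integers(500, 2000))
        iv = GenomicInterval("chr1", start, start + length, "+")
        g = GeneModel(
            gene_id=f"lnc{i + 1:03d}", name=f"LNC{i + 1:03d}",
            interval=iv, exons=(iv,), biotype="noncoding", database="GENCODE",
        )
        genes.append(g)
        regulated = i < n_regulated
        fold = 0.4 if regulated else 1.0
        calls.append(
            RegulationCall(
                gene_id=g.gene_id, cell_line="22Rv1",
                contrast="siAR_vs_siControl", fold=fold,
                call="induced" if regulated else "unchanged",
            )
        )
        if i < n_bound:
            peaks.append(
                Peak(GenomicInterval("chr1", g.tss + 5_000, g.tss + 5_400, "."), 50.0)
            )
    peakset = PeakSet(peaks=tuple(peaks), source_label="AR_22Rv1")
    binding = assign_peaks(peakset, genes, window_bp=10_000)
    return genes, [calls], binding
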