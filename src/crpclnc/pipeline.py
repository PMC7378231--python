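"""End-to-end orchestration: quantify -> classify -> curate -> integrate -> report.

Every stage is a plain function over files so the CLI subcommands can run
them standalone on the previous stage's outputs; :func:`run_discover`
chains them in memory and writes every intermediate. All randomness lives
in the simulation; the analysis stages are deterministic, so two runs on
identical inputs produce byte-identical result TSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import (
    ExpressionMatrix,
    GeneModel,
    PipelineError,
    SampleSheet,
    Thresholds,
    read_bed,
    read_gtf,
    read_matrix,
    read_sample_sheet,
    write_matrix,
)
from .curation import LncContextCall, curate_all
from .expression import (
    GeneClassification,
    classify_genes,
    compute_rpkm,
    group_means,
)
from .regulon import (
    CONTRAST_OF_LINE_DEFAULT,
    ar_target_genes,
    assign_peaks,
    call_regulation,
    crpc_lnc_funnel,
)
from .report import assemble_report


class StageError(PipelineError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class CellLineInput:
    counts: Path
    sheet: Path
    peaks: Path
    contrast: str


@dataclass
class PipelineConfig:
    gtf: Path
    cohort_counts: Path
    cohort_sheet: Path
    cell_lines: dict[str, CellLineInput]
    outdir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    require_closest: bool = True
    funnel_peaks_line: str = "22Rv1"
    min_overlap_fraction: float = 0.0

    @classmethod
    def from_simulation_dir(cls, sim_dir: str | Path, outdir: str | Path,
                            **kwargs) -> "PipelineConfig":
        """Standard paths as written by ``crpclnc.simulate.simulate``."""
        sim_dir = Path(sim_dir)
        lines = {}
        for line in ("LNCaP", "VCaP", "22Rv1"):
            lines[line] = CellLineInput(
                counts=sim_dir / f"{line}_counts.tsv",
                sheet=sim_dir / f"{line}_samples.tsv",
                peaks=sim_dir / f"AR_{line}.bed",
                contrast=CONTRAST_OF_LINE_DEFAULT[line],
            )
        return cls(
            gtf=sim_dir / "genes.gtf",
            cohort_counts=sim_dir / "cohort_counts.tsv",
            cohort_sheet=sim_dir / "cohort_samples.tsv",
            cell_lines=lines,
            outdir=Path(outdir),
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        def _p(x: str) -> Path:
            p = Path(x)
            return p if p.is_absolute() else base / p
        lines = {
            name: CellLineInput(
                counts=_p(d["counts"]), sheet=_p(d["sheet"]),
                peaks=_p(d["peaks"]), contrast=d["contrast"],
            )
            for name, d in raw.get("cell_lines", {}).items()
        }
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            gtf=_p(raw["gtf"]),
            cohort_counts=_p(raw["cohort_counts"]),
            cohort_sheet=_p(raw["cohort_sheet"]),
            cell_lines=lines,
            outdir=_p(raw["outdir"]),
            thresholds=thr,
            require_closest=raw.get("require_closest", True),
            funnel_peaks_line=raw.get("funnel_peaks_line", "22Rv1"),
            min_overlap_fraction=raw.get("min_overlap_fraction", 0.0),
        )

    def content_hash(self) -> str:
        payload = {
            "gtf": str(self.gtf),
            "cohort_counts": str(self.cohort_counts),
            "cohort_sheet": str(self.cohort_sheet),
            "cell_lines": {
                k: [str(v.counts), str(v.sheet), str(v.peaks), v.contrast]
                for k, v in sorted(self.cell_lines.items())
            },
            "thresholds": {
                "rpkm_min": dict(self.thresholds.rpkm_min),
                "alpha": self.thresholds.alpha,
                "window_target_bp": self.thresholds.window_target_bp,
                "window_lnc_bp": self.thresholds.window_lnc_bp,
                "fold_induced": self.thresholds.fold_induced,
                "fold_repressed": self.thresholds.fold_repressed,
                "pseudocount": self.thresholds.pseudocount,
            },
            "require_closest": self.require_closest,
            "funnel_peaks_line": self.funnel_peaks_line,
            "min_overlap_fraction": self.min_overlap_fraction,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    genes: list[GeneModel]
    cohort_rpkm: ExpressionMatrix
    cohort_sheet: SampleSheet
    classifications: list[GeneClassification]
    curation_calls: list[LncContextCall]
    binding_by_line: dict
    regulation_by_line: dict
    ar_targets: object
    funnel: object
    summary: object
    outdir: Path


# ---------------------------------------------------------------------------
# TSV serialization of stage outputs (fixed column order and float format)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_classifications(
    classifications: Sequence[GeneClassification],
    means: pd.DataFrame,
    path: Path,
) -> None:
    rows = []
    for c in classifications:
        row = {
            "gene_id": c.gene_id,
            "class": c.klass,
            "passed_filter": int(c.passed_expression_filter),
            "p_crpc_vs_pca": c.p_crpc_vs_pca,
            "p_crpc_vs_benign": c.p_crpc_vs_benign,
        }
        for grp in means.columns:
            row[f"mean_rpkm_{grp}"] = means.loc[c.gene_id, grp]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_classifications(path: Path) -> list[GeneClassification]:
    df = pd.read_csv(path, sep="\t", na_filter=False)
    return [
        GeneClassification(
            gene_id=str(r["gene_id"]),
            klass=str(r["class"]),
            passed_expression_filter=bool(int(r["passed_filter"])),
            p_crpc_vs_pca=float(r["p_crpc_vs_pca"]),
            p_crpc_vs_benign=float(r["p_crpc_vs_benign"]),
        )
        for r in df.to_dict("records")
    ]


def write_curation(calls: Sequence[LncContextCall], path: Path) -> None:
    rows = []
    for c in calls:
        ev = ";".join(
            f"{e.coding_gene_id}:{'same' if e.same_strand else 'opposite'}:"
            f"{e.overlap_bp}bp{':exonic' if e.exonic else ''}"
            for e in c.evidence
        )
        rows.append(
            {
                "gene_id": c.gene_id,
                "verdict": c.verdict,
                "context": c.context if c.context is not None else "",
                "evidence": ev,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_regulation(calls, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "cell_line": c.cell_line,
                "contrast": c.contrast,
                "fold": c.fold,
                "call": c.call,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_binding(calls, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "bound": int(c.bound),
                "nearest_peak_distance_bp": (
                    c.nearest_peak_distance_bp
                    if c.nearest_peak_distance_bp is not None
                    else -1
                ),
                "n_supporting_peaks": len(c.supporting_peaks),
                "window_bp": c.window_bp,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_discover(config: PipelineConfig) -> DiscoveryResult:
    """Execute the full discovery workflow and write all intermediates."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    # --- load inputs ---
    try:
        genes = read_gtf(config.gtf)
        cohort_sheet = read_sample_sheet(
            config.cohort_sheet, declared_groups=("benign", "pca", "crpc")
        )
        cohort_counts = read_matrix(config.cohort_counts, cohort_sheet)
    except (OSError, PipelineError) as exc:
        raise StageError("load", exc)

    # --- quantify ---
    try:
        rpkm = compute_rpkm(cohort_counts, genes, cohort_sheet)
        write_matrix(rpkm, outdir / "cohort_rpkm.tsv")
    except PipelineError as exc:
        raise StageError("quantify", exc)

    # --- classify ---
    try:
        classifications = classify_genes(rpkm, cohort_sheet, genes, thr)
        means = group_means(rpkm, cohort_sheet)
        write_classifications(classifications, means, outdir / "classification.tsv")
    except PipelineError as exc:
        raise StageError("classify", exc)

    # --- curate ---
    try:
        coding = [g for g in genes if g.biotype == "coding"]
        noncoding = [g for g in genes if g.biotype == "noncoding"]
        curation_calls, curation_summary = curate_all(
            noncoding, coding, config.min_overlap_fraction
        )
        write_curation(curation_calls, outdir / "curation.tsv")
    except PipelineError as exc:
        raise StageError("curate", exc)

    # --- integrate: binding + regulation + AR targets per cell line ---
    binding_by_line = {}
    regulation_by_line = {}
    try:
        for line, inp in config.cell_lines.items():
            sheet = read_sample_sheet(inp.sheet)
            counts = read_matrix(inp.counts, sheet)
            line_rpkm = compute_rpkm(counts, genes, sheet)
            regulation_by_line[line] = call_regulation(
                line_rpkm, sheet, inp.contrast, cell_line=line, thresholds=thr
            )
            peaks = read_bed(inp.peaks, source_label=f"AR_{line}")
            binding_by_line[line] = assign_peaks(
                peaks, genes, thr.window_target_bp,
                require_closest=config.require_closest,
            )
            write_regulation(
                regulation_by_line[line], outdir / f"regulation_{line}.tsv"
            )
            write_binding(
                binding_by_line[line], outdir / f"binding_{line}.tsv"
            )
        ref_line = next(iter(config.cell_lines))
        targets = ar_target_genes(
            binding_by_line[ref_line], regulation_by_line
        )
        target_rows = []
        for name, s in sorted(targets.per_cell_line.items()):
            for gid in sorted(s):
                target_rows.append({"set": name, "gene_id": gid})
        for gid in sorted(targets.lncap_vcap):
            target_rows.append({"set": "LNCaP&VCaP", "gene_id": gid})
        pd.DataFrame(target_rows, columns=["set", "gene_id"]).to_csv(
            outdir / "ar_targets.tsv", sep="\t", index=False
        )
    except (OSError, PipelineError) as exc:
        raise StageError("integrate", exc)

    # --- funnel + report ---
    try:
        klass = {c.gene_id: c.klass for c in classifications}
        kept = {c.gene_id for c in curation_calls if c.verdict == "kept"}
        candidates = [
            g for g in noncoding
            if g.gene_id in kept and klass[g.gene_id] in ("Type_A", "Type_B")
        ]
        funnel_line = config.funnel_peaks_line
        if funnel_line not in config.cell_lines:
            raise PipelineError(
                f"funnel peaks cell line {funnel_line!r} not configured"
            )
        lnc_peaks = read_bed(
            config.cell_lines[funnel_line].peaks, source_label=f"AR_{funnel_line}"
        )
        lnc_binding = assign_peaks(
            lnc_peaks, genes, thr.window_lnc_bp,
            require_closest=config.require_closest,
        )
        write_binding(lnc_binding, outdir / "binding_lnc_window.tsv")
        funnel = crpc_lnc_funnel(
            candidates,
            list(regulation_by_line.values()),
            lnc_binding,
            rpkm=rpkm,
            sheet=cohort_sheet,
        )
        funnel.to_frame().to_csv(
            outdir / "candidates.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        pd.DataFrame(
            {
                "stage": list(funnel.stage_counts),
                "count": list(funnel.stage_counts.values()),
            }
        ).to_csv(outdir / "funnel_stages.tsv", sep="\t", index=False)
        summary = assemble_report(classifications, curation_calls, funnel)
        summary.to_frame().to_csv(outdir / "summary.tsv", sep="\t", index=False)
    except PipelineError as exc:
        raise StageError("report", exc)

    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "n_genes": len(genes),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return DiscoveryResult(
        genes=genes,
        cohort_rpkm=rpkm,
        cohort_sheet=cohort_sheet,
        classifications=classifications,
        curation_calls=curation_calls,
        binding_by_line=binding_by_line,
        regulation_by_line=regulation_by_line,
        ar_targets=targets,
        funnel=funnel,
        summary=summary,
        outdir=outdir,
    )
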