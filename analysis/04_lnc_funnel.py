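#!/usr/bin/env python
"""Curate bona fide lncRNAs and run the CRPC-Lnc candidate funnel.

Noncoding transcripts whose exons coincide with same-strand coding exons
are excluded (indistinguishable from the mRNA in stranded RNA-seq); kept
lncRNAs are classified antisense / intergenic / other. CRPC-upregulated
curated lncRNAs are then narrowed to those with an androgen/AR regulation
call and AR binding within 10 kb of the TSS — the final candidate
report.
"""

from pathlib import Path

import pandas as pd

from crpclnc.core import read_bed, read_gtf, read_matrix, read_sample_sheet
from crpclnc.curation import curate_all
from crpclnc.expression import compute_rpkm
from crpclnc.pipeline import read_classifications, write_curation
from crpclnc.regulon import assign_peaks, crpc_lnc_funnel
from crpclnc.simulate import CONTRAST_OF_LINE

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "analysis" / "sim"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    genes = read_gtf(SIM / "genes.gtf")
    coding = [g for g in genes if g.biotype == "coding"]
    noncoding = [g for g in genes if g.biotype == "noncoding"]

    calls, summary = curate_all(noncoding, coding)
    write_curation(calls, OUT / "curation.tsv")
    print("curation:", dict(summary))

    classifications = read_classifications(OUT / "classification.tsv")
    klass = {c.gene_id: c.klass for c in classifications}
    kept = {c.gene_id for c in calls if c.verdict == "kept"}
    candidates = [g for g in noncoding
                  if g.gene_id in kept
                  and klass[g.gene_id] in ("Type_A", "Type_B")]

    regulation = []
    from crpclnc.regulon import call_regulation

    for line, contrast in CONTRAST_OF_LINE.items():
        sheet = read_sample_sheet(SIM / f"{line}_samples.tsv")
        rpkm = compute_rpkm(
            read_matrix(SIM / f"{line}_counts.tsv", sheet), genes, sheet
        )
        regulation.append(call_regulation(rpkm, sheet, contrast, cell_line=line))

    peaks = read_bed(SIM / "AR_22Rv1.bed")
    binding = assign_peaks(peaks, genes, 10_000)

    cohort_sheet = read_sample_sheet(SIM / "cohort_samples.tsv",
                                     declared_groups=("benign", "pca", "crpc"))
    cohort_rpkm = compute_rpkm(
        read_matrix(SIM / "cohort_counts.tsv", cohort_sheet), genes, cohort_sheet
    )
    funnel = crpc_lnc_funnel(candidates, regulation, binding,
                             rpkm=cohort_rpkm, sheet=cohort_sheet)
    funnel.to_frame().to_csv(OUT / "candidates.tsv", sep="\t", index=False,
                             float_format="%.10g")
    pd.DataFrame({"stage": list(funnel.stage_counts),
                  "count": list(funnel.stage_counts.values())}
                 ).to_csv(OUT / "funnel_stages.tsv", sep="\t", index=False)

    print("funnel: curated CRPC-up lncRNAs -> regulated -> bound within 10 kb")
    print("        " + " -> ".join(str(v) for v in funnel.stage_counts.values()))
    if funnel.rows:
        print("candidates (location, annotation, mean RPKM benign/Pca/CRPC):")
        for row in funnel.rows:
            m = row.mean_rpkm
            print(f"  {row.gene_id}  {row.location}  {row.annotation}  "
                  f"{m.get('benign', float('nan')):.1f} / "
                  f"{m.get('pca', float('nan')):.1f} / "
                  f"{m.get('crpc', float('nan')):.1f}")


if __name__ == "__main__":
    main()
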