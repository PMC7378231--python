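#!/usr/bin/env python
"""Assemble the run summary and the benign-relative log2 fold-change table.

Prints the stage counts of the whole discovery workflow and writes a
heatmap-ready table (per-sample log2 RPKM relative to the benign-group
mean) for the classified Type_A genes.
"""

from pathlib import Path

import pandas as pd

from crpclnc.core import ExpressionMatrix, read_sample_sheet
from crpclnc.curation import LncContextCall
from crpclnc.pipeline import read_classifications
from crpclnc.regulon import FunnelReport
from crpclnc.report import assemble_report, heatmap_table

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "analysis" / "sim"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    classifications = read_classifications(OUT / "classification.tsv")
    cur = pd.read_csv(OUT / "curation.tsv", sep="\t", na_filter=False)
    curation_calls = [
        LncContextCall(r["gene_id"], r["verdict"],
                       r["context"] or None, ())
        for r in cur.to_dict("records")
    ]
    stages = pd.read_csv(OUT / "funnel_stages.tsv", sep="\t")
    funnel = FunnelReport(
        stage_counts=dict(zip(stages["stage"], stages["count"])), rows=[]
    )
    summary = assemble_report(classifications, curation_calls, funnel)
    summary.to_frame().to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print("discovery summary:")
    for stage, count in summary.counts.items():
        print(f"  {stage:32s} {count}")

    sheet = read_sample_sheet(SIM / "cohort_samples.tsv",
                              declared_groups=("benign", "pca", "crpc"))
    rpkm_df = pd.read_csv(OUT / "cohort_rpkm.tsv", sep="\t", index_col=0)
    type_a = [c.gene_id for c in classifications if c.klass == "Type_A"]
    rpkm = ExpressionMatrix(values=rpkm_df.loc[type_a], unit="rpkm")
    table = heatmap_table(rpkm, sheet)
    table.to_csv(OUT / "heatmap_log2fc_type_a.tsv", sep="\t",
                 float_format="%.4f")
    print(f"log2 fold-change table for {len(type_a)} Type_A genes -> "
          f"{OUT / 'heatmap_log2fc_type_a.tsv'}")


if __name__ == "__main__":
    main()
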