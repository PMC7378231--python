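#!/usr/bin/env python
"""Integrate AR ChIP-seq binding with condition fold changes per cell line.

A gene is an AR target when an AR peak lies within 50 kb of its TSS (and
the peak's closest gene is that gene) AND the gene responds to androgen
(DHT fold > 1.5 / < 0.8 in LNCaP, VCaP) or to AR knockdown (siAR fold
< 0.8 / > 1.5 in 22Rv1). Also tests, chi-square on the 2x2 overlap table,
whether AR targets are enriched among CRPC-upregulated genes.
"""

from pathlib import Path

import pandas as pd

from crpclnc.core import read_bed, read_gtf, read_matrix, read_sample_sheet
from crpclnc.expression import compute_rpkm
from crpclnc.pipeline import read_classifications, write_binding, write_regulation
from crpclnc.regulon import (
    CONTRAST_OF_LINE_DEFAULT,
    ar_target_genes,
    assign_peaks,
    call_regulation,
)
from crpclnc.report import overlap_test

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "analysis" / "sim"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    genes = read_gtf(SIM / "genes.gtf")
    binding_by_line, regulation_by_line = {}, {}
    for line, contrast in CONTRAST_OF_LINE_DEFAULT.items():
        sheet = read_sample_sheet(SIM / f"{line}_samples.tsv")
        counts = read_matrix(SIM / f"{line}_counts.tsv", sheet)
        rpkm = compute_rpkm(counts, genes, sheet)
        regulation_by_line[line] = call_regulation(
            rpkm, sheet, contrast, cell_line=line
        )
        peaks = read_bed(SIM / f"AR_{line}.bed")
        binding_by_line[line] = assign_peaks(peaks, genes, 50_000)
        write_regulation(regulation_by_line[line], OUT / f"regulation_{line}.tsv")
        write_binding(binding_by_line[line], OUT / f"binding_{line}.tsv")
        n_reg = sum(c.regulated for c in regulation_by_line[line])
        n_bound = sum(b.bound for b in binding_by_line[line])
        print(f"{line}: {n_reg} regulated, {n_bound} AR-bound within 50 kb")

    targets = ar_target_genes(binding_by_line["22Rv1"], regulation_by_line)
    print(f"AR targets LNCaP&VCaP: {len(targets.lncap_vcap)}")
    print(f"AR targets 22Rv1:      {len(targets.r22rv1)}")
    rows = [{"set": "LNCaP&VCaP", "gene_id": g}
            for g in sorted(targets.lncap_vcap)]
    rows += [{"set": "22Rv1", "gene_id": g} for g in sorted(targets.r22rv1)]
    pd.DataFrame(rows).to_csv(OUT / "ar_targets.tsv", sep="\t", index=False)

    # enrichment of AR targets among CRPC-upregulated genes
    classifications = read_classifications(OUT / "classification.tsv")
    universe = [c.gene_id for c in classifications]
    up = {c.gene_id for c in classifications if c.klass in ("Type_A", "Type_B")}
    table, chisq = overlap_test(
        universe, targets.r22rv1 | targets.lncap_vcap, up
    )
    print(f"AR-target x CRPC-up overlap: a={table.a} b={table.b} "
          f"c={table.c} d={table.d}; chi2={chisq.statistic:.2f} "
          f"p={chisq.p_value:.3g}")


if __name__ == "__main__":
    main()
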