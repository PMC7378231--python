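#!/usr/bin/env python
"""Quantify the tissue cohort to RPKM and call Type_A / Type_B genes.

Type_A genes are significantly upregulated in CRPC versus both localized
cancer and benign prostate (exact Mann-Whitney, P < 0.05, after the
per-database expression filter); Type_B are upregulated versus benign only,
with Type_A removed. Writes cohort_rpkm.tsv and classification.tsv.
"""

from pathlib import Path

from crpclnc.core import read_gtf, read_matrix, read_sample_sheet, write_matrix
from crpclnc.expression import classify_genes, compute_rpkm, group_means
from crpclnc.pipeline import write_classifications

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "analysis" / "sim"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    genes = read_gtf(SIM / "genes.gtf")
    sheet = read_sample_sheet(SIM / "cohort_samples.tsv",
                              declared_groups=("benign", "pca", "crpc"))
    counts = read_matrix(SIM / "cohort_counts.tsv", sheet)
    rpkm = compute_rpkm(counts, genes, sheet)
    write_matrix(rpkm, OUT / "cohort_rpkm.tsv")

    calls = classify_genes(rpkm, sheet, genes)
    write_classifications(calls, group_means(rpkm, sheet),
                          OUT / "classification.tsv")

    n_pass = sum(c.passed_expression_filter for c in calls)
    n_a = sum(c.klass == "Type_A" for c in calls)
    n_b = sum(c.klass == "Type_B" for c in calls)
    print(f"{len(calls)} genes; {n_pass} pass the CRPC expression filter")
    print(f"Type_A (up vs Pca and benign): {n_a}")
    print(f"Type_B (up vs benign only):    {n_b}")


if __name__ == "__main__":
    main()
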