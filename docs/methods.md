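# Methods

## The discovery workflow

`crpclnc` implements a staged workflow for finding androgen-receptor (AR)
regulated long non-coding RNAs that are upregulated in castration-resistant
prostate cancer (CRPC):

1. **Quantification.** Read counts from a three-group tissue cohort
   (benign prostate n=6, localized prostate cancer "Pca" n=8, CRPC n=6)
   are normalized to RPKM: `count x 1e9 / (exonic_length_bp x library_size)`.
   Library sizes come from the sample sheet, not from matrix column sums,
   so RPKM does not depend on which genes happen to be quantified.
2. **Classification.** Genes passing a per-database expression filter on
   the CRPC-group mean RPKM (RefSeq > 5; GENCODE and NONCODE > 1) are
   tested with the two-sided Mann-Whitney U test. *Type_A* genes are
   significantly up in CRPC against both Pca and benign; *Type_B* against
   benign only, with Type_A removed. The two classes are disjoint by
   construction. No multiple-testing correction is applied by default —
   the workflow's criterion is a single P < 0.05 — but Benjamini-Hochberg
   is available behind a flag.
3. **Regulon integration.** AR ChIP-seq peaks are assigned to genes by
   TSS proximity; a protein-coding AR target must be bound within 50 kb
   and respond to androgen (DHT vs vehicle in LNCaP/VCaP) or to AR
   knockdown (siAR vs siControl in the AR-V7-expressing CRPC model 22Rv1).
4. **lncRNA curation.** Noncoding transcripts whose exons overlap a
   same-strand coding exon are excluded as indistinguishable from the
   mRNA; kept transcripts are classified antisense / intergenic / other.
5. **Candidate funnel.** Curated CRPC-upregulated lncRNAs are narrowed to
   those with any androgen/AR regulation call, then to those with AR
   binding within 10 kb of the TSS; the survivors form the candidate
   report (location, annotation, per-group mean RPKM).

## The exact Mann-Whitney test

With groups of 6 and 8 the U statistic is highly discrete, so p-values are
computed exactly whenever `n1 + n2 <= 20`: all `C(n1+n2, n1)` label
assignments are enumerated and the two-sided p is the share of assignments
whose rank-sum deviates from its null mean at least as much as observed.
Ties take midranks; ranks are doubled internally so all comparisons are on
exact integers. The smallest achievable two-sided p is therefore 2/3003
(~6.7e-4) for 6 vs 8 and 2/924 (~2.2e-3) for 6 vs 6 — the floor any
"significant" gene in this design actually reaches. Beyond 20 samples the
normal approximation with tie and continuity corrections (scipy) is used.
The reported direction is the sign of the median difference; a gene must
be significant *and* directed up to count as upregulated.

## Binding distance and the closest-gene rule

Peak-to-TSS distance is interval-to-point: 0 when the TSS lies inside the
peak, else the distance to the nearer peak edge (using `end - 1`, the last
covered base). By default a peak is first assigned to its closest-TSS
gene(s) — all genes tied at the minimum — and only an assigned peak can
bind a gene; this reads "closest genes to AR-binding sites" and "within
50 kb" as a conjunction. `require_closest=False` relaxes to a pure window
criterion. Enlarging the window never unbinds a gene, and every gene bound
at 10 kb is bound at 50 kb.

## Fold-change calls

Regulation is called from pseudocounted mean-RPKM ratios,
`fold = (mean_treated + eps) / (mean_control + eps)` with `eps = 0.01`
applied symmetrically so that `fold(a, a) = 1` and all-zero genes are
"unchanged". Thresholds are strict: fold > 1.5 induced, fold < 0.8
repressed, read with the sign conventions of each contrast (a gene that
*falls* under siAR is AR-*induced*). The stored call is always the
direction of AR/androgen regulation of the gene.

## Curation rules

Exclusion requires same-strand exonic overlap of >= 1 bp; because the
libraries are directional, opposite-strand exon overlap is distinguishable
and never triggers exclusion. A configurable minimum overlap fraction of
the candidate's exonic length (default 0, i.e. any overlap) is exposed
because sub-exon overlaps are a judgment call in manual curation.
"Antisense" is decided on gene-body overlap with an opposite-strand coding
gene — a lncRNA in the antisense region of a coding locus — not on exon
overlap; "intergenic" means no coding gene-body overlap on either strand;
everything else kept is "other" (sense/intronic/overlapping).

## The synthetic study

The generator (`crpclnc.simulate`) emulates the study design so every
stage is testable with no external data. Counts are negative binomial with
gene mean `RPKM_target x length_kb x library_size / 1e6` and dispersion
0.1 (a standard bulk RNA-seq noise level); library sizes are drawn in
15-30 million. Planted effects at the defaults: 50 Type_A and 30 Type_B
genes (CRPC-group RPKM targets 25 vs 2.5/3.5 for coding Type_A, equal
CRPC/Pca levels for Type_B); 40 coding AR targets with peaks at 49 kb from
the TSS plus 10 bound-but-unregulated genes and 10 regulated genes with
peaks at 51 kb (just outside the window); 30 antisense, 30 intergenic and
20 exonic-decoy lncRNAs, of which 16 are CRPC-upregulated, 12 regulated
and 8 AR-bound within 10 kb — the planted funnel. Planted fold factors are
3x (and 1/3x).

Two realism levels are provided. In `separation="complete"` each planted
gene's counts are rejection-sampled until the realized data satisfy the
planted truth exactly — every Type_A gene's minimum CRPC RPKM exceeds the
maximum of both comparison groups, realized folds fall on the intended
side of the 1.5/0.8 thresholds, and null genes are neither significant
nor outside the fold band. This makes perfect recovery of the planted
labels a property of the fixture and pins the exact p-values a recovered
gene attains (2/3003 and 2/924). `separation="noisy"` draws once with no
rejection and is the mode for null calibration (type-I error measurement).

Genomic layout guarantees unambiguous binding truth: a planted peak's
clearance zone contains no TSS other than its target's within the 50 kb
window, and decoy peaks are placed beyond the window of every TSS. Genes
with peak clearances are ~20x wider than plain genes, so the generator
deals them across chromosomes per footprint class and raises a generation
error when the requested genes cannot fit the chromosome length.
Planted-bound lncRNAs are intergenic by construction: an antisense lncRNA
shares its host's TSS neighborhood and cannot own an exclusive peak.

What the generator does **not** emulate: isoform structure and splice
variants (notably AR-V7 vs full-length AR), mapping ambiguity between the
three annotation databases, batch effects, tumor purity and the biological
correlation structure of real cohorts. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated model,
not performance on real tissue data.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GTF is converted
  on read/write, BED is native. TSS is `start` on "+", `end - 1` on "-".
- "Highly expressed in CRPC" is operationalized as the *mean* RPKM over
  CRPC samples (matching the per-group averages of the candidate report);
  median or maximum would be defensible alternatives.
- The three source databases are modeled as a per-gene tag in one merged
  GTF rather than three separate annotations; a transcript present in two
  databases must be pre-resolved to one tag.
- Chi-square overlap tests default to no Yates correction (flag
  available); tables with a zero marginal are rejected rather than
  returning 0/0.
- The benign-relative heatmap table uses log2 with the same symmetric
  pseudocount; it is presentation-layer only.
- Type_A imposes no constraint on the benign-vs-Pca comparison; only the
  two CRPC contrasts are tested.
- All randomness is confined to the generator; analysis stages are
  deterministic, and two runs on the same inputs are byte-identical.

## Problem sizes

Default synthetic study: 380 genes (300 coding, 80 noncoding) on two 5 Mb
chromosomes, 20 cohort samples, 3 cell lines x 4 samples, ~80 peaks. The
null-calibration cohort uses 2,000 genes on 25 Mb chromosomes. These sizes
exercise every code path — exact tests, both windows, all three lncRNA
contexts, decoy peaks — while a full analysis completes in seconds.

## Known limitations

- The exact test enumerates up to C(20,10) = 184,756 assignments; the
  cutoff is chosen to cover the 6/8/6 design exactly, and larger designs
  silently switch to the corrected normal approximation.
- The funnel reduction from bound candidates to the final named set in
  the original study used a literature novelty criterion, which is not
  computable and is out of scope.
- Percentages of the cell-line overlap comparisons depend on denominator
  conventions; the raw 2x2 tables are exposed so any convention can be
  recomputed.
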