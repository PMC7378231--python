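"""RPKM normalization, exact Mann-Whitney testing, and CRPC gene classes.

The cohort design is three tissue groups (benign n=6, localized prostate
cancer "pca" n=8, CRPC n=6). Differential testing uses the two-sided
Mann-Whitney U test; with group sizes this small the p-value is computed by
full enumeration of all C(n1+n2, n1) label assignments (midranks for ties),
so the smallest achievable two-sided p is 2/3003 for 6 vs 8 and 2/924 for
6 vs 6. Genes are classified:

* expression filter: mean RPKM over CRPC samples above the per-database
  threshold (RefSeq > 5; GENCODE/NONCODE > 1);
* Type_A: filter and significantly up in CRPC vs both pca and benign;
* Type_B: filter and significantly up in CRPC vs benign, minus Type_A.

No multiple-testing correction is applied by default (single P < alpha
criterion); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    GeneModel,
    SampleSheet,
    Thresholds,
    ValidationError,
)

EXACT_LIMIT = 20  # n1 + n2 up to which the exact enumeration is used


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    comparison: str
    u_statistic: float
    p_value: float
    direction: str  # up | down | none (first group minus second, by medians)
    method: str  # exact | normal_approx


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    klass: str  # Type_A | Type_B | unclassified
    passed_expression_filter: bool
    p_crpc_vs_pca: float
    p_crpc_vs_benign: float


@lru_cache(maxsize=32)
def _combination_matrix(n1: int, n: int) -> np.ndarray:
    """All C(n, n1) index subsets of size n1, as an int array (rows=subsets)."""
    combs = list(itertools.combinations(range(n), n1))
    return np.array(combs, dtype=np.intp)


def _midranks_doubled(pooled: np.ndarray) -> np.ndarray:
    """Midranks of the pooled sample, doubled so ties give exact integers."""
    ranks = stats.rankdata(pooled, method="average")
    doubled = np.rint(ranks * 2).astype(np.int64)
    return doubled


def mann_whitney(
    a: Sequence[float], b: Sequence[float], gene_id: str = "", comparison: str = ""
) -> DifferentialResult:
    """Two-sided Mann-Whitney U test of two independent groups.

    Exact p by full enumeration of all label assignments when
    ``n1 + n2 <= 20`` (midranks for ties); otherwise the normal
    approximation with tie and continuity corrections. The reported
    direction is the sign of the median difference (first minus second).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("values must be finite")

    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks2 = _midranks_doubled(pooled)  # doubled midranks (integers)
    r1_2 = int(ranks2[:n1].sum())
    u1 = r1_2 / 2.0 - n1 * (n1 + 1) / 2.0

    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "up"
    elif med_a < med_b:
        direction = "down"
    else:
        direction = "none"

    if np.all(pooled == pooled[0]):
        return DifferentialResult(
            gene_id, comparison, n1 * n2 / 2.0, 1.0, "none", "exact"
        )

    if n <= EXACT_LIMIT:
        comb = _combination_matrix(n1, n)
        sums = ranks2[comb].sum(axis=1)  # doubled rank sums, exact integers
        center2 = n1 * (n + 1)  # doubled null mean of R1
        obs_dev = abs(r1_2 - center2)
        count = int(np.count_nonzero(np.abs(sums - center2) >= obs_dev))
        p = count / comb.shape[0]
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(1.0, res.pvalue))
        method = "normal_approx"

    return DifferentialResult(gene_id, comparison, float(u1), p, direction, method)


def compute_rpkm(
    counts: ExpressionMatrix,
    genes: Sequence[GeneModel],
    sheet: SampleSheet,
) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million: count * 1e9 / (exonic_length * library).

    Library sizes come from the sample sheet, not from column sums, so that
    RPKM is invariant to which genes happen to be in the matrix.
    """
    if counts.unit != "count":
        raise ValidationError("compute_rpkm expects a count matrix")
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in counts.genes if gid not in by_id]
    if missing:
        raise ValidationError(f"genes without a model: {missing[:10]}")
    lengths = np.array(
        [by_id[gid].exonic_length for gid in counts.genes], dtype=float
    )
    if (lengths <= 0).any():
        raise ValidationError("gene with non-positive exonic length")
    libs = np.array(
        [sheet.library_size(s) for s in counts.samples], dtype=float
    )
    if (libs <= 0).any():
        raise ValidationError("zero or negative library size")
    arr = counts.values.to_numpy(dtype=float)
    rpkm = arr * 1e9 / (lengths[:, None] * libs[None, :])
    df = pd.DataFrame(
        rpkm, index=counts.values.index, columns=counts.values.columns
    )
    return ExpressionMatrix(values=df, unit="rpkm")


def group_means(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Convenience: DataFrame of per-group mean expression (genes x groups)."""
    cols = {}
    for group in sheet.groups:
        samples = sheet.samples_in(group)
        cols[group] = matrix.values[samples].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.values.index)


def classify_genes(
    rpkm: ExpressionMatrix,
    sheet: SampleSheet,
    genes: Sequence[GeneModel],
    thresholds: Thresholds = Thresholds(),
    bh_correct: bool = False,
) -> list[GeneClassification]:
    """Classify genes into Type_A / Type_B / unclassified.

    The expression filter is the mean RPKM over CRPC samples compared with
    the per-database threshold. Type_A requires significant up-regulation
    in CRPC against both other groups; Type_B against benign only, with
    Type_A removed. ``bh_correct`` optionally applies Benjamini-Hochberg
    within each comparison before thresholding (off by default).
    """
    if rpkm.unit != "rpkm":
        raise ValidationError("classify_genes expects an RPKM matrix")
    for group in ("benign", "pca", "crpc"):
        n = len(sheet.samples_in(group))
        if n < 2:
            raise ValidationError(
                f"group {group!r} has {n} samples; need at least 2"
            )
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in rpkm.genes if gid not in by_id]
    if missing:
        raise ValidationError(f"genes without a model: {missing[:10]}")

    crpc_cols = sheet.samples_in("crpc")
    pca_cols = sheet.samples_in("pca")
    benign_cols = sheet.samples_in("benign")
    vals = rpkm.values

    p_pca = np.empty(len(rpkm.genes))
    p_ben = np.empty(len(rpkm.genes))
    up_pca = np.zeros(len(rpkm.genes), dtype=bool)
    up_ben = np.zeros(len(rpkm.genes), dtype=bool)
    passed = np.zeros(len(rpkm.genes), dtype=bool)

    crpc_arr = vals[crpc_cols].to_numpy(dtype=float)
    pca_arr = vals[pca_cols].to_numpy(dtype=float)
    ben_arr = vals[benign_cols].to_numpy(dtype=float)

    for i, gid in enumerate(rpkm.genes):
        model = by_id[gid]
        passed[i] = crpc_arr[i].mean() > thresholds.rpkm_min[model.database]
        r_pca = mann_whitney(crpc_arr[i], pca_arr[i], gid, "crpc_vs_pca")
        r_ben = mann_whitney(crpc_arr[i], ben_arr[i], gid, "crpc_vs_benign")
        p_pca[i] = r_pca.p_value
        p_ben[i] = r_ben.p_value
        up_pca[i] = r_pca.direction == "up"
        up_ben[i] = r_ben.direction == "up"

    if bh_correct:
        p_pca = stats.false_discovery_control(p_pca, method="bh")
        p_ben = stats.false_discovery_control(p_ben, method="bh")

    out: list[GeneClassification] = []
    for i, gid in enumerate(rpkm.genes):
        sig_pca = (p_pca[i] < thresholds.alpha) and up_pca[i]
        sig_ben = (p_ben[i] < thresholds.alpha) and up_ben[i]
        if passed[i] and sig_pca and sig_ben:
            klass = "Type_A"
        elif passed[i] and sig_ben:
            klass = "Type_B"
        else:
            klass = "unclassified"
        out.append(
            GeneClassification(
                gene_id=gid,
                klass=klass,
                passed_expression_filter=bool(passed[i]),
                p_crpc_vs_pca=float(p_pca[i]),
                p_crpc_vs_benign=float(p_ben[i]),
            )
        )
    return out
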