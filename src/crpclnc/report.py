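"""Set-overlap chi-square tests, fold-change tables and the pipeline summary."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SampleSheet, ValidationError
from .curation import LncContextCall
from .expression import GeneClassification
from .regulon import FunnelReport


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: in/out of set 1; columns: in/out of set 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("cell counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    p_value: float
    df: int = 1


def chisq_2x2(table: ContingencyTable2x2, yates: bool = False) -> ChisqResult:
    """Pearson chi-square on a 2x2 table (df=1), Yates correction optional.

    Errors when a marginal is zero (expected counts undefined).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValidationError("zero marginal: chi-square statistic undefined")
    stat, p, dof, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=yates
    )
    return ChisqResult(statistic=float(stat), p_value=float(p), df=int(dof))


def overlap_test(
    universe: Collection[str],
    set1: Collection[str],
    set2: Collection[str],
    yates: bool = False,
) -> tuple[ContingencyTable2x2, ChisqResult]:
    """2x2 membership table of two gene sets within a universe + chi-square."""
    uni = set(universe)
    s1, s2 = set(set1), set(set2)
    if not s1 <= uni or not s2 <= uni:
        stray = sorted((s1 | s2) - uni)[:5]
        raise ValidationError(f"sets not contained in universe: {stray}")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(uni - s1 - s2)
    table = ContingencyTable2x2(a, b, c, d)
    return table, chisq_2x2(table, yates=yates)


def heatmap_table(
    rpkm: ExpressionMatrix,
    sheet: SampleSheet,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-sample log2 fold change relative to the benign-group mean.

    entry = log2((value + eps) / (benign mean + eps)); columns are grouped
    by tissue class. Presentation-layer only (feeds heatmap rendering).
    """
    if "benign" not in sheet.groups:
        raise ValidationError("heatmap_table: benign group missing")
    benign = sheet.samples_in("benign")
    base = rpkm.values[benign].mean(axis=1).to_numpy(dtype=float)
    ordered = []
    for group in sheet.groups:
        ordered.extend(sheet.samples_in(group))
    arr = rpkm.values[ordered].to_numpy(dtype=float)
    table = np.log2((arr + pseudocount) / (base[:, None] + pseudocount))
    return pd.DataFrame(table, index=rpkm.values.index, columns=ordered)


@dataclass
class PipelineSummary:
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.counts), "count": list(self.counts.values())}
        )


def assemble_report(
    classifications: Sequence[GeneClassification],
    curation_calls: Sequence[LncContextCall],
    funnel: FunnelReport,
) -> PipelineSummary:
    """Assemble the stage-count summary of one full discovery run."""
    class_ids = {c.gene_id for c in classifications}
    stray = [c.gene_id for c in curation_calls if c.gene_id not in class_ids]
    if stray:
        raise ValidationError(
            f"curation genes absent from classification universe: {stray[:5]}"
        )
    klass = {c.gene_id: c for c in classifications}
    kept = {c.gene_id for c in curation_calls if c.verdict == "kept"}
    up = {g for g, c in klass.items() if c.klass in ("Type_A", "Type_B")}

    counts = {
        "expression_filter_pass": sum(
            c.passed_expression_filter for c in classifications
        ),
        "type_a": sum(c.klass == "Type_A" for c in classifications),
        "type_b": sum(c.klass == "Type_B" for c in classifications),
        "curated_lncrna": len(kept),
        "curated_lncrna_type_a": len(
            {g for g in kept if klass[g].klass == "Type_A"}
        ),
        "curated_lncrna_type_b": len(
            {g for g in kept if klass[g].klass == "Type_B"}
        ),
        "funnel_curated_upregulated": funnel.stage_counts["curated"],
        "funnel_regulated": funnel.stage_counts["regulated"],
        "funnel_bound_within_window": funnel.stage_counts["bound_within_window"],
    }
    return PipelineSummary(counts=counts)
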