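"""RPKM formula, exact Mann-Whitney against brute force, gene classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crpclnc.core import ExpressionMatrix, SampleSheet, Thresholds, ValidationError
from crpclnc.expression import (
    classify_genes,
    compute_rpkm,
    group_means,
    mann_whitney,
)
from conftest import cohort_sheet, make_gene, matrix_from_rows


# ---------------------------------------------------------------------------
# independent brute-force oracle for the exact two-sided Mann-Whitney test
# ---------------------------------------------------------------------------

def _midranks(values):
    """Average ranks (1-based) computed by plain sorting, no scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_mw_p(a, b):
    """Two-sided exact p: share of label assignments at least as extreme.

    Extremity is the absolute deviation of the group-1 rank sum from its
    null mean over all C(n1+n2, n1) assignments (midranks for ties).
    """
    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    ranks = _midranks(pooled)
    center = n1 * (n + 1) / 2
    obs = abs(sum(ranks[:n1]) - center)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in comb) - center) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation_6_vs_8(self):
        r = mann_whitney([10, 11, 12, 13, 14, 15], [1, 2, 3, 4, 5, 6, 7, 8])
        assert r.p_value == pytest.approx(2 / 3003, abs=1e-15)
        assert r.direction == "up"
        assert r.method == "exact"

    def test_identical_groups_give_p_one(self):
        r = mann_whitney([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert r.p_value == 1.0
        assert r.direction == "none"

    def test_all_constant_values(self):
        r = mann_whitney([5, 5, 5], [5, 5, 5])
        assert r.p_value == 1.0
        assert r.direction == "none"

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
    )
    def test_u_statistic_identity(self, a, b):
        u_ab = mann_whitney(a, b).u_statistic
        u_ba = mann_whitney(b, a).u_statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert 0 <= u_ab <= len(a) * len(b)

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_exact_p_matches_enumeration(self, with_ties):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            if with_ties:
                a = rng.integers(0, 6, n1).astype(float)
                b = rng.integers(0, 6, n2).astype(float)
            else:
                vals = rng.permutation(n1 + n2).astype(float)
                a, b = vals[:n1], vals[n1:]
            got = mann_whitney(a, b).p_value
            want = brute_force_mw_p(list(a), list(b))
            assert got == pytest.approx(want, abs=1e-12)

    def test_minimum_achievable_p_values(self):
        # discreteness floor of the exact test at the study's group sizes
        r68 = mann_whitney(list(range(100, 106)), list(range(8)))
        assert r68.p_value == pytest.approx(2 / 3003, abs=1e-15)
        r66 = mann_whitney(list(range(100, 106)), list(range(6)))
        assert r66.p_value == pytest.approx(2 / 924, abs=1e-15)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 1, 15)
        b = rng.normal(0, 1, 15)
        r = mann_whitney(a, b)
        assert r.method == "normal_approx"
        assert 0 < r.p_value <= 1

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([1], [2, 3])


class TestComputeRpkm:
    def test_direct_formula(self):
        genes = [make_gene("g1", start=0, end=2000, exons=[(0, 2000)])]
        sheet = SampleSheet(
            entries={"s1": ("crpc", 10_000_000)},
            declared_groups=("benign", "pca", "crpc"),
        )
        counts = matrix_from_rows({"g1": [50]}, ["s1"], unit="count")
        rpkm = compute_rpkm(counts, genes, sheet)
        assert rpkm.values.loc["g1", "s1"] == pytest.approx(2.5)
        assert rpkm.unit == "rpkm"

    def test_zero_count_gives_zero(self):
        genes = [make_gene("g1", start=0, end=2000)]
        sheet = SampleSheet(entries={"s1": ("x", 10_000_000)})
        counts = matrix_from_rows({"g1": [0]}, ["s1"], unit="count")
        assert compute_rpkm(counts, genes, sheet).values.loc["g1", "s1"] == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        genes = [
            make_gene(f"g{i}", start=0, end=1000 + 100 * i) for i in range(5)
        ]
        raw = rng.integers(0, 500, (5, 3))
        lib = [10_000_000, 20_000_000, 15_000_000]
        s1 = SampleSheet(
            entries={f"s{j}": ("x", lib[j]) for j in range(3)}
        )
        s2 = SampleSheet(
            entries={f"s{j}": ("x", 2 * lib[j]) for j in range(3)}
        )
        m1 = ExpressionMatrix(
            pd.DataFrame(raw, index=[g.gene_id for g in genes],
                         columns=["s0", "s1", "s2"]),
            unit="count",
        )
        m2 = ExpressionMatrix(
            pd.DataFrame(raw * 2, index=[g.gene_id for g in genes],
                         columns=["s0", "s1", "s2"]),
            unit="count",
        )
        r1 = compute_rpkm(m1, genes, s1).values.to_numpy()
        r2 = compute_rpkm(m2, genes, s2).values.to_numpy()
        np.testing.assert_allclose(r1, r2)

    def test_missing_model_lists_gene(self):
        sheet = SampleSheet(entries={"s1": ("x", 10)})
        counts = matrix_from_rows({"gX": [1]}, ["s1"], unit="count")
        with pytest.raises(ValidationError, match="gX"):
            compute_rpkm(counts, [], sheet)


def _classification_fixture():
    """Three genes: a clear Type_A, a Type_B, and a filter-failing gene."""
    sheet = cohort_sheet()
    samples = sheet.sample_ids
    rows = {}
    # Type_A: CRPC clearly above both other groups, mean 20 > 5
    rows["ga"] = [2.0 + 0.1 * i for i in range(6)] \
        + [3.0 + 0.1 * i for i in range(8)] + [20.0 + i for i in range(6)]
    # Type_B: CRPC ~ Pca, both far above benign
    rows["gb"] = [2.0 + 0.1 * i for i in range(6)] \
        + [18.0, 21.0, 19.0, 22.0, 18.5, 20.5, 21.5, 19.5] \
        + [19.0, 20.0, 21.0, 18.0, 22.0, 20.5]
    # below the RefSeq filter despite perfect separation
    rows["gc"] = [0.1 * i for i in range(6)] \
        + [0.5 + 0.1 * i for i in range(8)] + [3.0 + 0.1 * i for i in range(6)]
    genes = [make_gene(g, start=i * 10_000, end=i * 10_000 + 2000)
             for i, g in enumerate(rows)]
    return matrix_from_rows(rows, samples), sheet, genes


class TestClassifyGenes:
    def test_planted_classes_recovered(self):
        rpkm, sheet, genes = _classification_fixture()
        out = {c.gene_id: c for c in classify_genes(rpkm, sheet, genes)}
        assert out["ga"].klass == "Type_A"
        assert out["ga"].p_crpc_vs_pca == pytest.approx(2 / 3003, abs=1e-15)
        assert out["ga"].p_crpc_vs_benign == pytest.approx(2 / 924, abs=1e-15)
        assert out["gb"].klass == "Type_B"
        assert out["gc"].klass == "unclassified"
        assert not out["gc"].passed_expression_filter

    def test_type_a_and_b_disjoint_and_require_filter(self):
        rpkm, sheet, genes = _classification_fixture()
        calls = classify_genes(rpkm, sheet, genes)
        a = {c.gene_id for c in calls if c.klass == "Type_A"}
        b = {c.gene_id for c in calls if c.klass == "Type_B"}
        assert not a & b
        for c in calls:
            if c.klass != "unclassified":
                assert c.passed_expression_filter

    def test_gencode_threshold_is_lower(self):
        rpkm, sheet, genes = _classification_fixture()
        # the same low-expressed gene passes when tagged GENCODE (> 1)
        genes2 = [
            g if g.gene_id != "gc" else make_gene(
                "gc", start=g.interval.start, end=g.interval.end,
                database="GENCODE", biotype="noncoding",
            )
            for g in genes
        ]
        out = {c.gene_id: c for c in classify_genes(rpkm, sheet, genes2)}
        assert out["gc"].passed_expression_filter
        assert out["gc"].klass == "Type_A"

    def test_too_small_group_rejected(self):
        rpkm, sheet, genes = _classification_fixture()
        small = SampleSheet(
            entries={
                k: v for k, v in sheet.entries.items()
                if not k.startswith("benign") or k == "benign_1"
            },
            declared_groups=("benign", "pca", "crpc"),
        )
        vals = rpkm.values[small.sample_ids]
        small_m = ExpressionMatrix(values=vals, unit="rpkm")
        with pytest.raises(ValidationError, match="benign"):
            classify_genes(small_m, small, genes)


def test_group_means_matches_manual_average():
    rpkm, sheet, _ = _classification_fixture()
    means = group_means(rpkm, sheet)
    crpc = sheet.samples_in("crpc")
    assert means.loc["ga", "crpc"] == pytest.approx(
        rpkm.values.loc["ga", crpc].mean()
    )
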