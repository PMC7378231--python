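"""Peak-to-TSS assignment vs brute force, fold-change calls, funnel nesting."""

import numpy as np
import pytest

from crpclnc.core import (
    GenomicInterval,
    Peak,
    PeakSet,
    SampleSheet,
    Thresholds,
    ValidationError,
)
from crpclnc.regulon import (
    ar_target_genes,
    assign_peaks,
    call_regulation,
    crpc_lnc_funnel,
    peak_tss_distance,
)
from crpclnc.simulate import make_funnel_fixture
from conftest import make_gene, matrix_from_rows


# ---------------------------------------------------------------------------
# brute-force oracle: plain double loop over peaks x genes
# ---------------------------------------------------------------------------

def brute_force_bound(peaks, genes, window_bp, require_closest=True):
    dists = {}
    for j, p in enumerate(peaks.peaks):
        for i, g in enumerate(genes):
            if p.interval.chrom != g.interval.chrom:
                continue
            s, e, t = p.interval.start, p.interval.end, g.tss
            d = 0 if s <= t < e else min(abs(s - t), abs(e - 1 - t))
            dists[(j, i)] = d
    bound = set()
    for j in range(len(peaks.peaks)):
        row = {i: d for (jj, i), d in dists.items() if jj == j}
        if not row:
            continue
        dmin = min(row.values())
        for i, d in row.items():
            eligible = d <= window_bp
            if require_closest:
                eligible = eligible and d == dmin
            if eligible:
                bound.add(genes[i].gene_id)
    return bound


def random_instance(rng, n_peaks=25, n_genes=12, span=2_000_000):
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, span))
        genes.append(
            make_gene(
                f"g{i}", chrom=f"chr{rng.integers(1, 3)}", start=start,
                end=start + int(rng.integers(500, 5000)),
                strand="+-"[int(rng.integers(0, 2))],
            )
        )
    peaks = []
    for _ in range(n_peaks):
        s = int(rng.integers(0, span))
        peaks.append(
            Peak(GenomicInterval(f"chr{rng.integers(1, 3)}", s,
                                 s + int(rng.integers(100, 1500)), "."))
        )
    return PeakSet(peaks=tuple(peaks), source_label="t"), genes


class TestAssignPeaks:
    def test_distance_convention(self):
        assert peak_tss_distance(149_000, 150_500, 100_000) == 49_000
        assert peak_tss_distance(151_000, 152_000, 100_000) == 51_000
        assert peak_tss_distance(99_000, 101_000, 100_000) == 0

    def test_window_boundary(self):
        g = make_gene("g1", start=100_000, end=105_000, strand="+")
        inside = PeakSet(
            (Peak(GenomicInterval("chr1", 149_000, 150_500, ".")),), "t"
        )
        outside = PeakSet(
            (Peak(GenomicInterval("chr1", 151_000, 152_000, ".")),), "t"
        )
        (b_in,) = assign_peaks(inside, [g], 50_000)
        (b_out,) = assign_peaks(outside, [g], 50_000)
        assert b_in.bound and b_in.nearest_peak_distance_bp == 49_000
        assert not b_out.bound and b_out.nearest_peak_distance_bp == 51_000

    def test_tie_assigns_both_genes(self):
        g1 = make_gene("g1", start=100_000, end=101_000, strand="+")
        g2 = make_gene("g2", start=120_000, end=121_000, strand="+")
        # peak edges equidistant from both TSSs
        peaks = PeakSet(
            (Peak(GenomicInterval("chr1", 105_000, 115_001, ".")),), "t"
        )
        calls = assign_peaks(peaks, [g1, g2], 50_000)
        assert all(c.bound for c in calls)

    @pytest.mark.parametrize("require_closest", [True, False])
    def test_matches_brute_force_oracle(self, require_closest):
        rng = np.random.default_rng(7)
        for _ in range(100):
            peaks, genes = random_instance(rng)
            calls = assign_peaks(peaks, genes, 60_000,
                                 require_closest=require_closest)
            got = {c.gene_id for c in calls if c.bound}
            want = brute_force_bound(peaks, genes, 60_000, require_closest)
            assert got == want

    def test_window_monotonicity(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            peaks, genes = random_instance(rng)
            small = {c.gene_id for c in assign_peaks(peaks, genes, 10_000)
                     if c.bound}
            large = {c.gene_id for c in assign_peaks(peaks, genes, 50_000)
                     if c.bound}
            assert small <= large

    def test_empty_inputs(self):
        g = make_gene("g1")
        empty = PeakSet((), "t")
        (call,) = assign_peaks(empty, [g], 50_000)
        assert not call.bound and call.nearest_peak_distance_bp is None
        with pytest.raises(ValidationError):
            assign_peaks(empty, [], 50_000)


def _two_condition_sheet(control, treated):
    return SampleSheet(
        entries={
            f"{control}_1": (control, 10_000_000),
            f"{control}_2": (control, 10_000_000),
            f"{treated}_1": (treated, 10_000_000),
            f"{treated}_2": (treated, 10_000_000),
        }
    )


class TestCallRegulation:
    def test_dht_induction_threshold(self):
        sheet = _two_condition_sheet("vehicle", "DHT")
        m = matrix_from_rows(
            {"g1": [10, 10, 16, 16], "g2": [10, 10, 12, 12]},
            sheet.sample_ids,
        )
        calls = {c.gene_id: c for c in call_regulation(m, sheet, "DHT_vs_vehicle")}
        assert calls["g1"].call == "induced"
        assert calls["g1"].fold == pytest.approx(1.6, rel=1e-3)
        assert calls["g2"].call == "unchanged"

    def test_siar_inverts_interpretation(self):
        sheet = _two_condition_sheet("siControl", "siAR")
        m = matrix_from_rows(
            {"g1": [10, 10, 7, 7], "g2": [10, 10, 17, 17]},
            sheet.sample_ids,
        )
        calls = {
            c.gene_id: c for c in call_regulation(m, sheet, "siAR_vs_siControl")
        }
        # falls on knockdown => the gene is AR-induced
        assert calls["g1"].call == "induced"
        assert calls["g1"].fold == pytest.approx(0.7, rel=1e-2)
        # rises on knockdown => AR-repressed
        assert calls["g2"].call == "repressed"

    def test_zero_expression_is_unchanged(self):
        sheet = _two_condition_sheet("vehicle", "DHT")
        m = matrix_from_rows({"g1": [0, 0, 0, 0]}, sheet.sample_ids)
        (call,) = call_regulation(m, sheet, "DHT_vs_vehicle")
        assert call.fold == pytest.approx(1.0)
        assert call.call == "unchanged"

    def test_missing_condition_rejected(self):
        sheet = SampleSheet(entries={"a_1": ("vehicle", 10), "a_2": ("vehicle", 10)})
        m = matrix_from_rows({"g1": [1, 1]}, sheet.sample_ids)
        with pytest.raises(ValidationError, match="DHT"):
            call_regulation(m, sheet, "DHT_vs_vehicle")


class TestArTargets:
    def _binding(self, bound_ids, universe):
        peaks = []
        genes = []
        for i, gid in enumerate(universe):
            g = make_gene(gid, start=100_000 * (i + 1), end=100_000 * (i + 1) + 1000)
            genes.append(g)
            if gid in bound_ids:
                peaks.append(Peak(GenomicInterval("chr1", g.tss + 100,
                                                  g.tss + 400, ".")))
        return assign_peaks(PeakSet(tuple(peaks), "t"), genes, 50_000)

    def _regulation(self, regulated_ids, universe, line):
        from crpclnc.regulon import RegulationCall

        return [
            RegulationCall(
                gene_id=g, cell_line=line, contrast="siAR_vs_siControl",
                fold=0.4 if g in regulated_ids else 1.0,
                call="induced" if g in regulated_ids else "unchanged",
            )
            for g in universe
        ]

    def test_bound_and_regulated_required(self):
        universe = ["g1", "g2", "g3", "g4"]
        binding = self._binding({"g1", "g2"}, universe)
        reg = {"22Rv1": self._regulation({"g2", "g3"}, universe, "22Rv1")}
        targets = ar_target_genes(binding, reg)
        assert targets.r22rv1 == {"g2"}

    def test_lncap_vcap_intersection(self):
        universe = ["g1", "g2", "g3"]
        binding = self._binding({"g1", "g2", "g3"}, universe)
        reg = {
            "LNCaP": self._regulation({"g1", "g2"}, universe, "LNCaP"),
            "VCaP": self._regulation({"g2", "g3"}, universe, "VCaP"),
        }
        targets = ar_target_genes(binding, reg)
        assert targets.lncap_vcap == {"g2"}

    def test_universe_mismatch_rejected(self):
        universe = ["g1", "g2"]
        binding = self._binding(set(), universe)
        reg = {"22Rv1": self._regulation(set(), ["g1"], "22Rv1")}
        with pytest.raises(ValidationError):
            ar_target_genes(binding, reg)


class TestFunnel:
    def test_fixture_counts_and_nesting(self):
        genes, regulation, binding = make_funnel_fixture(
            n_total=40, n_regulated=15, n_bound=6, seed=1
        )
        report = crpc_lnc_funnel(genes, regulation, binding)
        assert report.stage_counts == {
            "curated": 40, "regulated": 15, "bound_within_window": 6,
        }
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        assert len(report.rows) == 6

    def test_regulated_but_distant_peak_excluded(self):
        genes, regulation, _ = make_funnel_fixture(
            n_total=5, n_regulated=5, n_bound=0, seed=2
        )
        # one peak at 12 kb: regulated but outside the 10 kb window
        peaks = PeakSet(
            (Peak(GenomicInterval("chr1", genes[0].tss + 12_000,
                                  genes[0].tss + 12_400, ".")),),
            "t",
        )
        binding = assign_peaks(peaks, genes, 10_000)
        report = crpc_lnc_funnel(genes, regulation, binding)
        assert report.stage_counts["bound_within_window"] == 0

    def test_empty_candidates(self):
        report = crpc_lnc_funnel([], [], [])
        assert report.stage_counts == {
            "curated": 0, "regulated": 0, "bound_within_window": 0,
        }
        assert report.rows == []

    def test_rows_carry_location_and_group_means(self):
        genes, regulation, binding = make_funnel_fixture(
            n_total=3, n_regulated=3, n_bound=3, seed=3
        )
        report = crpc_lnc_funnel(genes, regulation, binding)
        row = report.rows[0]
        iv = genes[0].interval
        assert row.location == f"chr1:{iv.start + 1}-{iv.end}"
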