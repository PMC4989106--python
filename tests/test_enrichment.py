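"""Statistical kernels and the overlap-enrichment analyses, checked against
hand-derived values and exact enumeration oracles."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from scipy import stats

from ucekit.enrichment import (
    EnrichmentResult,
    FunctionProfile,
    alt_splicing_test,
    bh_adjust,
    chi_square_2x2,
    combo_fold,
    ese_motif_scan,
    factor_scan,
    function_profiles,
    mann_whitney,
    multifunctionality,
)
from ucekit.model import GenomicInterval, PeakSet
from ucekit.simulate import PeakTrackSpec, place_peaks


class TestChiSquare:
    def test_yates_worked_example(self):
        # hand value: n(|ad-bc|-n/2)^2/(r1 r2 c1 c2) for (30,70,10,90)
        stat, p = chi_square_2x2((30, 70, 10, 90), yates=True)
        assert stat == pytest.approx(11.28125)
        assert 0 < p < 0.001

    def test_identical_proportions_zero_statistic(self):
        stat, p = chi_square_2x2((10, 90, 10, 90))
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_untestable(self):
        stat, p = chi_square_2x2((0, 100, 0, 100))
        assert math.isnan(stat) and math.isnan(p)

    def test_without_yates_matches_closed_form(self):
        a, b, c, d = 30, 70, 10, 90
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _ = chi_square_2x2((a, b, c, d), yates=False)
        assert stat == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2((-1, 2, 3, 4))


class TestBHAdjust:
    def test_stepup_worked_example(self):
        got = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(got, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_unchanged(self):
        assert bh_adjust([1.0]) == [1.0]

    def test_equal_values_fixed_point(self):
        assert np.allclose(bh_adjust([0.03] * 7), [0.03] * 7)

    def test_nan_rows_excluded_from_family(self):
        got = bh_adjust([0.01, np.nan, 0.04, 0.03, np.nan, 0.005])
        assert np.isnan(got[1]) and np.isnan(got[4])
        assert np.allclose(got[[0, 2, 3, 5]], [0.02, 0.04, 0.04, 0.02])

    def test_monotone_and_capped(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestMannWhitney:
    def test_extreme_ranking_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / comb(6, 3))  # = 0.1

    def test_agrees_with_enumeration_small_n(self, rng):
        # exact two-sided p by full enumeration of group assignments
        x, y = [2, 3, 3, 4], [0, 1, 1, 2]
        u_obs, p_obs = mann_whitney(x, y)
        pooled = x + y
        n = len(x)

        def ustat(idx):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
            return sum(
                (a > b) + 0.5 * (a == b) for a in xs for b in ys
            )

        us = [ustat(set(c)) for c in itertools.combinations(range(8), n)]
        mean_u = np.mean(us)
        extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us)
        assert p_obs == pytest.approx(extreme / len(us))


class TestFactorScan:
    CHROM = {"chr1": 300_000}

    def _elements(self, rng, n, length=60):
        starts = np.sort(rng.choice(self.CHROM["chr1"] - length, n, replace=False))
        return [
            GenomicInterval("chr1", int(s), int(s) + length, f"e{i}")
            for i, s in enumerate(starts)
        ]

    def test_biased_factor_enriched_unbiased_ns(self, rng):
        elements = self._elements(rng, 600)
        reference = self._elements(rng, 600)
        biased = place_peaks(
            rng, self.CHROM, elements,
            PeakTrackSpec("A", n_peaks=2000, width_range=(100, 200), uce_bias=10),
        )
        unbiased = place_peaks(
            rng, self.CHROM, elements,
            PeakTrackSpec("B", n_peaks=2000, width_range=(100, 200), uce_bias=1),
        )
        results = factor_scan(
            {"intergenic": elements},
            {"intergenic": reference},
            [PeakSet("A", "e", biased), PeakSet("B", "e", unbiased)],
        )
        res = {(r.factor, r.element_class): r for r in results}
        assert res[("A", "intergenic")].direction == "enriched"
        assert res[("A", "intergenic")].fold > 1
        assert res[("B", "intergenic")].direction == "ns"

    def test_empty_class_untestable(self, rng):
        elements = self._elements(rng, 50)
        peaks = self._elements(rng, 50, length=200)
        results = factor_scan(
            {"intergenic": elements}, {"intergenic": elements}, [PeakSet("A", "e", peaks)]
        )
        by_class = {r.element_class: r for r in results}
        assert by_class["exonic"].direction == "untestable"
        assert math.isnan(by_class["exonic"].p_adj)

    def test_family_size_spans_factors_and_classes(self, rng):
        elements = {c: self._elements(rng, 30) for c in ("intergenic", "intronic", "exonic")}
        peak_sets = [
            PeakSet(f, "e", self._elements(rng, 40, length=150)) for f in "ABCDE"
        ]
        results = factor_scan(elements, elements, peak_sets)
        assert len(results) == 5 * 3  # one test per factor x class

    def test_fold_direction_consistency(self, rng):
        elements = {c: self._elements(rng, 100) for c in ("intergenic",)}
        peak_sets = [PeakSet("A", "e", self._elements(rng, 500, length=400))]
        for r in factor_scan(elements, elements, peak_sets):
            if r.direction == "enriched":
                assert r.fold > 1
            elif r.direction == "depleted":
                assert r.fold < 1
            assert math.isnan(r.p_adj) or r.p_adj >= r.p


def _profile(flags):
    return FunctionProfile(GenomicInterval("chr1", 0, 50), *flags)


class TestMultifunctionality:
    def test_flags_from_tracks(self):
        el = [GenomicInterval("chr1", 100, 160)]
        coding = [GenomicInterval("chr1", 150, 300)]
        splice = [GenomicInterval("chr1", 159, 160)]
        editing = [GenomicInterval("chr1", 500, 501)]
        peaks = [PeakSet("A", "e", [GenomicInterval("chr1", 0, 120)])]
        prof = function_profiles(el, coding, splice, editing, peaks)[0]
        assert (prof.coding, prof.splice_site, prof.editing, prof.tf_bound) == (
            True, True, False, True,
        )
        assert prof.score == 3

    def test_shift_detected(self):
        high = [_profile(f) for f in [
            (1, 1, 0, 0), (1, 1, 1, 0), (1, 1, 1, 0), (1, 1, 1, 1),
            (1, 1, 1, 0), (1, 1, 1, 1),
        ]]
        low = [_profile(f) for f in [
            (0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (1, 1, 0, 0),
            (0, 1, 0, 0), (0, 0, 0, 0),
        ]]
        res = multifunctionality(high, low)
        assert res["element_scores"] == [0, 0, 1, 3, 2]
        assert res["mann_whitney_p"] < 0.05


class TestComboFold:
    def test_identical_profiles_all_folds_one(self):
        profs = [_profile(f) for f in itertools.product((0, 1), repeat=4)]
        df = combo_fold(profs, list(profs))
        assert np.allclose(df["fold"], 1.0)
        assert df["prop_elements"].sum() == pytest.approx(1.0)
        assert df["prop_reference"].sum() == pytest.approx(1.0)

    def test_constructed_tetrafunctional_fold_100(self):
        tetra = (True, True, True, True)
        none = (False, False, False, False)
        elements = [_profile(tetra)] * 100 + [_profile(none)] * 900
        reference = [_profile(tetra)] * 1 + [_profile(none)] * 999
        df = combo_fold(elements, reference)
        row = df[(df.coding) & (df.splice_site) & (df.editing) & (df.tf_bound)]
        assert row["fold"].iloc[0] == pytest.approx(100.0)

    def test_all_zero_flags_single_combination(self):
        profs = [_profile((0, 0, 0, 0))] * 5
        df = combo_fold(profs, profs)
        nonzero = df[df.n_elements > 0]
        assert len(nonzero) == 1 and nonzero["fold"].iloc[0] == 1.0

    def test_zero_reference_proportion_infinite_fold(self):
        elements = [_profile((1, 0, 0, 0))] * 2
        reference = [_profile((0, 0, 0, 0))] * 2
        df = combo_fold(elements, reference)
        row = df[(df.coding) & ~(df.splice_site) & ~(df.editing) & ~(df.tf_bound)]
        assert math.isinf(row["fold"].iloc[0])


class TestAltSplicing:
    def test_all_elements_alt_spliced_vs_half_reference(self, rng):
        alt_exons = [
            GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(100)
        ]
        elements = [
            GenomicInterval("chr1", i * 1000 + 50, i * 1000 + 120) for i in range(100)
        ]
        # half the reference overlaps alternative exons
        reference = elements[:50] + [
            GenomicInterval("chr1", 200_000 + i * 500, 200_000 + i * 500 + 70)
            for i in range(50)
        ]
        res = alt_splicing_test(elements, alt_exons, reference)
        assert res.fold == pytest.approx(2.0)
        assert res.p < 0.05 and res.direction == "enriched"

    def test_element_overlapping_both_kinds_counts_alt(self):
        alt = [GenomicInterval("chr1", 100, 200)]
        elements = [GenomicInterval("chr1", 150, 260)]  # also overlaps [200,300) const
        reference = [GenomicInterval("chr1", 150, 260), GenomicInterval("chr1", 500, 560)]
        res = alt_splicing_test(elements, alt, reference)
        assert res.a == 1 and res.b == 0

    def test_empty_exon_table_untestable(self):
        elements = [GenomicInterval("chr1", 0, 50)]
        res = alt_splicing_test(elements, [], elements)
        assert res.direction == "untestable"


class TestEseScan:
    def test_planted_motif_enriched(self, rng):
        motif = "GAAGAA"
        bg = ["".join(rng.choice(list("CT"), size=80)) for _ in range(200)]
        elements = [s[:40] + motif + s[40:] for s in bg]
        reference = ["".join(rng.choice(list("CT"), size=86)) for _ in range(200)]
        decoy_motifs = ["ACGTAC", motif]
        results = ese_motif_scan(elements, reference, decoy_motifs)
        by_motif = {r.factor: r for r in results}
        assert by_motif[motif].direction == "enriched"
        assert by_motif[motif].p_adj < 0.05
        assert by_motif["ACGTAC"].direction == "untestable"

    def test_element_equal_to_motif_matches(self):
        results = ese_motif_scan(["GAAGAA"], ["CCCCCC", "GAAGAA"], ["GAAGAA"])
        assert results[0].a == 1 and results[0].c == 1

    def test_empty_motif_list(self):
        assert ese_motif_scan(["ACGT"], ["ACGT"], []) == []

    def test_non_acgt_motif_rejected(self):
        with pytest.raises(ValueError):
            ese_motif_scan(["ACGT"], ["ACGT"], ["GANGAA"])


class TestNullCalibration:
    def test_family_wise_false_positive_rate(self):
        # unbiased tracks: fraction of significant (factor x class) tests at
        # p_adj < 0.05 stays within binomial error of <= 0.05 over 100
        # simulated families
        chrom = {"chr1": 200_000}
        n_sig = n_tests = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            starts = np.sort(r.choice(chrom["chr1"] - 60, 400, replace=False))
            els = [GenomicInterval("chr1", int(s), int(s) + 60) for s in starts[:200]]
            refs = [GenomicInterval("chr1", int(s), int(s) + 60) for s in starts[200:]]
            peak_sets = [
                PeakSet(
                    f, "e",
                    place_peaks(r, chrom, [], PeakTrackSpec(f, n_peaks=800,
                                                            width_range=(100, 200))),
                )
                for f in "ABC"
            ]
            results = factor_scan({"intergenic": els}, {"intergenic": refs}, peak_sets)
            for res in results:
                if not math.isnan(res.p_adj):
                    n_tests += 1
                    n_sig += res.p_adj < 0.05
        rate = n_sig / n_tests
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)
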