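"""TSS-window signal, region classification, differential peaks, QN, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_annotation, make_peaks
from oracles import classify_oracle, hypergeom_enum_p, overlap_fraction_oracle

from dccircuit.chip import (
    classify_regions,
    detect_bivalent,
    differential_peaks,
    fisher_target_enrichment,
    overlap_fraction,
    pca,
    quantile_normalize,
    tss_window_signal,
)
from dccircuit.intervals import GenomicInterval, PeakSet


class TestTssWindowSignal:
    annot = make_annotation([("g1", "chr1", "+", 10_000)])

    def test_no_peak_in_window_is_zero(self):
        peaks = make_peaks([("chr1", 50_000, 51_000)])
        assert tss_window_signal(peaks, self.annot, 1_000)["g1"] == 0.0

    def test_full_unit_coverage_is_one(self):
        peaks = make_peaks([("chr1", 9_000, 11_000, 1.0)])
        assert tss_window_signal(peaks, self.annot, 1_000)["g1"] == pytest.approx(1.0)

    def test_partial_coverage_matches_per_base_sum(self):
        peaks = make_peaks([("chr1", 9_000, 9_500, 2.0)])
        sig = tss_window_signal(peaks, self.annot, 1_000)["g1"]
        assert sig == pytest.approx(2.0 * 500 / 2_000)
        # per-base brute force
        cov = np.zeros(2_000)
        for s, e, sc in [(9_000, 9_500, 2.0)]:
            lo, hi = max(s, 9_000), min(e, 11_000)
            cov[lo - 9_000 : hi - 9_000] += sc
        assert sig == pytest.approx(cov.sum() / 2_000)

    def test_random_fixture_matches_per_base_oracle(self, rng):
        genes = [(f"g{i}", "chr1", "+", int(t)) for i, t in
                 enumerate(rng.integers(5_000, 95_000, size=10))]
        annot = make_annotation(genes)
        peaks = make_peaks(
            [
                ("chr1", int(s), int(s) + int(w), float(sc))
                for s, w, sc in zip(
                    rng.integers(0, 99_000, 40),
                    rng.integers(100, 3_000, 40),
                    rng.uniform(0.5, 5, 40),
                )
            ]
        )
        sig = tss_window_signal(peaks, annot, 1_000)
        for gid, _, _, tss in genes:
            ws, we = tss - 1_000, tss + 1_000
            total = 0.0
            for iv in peaks:
                ov = min(iv.end, we) - max(iv.start, ws)
                if ov > 0:
                    total += iv.score * ov
            assert sig[gid] == pytest.approx(total / 2_000)

    def test_additive_in_disjoint_peak_sets(self):
        a = make_peaks([("chr1", 9_000, 9_400, 2.0)])
        b = make_peaks([("chr1", 10_100, 10_700, 3.0)])
        both = make_peaks(
            [("chr1", 9_000, 9_400, 2.0), ("chr1", 10_100, 10_700, 3.0)]
        )
        s = tss_window_signal
        assert s(both, self.annot, 1_000)["g1"] == pytest.approx(
            s(a, self.annot, 1_000)["g1"] + s(b, self.annot, 1_000)["g1"]
        )

    def test_unknown_chromosome_raises_with_sizes(self):
        peaks = make_peaks([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            tss_window_signal(peaks, self.annot, 1_000, chrom_sizes={"chr9": 10})


class TestClassifyRegions:
    def test_rule_text_cases(self):
        me1 = make_peaks([("chr1", 100, 500)])
        me3 = make_peaks([("chr1", 1_000, 1_200)])
        pu1 = make_peaks(
            [("chr1", 200, 300), ("chr1", 1_050, 1_150), ("chr1", 5_000, 5_100)]
        )
        labels = classify_regions(me1, me3, pu1)["label"].tolist()
        assert labels == ["enhancer", "neither", "neither"]
        # promoter needs both marks
        me1b = make_peaks([("chr1", 100, 500), ("chr1", 1_000, 1_100)])
        labels = classify_regions(me1b, me3, pu1)["label"].tolist()
        assert labels == ["enhancer", "active_promoter", "neither"]

    def test_random_fixture_matches_quadratic_oracle(self, rng):
        def rand_peaks(n):
            starts = rng.integers(0, 50_000, n)
            return make_peaks(
                [("chr%d" % rng.integers(1, 3), int(s), int(s) + int(w))
                 for s, w in zip(starts, rng.integers(50, 800, n))]
            )

        me1, me3, pu1 = rand_peaks(80), rand_peaks(80), rand_peaks(200)
        got = classify_regions(me1, me3, pu1)["label"].tolist()
        assert got == classify_oracle(me1, me3, list(pu1))

    def test_invariant_under_input_order_permutation(self, rng):
        ivs = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 10_000, 50)]
        me1 = make_peaks(ivs[:20])
        me3 = make_peaks(ivs[20:30])
        pu1_sorted = make_peaks(sorted(ivs[30:]))
        pu1_shuffled = make_peaks(list(reversed(ivs[30:])))
        a = classify_regions(me1, me3, pu1_sorted)
        b = classify_regions(me1, me3, pu1_shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestBivalent:
    annot = make_annotation([("g1", "chr1", "+", 5_000), ("g2", "chr1", "-", 50_000)])

    def test_single_mark_is_not_bivalent(self):
        me3 = make_peaks([("chr1", 4_500, 5_500)])
        k27 = make_peaks([("chr1", 49_000, 51_000)])
        assert detect_bivalent(me3, k27, self.annot) == []

    def test_both_marks_at_tss_is_bivalent(self):
        me3 = make_peaks([("chr1", 4_500, 5_500)])
        k27 = make_peaks([("chr1", 5_900, 6_100)])
        assert detect_bivalent(me3, k27, self.annot) == ["g1"]


class TestDifferentialPeaks:
    def test_identical_sets_all_shared(self):
        ivs = [("chr1", 100, 300, 5.0), ("chr1", 1_000, 1_200, 7.0)]
        calls = differential_peaks(make_peaks(ivs), make_peaks(ivs))
        assert [c.direction for c in calls] == ["shared", "shared"]

    def test_present_only_in_a_is_a_specific(self):
        a = make_peaks([("chr1", 100, 300, 5.0), ("chr1", 1_000, 1_200, 5.0)])
        b = make_peaks([("chr1", 1_000, 1_200, 5.0)])
        calls = differential_peaks(a, b)
        by_start = {c.interval.start: c.direction for c in calls}
        assert by_start[100] == "a-specific"

    def test_empty_inputs_give_empty_result(self):
        assert differential_peaks(make_peaks([]), make_peaks([])) == []

    def test_planted_three_fold_differences_all_called(self, rng):
        # 25 three-fold peaks per side among 150 equal shared peaks; the
        # symmetric design keeps library totals equal so normalization does
        # not erode the planted fold changes
        starts = np.arange(200) * 2_000
        base = rng.uniform(5, 10, 200)
        idx = np.arange(200)
        a_scores = np.where(idx < 25, 3 * base, base)
        b_scores = np.where((idx >= 25) & (idx < 50), 3 * base, base)
        a = make_peaks(
            [("chr1", int(s), int(s) + 400, float(v)) for s, v in zip(starts, a_scores)]
        )
        b = make_peaks(
            [("chr1", int(s), int(s) + 400, float(v)) for s, v in zip(starts, b_scores)]
        )
        calls = differential_peaks(a, b, fc_threshold=2.0)
        assert len(calls) == 200
        assert all(c.direction == "a-specific" for c in calls[:25])
        assert all(c.direction == "b-specific" for c in calls[25:50])
        assert all(c.direction == "shared" for c in calls[50:])
        # brute-force recomputation of the normalized ratio rule
        tot_a, tot_b = a_scores.sum(), b_scores.sum()
        target = (tot_a + tot_b) / 2
        for c, va, vb in zip(calls, a_scores, b_scores):
            ratio = (va * target / tot_a + 0.5) / (vb * target / tot_b + 0.5)
            assert c.fold_change == pytest.approx(ratio)

    def test_antisymmetric_direction_labels(self, rng):
        ivs_a = [("chr1", int(s), int(s) + 300, float(v)) for s, v in
                 zip(rng.integers(0, 50_000, 20) * 10, rng.uniform(1, 20, 20))]
        ivs_b = [("chr1", int(s), int(s) + 300, float(v)) for s, v in
                 zip(rng.integers(0, 50_000, 20) * 10, rng.uniform(1, 20, 20))]
        fwd = differential_peaks(make_peaks(ivs_a), make_peaks(ivs_b))
        rev = differential_peaks(make_peaks(ivs_b), make_peaks(ivs_a))
        flip = {"a-specific": "b-specific", "b-specific": "a-specific", "shared": "shared"}
        assert [flip[c.direction] for c in fwd] == [c.direction for c in rev]


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self, rng):
        col = rng.uniform(size=10)
        df = pd.DataFrame({"a": col, "b": col})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_permuted_columns_become_identical_multisets(self, rng):
        a = rng.uniform(size=30)
        df = pd.DataFrame({"a": a, "b": rng.permutation(a), "c": rng.normal(size=30)})
        out = quantile_normalize(df)
        for col in out.columns:
            np.testing.assert_allclose(np.sort(out[col]), np.sort(out["a"]))

    def test_tie_handling_matches_stepwise_construction(self):
        df = pd.DataFrame(
            {"a": [5.0, 2.0, 3.0, 4.0, 1.0],
             "b": [2.0, 2.0, 3.0, 4.0, 5.0],
             "c": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        out = quantile_normalize(df)
        # independent step-by-step oracle
        ref = np.mean(np.sort(df.to_numpy(), axis=0), axis=1)
        for col in df.columns:
            ranks = stats.rankdata(df[col], method="average")
            expected = [
                ref[int(r) - 1] if float(r).is_integer()
                else (ref[int(np.floor(r)) - 1] + ref[int(np.ceil(r)) - 1]) / 2
                for r in ranks
            ]
            np.testing.assert_allclose(out[col], expected)

    def test_equal_column_means_and_rank_preservation(self, rng):
        df = pd.DataFrame(rng.uniform(size=(50, 4)), columns=list("abcd"))
        out = quantile_normalize(df)
        means = out.mean()
        np.testing.assert_allclose(means, means.iloc[0])
        for col in df.columns:
            np.testing.assert_array_equal(
                np.argsort(df[col].to_numpy()), np.argsort(out[col].to_numpy())
            )

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


class TestPCA:
    def test_rank_one_data_has_unit_first_component(self):
        t = np.arange(6, dtype=float)
        X = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0]))
        _, evr = pca(X, n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_duplicated_samples_get_identical_coordinates(self, rng):
        X = rng.normal(size=(5, 8))
        X = np.vstack([X, X[2]])
        coords, _ = pca(pd.DataFrame(X), n_components=3)
        np.testing.assert_allclose(coords.iloc[2], coords.iloc[-1], atol=1e-9)

    def test_constant_matrix_is_all_zero(self):
        coords, evr = pca(pd.DataFrame(np.full((4, 5), 3.0)), n_components=2)
        assert np.all(coords.to_numpy() == 0)
        assert np.all(evr == 0)

    def test_variances_match_covariance_eigenvalues(self, rng):
        X = rng.normal(size=(6, 40))
        coords, evr = pca(pd.DataFrame(X), n_components=5)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / 5))[::-1]
        total = (Xc**2).sum() / 5
        np.testing.assert_allclose(evr, eig[:5] / total, atol=1e-10)
        # coordinates have variance equal to the eigenvalues
        np.testing.assert_allclose(
            (coords.to_numpy() ** 2).sum(axis=0) / 5, eig[:5], atol=1e-8
        )


class TestOverlapFraction:
    def test_contained_intervals_give_one(self):
        a = make_peaks([("chr1", 10, 20), ("chr1", 100, 110)])
        b = make_peaks([("chr1", 0, 200)])
        assert overlap_fraction(a, b) == 1.0

    def test_disjoint_chromosomes_give_zero(self):
        a = make_peaks([("chr1", 10, 20)])
        b = make_peaks([("chr2", 10, 20)])
        assert overlap_fraction(a, b) == 0.0

    def test_empty_query_is_nan(self):
        assert np.isnan(overlap_fraction(make_peaks([]), make_peaks([("chr1", 0, 5)])))

    def test_matches_quadratic_oracle(self, rng):
        def rand(n):
            return make_peaks(
                [("chr1", int(s), int(s) + int(w)) for s, w in
                 zip(rng.integers(0, 30_000, n), rng.integers(10, 500, n))]
            )

        a, b = rand(100), rand(100)
        assert overlap_fraction(a, b) == pytest.approx(
            overlap_fraction_oracle(list(a), list(b))
        )


class TestFisherTargetEnrichment:
    universe = {f"g{i}" for i in range(10)}

    def test_zero_overlap_gives_p_one(self):
        orr, p = fisher_target_enrichment({"g0", "g1"}, {"g5", "g6"}, self.universe)
        assert p == pytest.approx(1.0)

    def test_perfect_split_matches_enumeration(self):
        targets = {f"g{i}" for i in range(5)}
        orr, p = fisher_target_enrichment(targets, targets, self.universe)
        assert p == pytest.approx(1 / 252)

    def test_random_tables_match_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 31))
            universe = {f"g{i}" for i in range(n)}
            genes = sorted(universe)
            targets = set(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
            de = set(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
            _, p = fisher_target_enrichment(targets, de, universe)
            a = len(de & targets)
            b = len(de - targets)
            c = len(targets - de)
            d = n - a - b - c
            assert p == pytest.approx(hypergeom_enum_p(a, b, c, d), rel=1e-9)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            fisher_target_enrichment(set(), set(), set())
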