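import math

import numpy as np
import pytest

from convergescan import (css, da_outlier_windows, make_windows,
                          outlier_overlap_test, patterson_d,
                          window_divergence, window_diversity)
from convergescan.variants import GenotypeMatrix
from convergescan.windows import Window, allele_sharing_distance

from conftest import (dxy_site_oracle, make_af, make_panel,
                      make_variant_table, pi_site_oracle)


class TestMakeWindows:
    def test_simple_tiling(self):
        wins = make_windows({"c": 50_000}, 20_000, 10_000)
        assert [w.start for w in wins] == [0, 10_000, 20_000, 30_000, 40_000]
        assert wins[-1].end == 50_000

    def test_short_contig_single_truncated_window(self):
        wins = make_windows({"c": 5_000}, 20_000, 10_000)
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (0, 5_000)

    def test_count_matches_closed_form(self):
        """One window per step start below the contig end: ceil(L/step)."""
        lengths = {"a": 73_000, "b": 20_000, "c": 131_000}
        wins = make_windows(lengths, 20_000, 10_000)
        expected = sum(math.ceil(length / 10_000) for length in lengths.values())
        assert len(wins) == expected

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100}, 0, 10)
        with pytest.raises(ValueError):
            make_windows({"c": 100}, 10, 20)


class TestDiversity:
    def test_monomorphic_window_pi_zero(self):
        panel = make_panel(2)
        vt = make_variant_table(5)
        calls = np.zeros((5, 10), dtype=np.int8)
        pi = window_diversity(GenotypeMatrix(calls), vt, panel,
                              [Window("chr1", 0, 10_000)])
        assert all(pi[f"pi_{sp}"].iloc[0] == 0.0 for sp in panel.species())

    def test_single_snp_closed_form(self):
        """One SNP with allele counts (2,2) in 4 copies: pi = (4/6)/10000."""
        panel = make_panel(2)
        vt = make_variant_table(1)
        calls = np.zeros((1, 10), dtype=np.int8)
        idx = panel.sample_indices("slenderA")
        calls[0, idx[0]] = 2  # alleles (1,1,0,0): 4 of 6 pairs differ
        pi = window_diversity(GenotypeMatrix(calls), vt, panel,
                              [Window("chr1", 0, 10_000)])
        assert pi["pi_slenderA"].iloc[0] == pytest.approx((4 / 6) / 10_000)

    def test_matches_haplotype_pair_oracle(self):
        rng = np.random.default_rng(4)
        panel = make_panel(3)
        vt = make_variant_table(50)
        calls = rng.integers(0, 3, size=(50, 15)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = -1
        win = Window("chr1", 0, 5_100)
        pi = window_diversity(GenotypeMatrix(calls), vt, panel, [win])
        for sp in panel.species():
            cols = panel.sample_indices(sp)
            expected = sum(
                pi_site_oracle(calls[i, cols]) for i in range(50)
            ) / win.size
            assert pi[f"pi_{sp}"].iloc[0] == pytest.approx(expected)

    def test_indels_excluded_by_default(self):
        panel = make_panel(2)
        vt = make_variant_table(2)
        vt.df.loc[1, "vtype"] = "indel"
        calls = np.tile(np.array([[1] * 10], dtype=np.int8), (2, 1))
        win = [Window("chr1", 0, 1_000)]
        pi_ex = window_diversity(GenotypeMatrix(calls), vt, panel, win)
        pi_in = window_diversity(GenotypeMatrix(calls), vt, panel, win,
                                 exclude_indels=False)
        assert pi_in["pi_slenderA"].iloc[0] == 2 * pi_ex["pi_slenderA"].iloc[0]


class TestDivergence:
    def test_identical_populations_da_zero(self):
        """When A and B have identical genotype columns, Da -> 0 up to the
        within/between estimator bias at finite n (exactly 0 for fixed sites)."""
        panel = make_panel(2)
        vt = make_variant_table(3)
        calls = np.zeros((3, 10), dtype=np.int8)
        for sp in ("slenderA", "stoutA"):
            calls[0, panel.sample_indices(sp)] = 2  # fixed alt in both
        gt = GenotypeMatrix(calls)
        from convergescan import allele_frequencies

        af = allele_frequencies(gt, panel)
        win = [Window("chr1", 0, 10_000)]
        pi = window_diversity(gt, vt, panel, win)
        div = window_divergence(af, vt, win, ("slenderA", "stoutA"), pi)
        assert div["dxy"].iloc[0] == 0.0
        assert div["da"].iloc[0] == 0.0

    def test_single_fixed_difference(self):
        panel = make_panel(2)
        vt = make_variant_table(1)
        calls = np.zeros((1, 10), dtype=np.int8)
        calls[0, panel.sample_indices("slenderA")] = 2
        gt = GenotypeMatrix(calls)
        from convergescan import allele_frequencies

        af = allele_frequencies(gt, panel)
        win = [Window("chr1", 0, 20_000)]
        pi = window_diversity(gt, vt, panel, win)
        div = window_divergence(af, vt, win, ("slenderA", "stoutA"), pi)
        assert div["dxy"].iloc[0] == pytest.approx(5e-5)

    def test_matches_between_pair_oracle_and_da_identity(self):
        rng = np.random.default_rng(9)
        panel = make_panel(3)
        vt = make_variant_table(60)
        calls = rng.integers(0, 3, size=(60, 15)).astype(np.int8)
        gt = GenotypeMatrix(calls)
        from convergescan import allele_frequencies

        af = allele_frequencies(gt, panel)
        win = Window("chr1", 0, 6_100)
        pi = window_diversity(gt, vt, panel, [win])
        div = window_divergence(af, vt, [win], ("slenderB", "stoutC"), pi)
        ca = panel.sample_indices("slenderB")
        cb = panel.sample_indices("stoutC")
        expected = sum(
            dxy_site_oracle(calls[i, ca], calls[i, cb]) for i in range(60)
        ) / win.size
        assert div["dxy"].iloc[0] == pytest.approx(expected)
        da = div["da"].iloc[0]
        assert da == pytest.approx(
            div["dxy"].iloc[0]
            - (pi["pi_slenderB"].iloc[0] + pi["pi_stoutC"].iloc[0]) / 2
        )

    def test_identical_pair_errors(self):
        af = make_af([[0.5] * 5])
        with pytest.raises(ValueError):
            window_divergence(af, make_variant_table(1),
                              [Window("chr1", 0, 100)], ("stoutA", "stoutA"),
                              None)


class TestDaOutliers:
    def test_hundred_distinct_values_give_five(self):
        rng = np.random.default_rng(0)
        da = rng.permutation(100).astype(float)
        out = da_outlier_windows(da)
        assert len(out) == 5
        assert set(da[out]) == {95, 96, 97, 98, 99}

    def test_all_equal_da_yields_empty(self):
        assert len(da_outlier_windows(np.ones(50))) == 0

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(1)
        da = rng.normal(size=400)
        out = da_outlier_windows(da, 0.95)
        cut = np.quantile(da, 0.95)
        assert set(out) == {i for i, v in enumerate(da) if v > cut}


class TestOverlap:
    def test_identical_full_sets(self):
        u = np.arange(20)
        obs, exp, p = outlier_overlap_test(u, u, 20, n_perm=50,
                                           rng=np.random.default_rng(0))
        assert obs == exp == 20
        assert p == 1.0

    def test_disjoint_halves(self):
        a = np.arange(50)
        b = np.arange(50, 100)
        obs, exp, p = outlier_overlap_test(a, b, 100, n_perm=99,
                                           rng=np.random.default_rng(0))
        assert obs == 0
        assert exp == 25.0
        assert p == 1.0

    def test_random_sets_match_hypergeometric_mean(self):
        rng = np.random.default_rng(2)
        n_total = 4_000
        a = rng.choice(n_total, 400, replace=False)
        b = rng.choice(n_total, 410, replace=False)
        obs, exp, p = outlier_overlap_test(a, b, n_total, n_perm=200, rng=rng)
        assert exp == pytest.approx(400 * 410 / n_total)
        # hypergeometric sd ~ 6; observed overlap within 4 sd of the mean
        assert abs(obs - exp) < 25
        assert p > 0.001

    def test_universe_too_small(self):
        with pytest.raises(ValueError):
            outlier_overlap_test(np.arange(10), np.arange(3), 5)


class TestCSS:
    def test_identical_individuals_css_zero_p_one(self):
        panel = make_panel(2)
        vt = make_variant_table(10, spacing=10)
        calls = np.ones((10, 10), dtype=np.int8)
        rec = css(GenotypeMatrix(calls), vt, Window("chr1", 0, 200), panel,
                  n_perm=49, rng=np.random.default_rng(0))
        assert rec.css == pytest.approx(0.0, abs=1e-12)
        assert rec.p_perm == 1.0

    def test_two_point_clusters_recover_between_distance(self):
        """Slender all hom-ref, stout all hom-alt: allele-sharing distance 1
        between morphs, 0 within; the embedded separation is the CSS."""
        panel = make_panel(3)
        vt = make_variant_table(20, spacing=10)
        calls = np.zeros((20, 15), dtype=np.int8)
        for i in panel.morph_members("stout"):
            calls[:, i] = 2
        rec = css(GenotypeMatrix(calls), vt, Window("chr1", 0, 300), panel,
                  n_perm=199, rng=np.random.default_rng(1))
        assert rec.css == pytest.approx(1.0, abs=1e-6)
        assert rec.p_perm <= 0.02  # near the permutation floor

    def test_empty_window_flagged_undefined(self):
        panel = make_panel(2)
        vt = make_variant_table(5, spacing=1000)
        calls = np.zeros((5, 10), dtype=np.int8)
        rec = css(GenotypeMatrix(calls), vt, Window("chr2", 0, 100), panel)
        assert not rec.defined
        assert np.isnan(rec.css)

    def test_invariant_to_relabeling_within_morph(self):
        rng = np.random.default_rng(3)
        panel = make_panel(3)
        vt = make_variant_table(30, spacing=10)
        calls = rng.integers(0, 3, size=(30, 15)).astype(np.int8)
        w = Window("chr1", 0, 400)
        r1 = css(GenotypeMatrix(calls), vt, w, panel, n_perm=0)
        # swap the two slenderA individuals' columns (same morph)
        perm = calls.copy()
        a, b = panel.sample_indices("slenderA")[:2]
        perm[:, [a, b]] = perm[:, [b, a]]
        r2 = css(GenotypeMatrix(perm), vt, w, panel, n_perm=0)
        assert r1.css == pytest.approx(r2.css, abs=1e-9)

    def test_distance_matrix_matches_pair_loop(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(40, 8)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = -1
        d = allele_sharing_distance(calls)
        for i in range(8):
            for j in range(i + 1, 8):
                both = (calls[:, i] >= 0) & (calls[:, j] >= 0)
                exp = np.abs(
                    calls[both, i].astype(float) - calls[both, j]
                ).mean() / 2
                assert d[i, j] == pytest.approx(exp)


class TestPattersonD:
    def test_p1_equals_p2_gives_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random((100, 4))
        p[:, 1] = p[:, 0]
        af = make_af(p, ["p1", "p2", "p3", "out"])
        rec = patterson_d(af, ("p1", "p2", "p3", "out"))
        assert rec.d == pytest.approx(0.0, abs=1e-12)

    def test_single_pure_abba_site(self):
        af = make_af([[0.0, 1.0, 1.0, 0.0]], ["p1", "p2", "p3", "out"])
        rec = patterson_d(af, ("p1", "p2", "p3", "out"))
        assert rec.d == 1.0
        assert rec.abba == 1.0 and rec.baba == 0.0

    def test_matches_site_pattern_counting_on_fixed_sites(self):
        """With frequencies in {0,1} the statistic reduces to counting ABBA
        and BABA site patterns directly."""
        rng = np.random.default_rng(5)
        p = rng.integers(0, 2, size=(500, 4)).astype(float)
        af = make_af(p, ["p1", "p2", "p3", "out"])
        rec = patterson_d(af, ("p1", "p2", "p3", "out"))
        abba = baba = 0
        for row in p:
            if row[3] == 0 and row[2] == 1:
                if row[0] == 0 and row[1] == 1:
                    abba += 1
                elif row[0] == 1 and row[1] == 0:
                    baba += 1
        assert rec.abba == abba and rec.baba == baba
        assert rec.d == pytest.approx((abba - baba) / (abba + baba))

    def test_antisymmetric_under_p1_p2_swap(self):
        rng = np.random.default_rng(6)
        p = rng.random((200, 4))
        af = make_af(p, ["p1", "p2", "p3", "out"])
        d12 = patterson_d(af, ("p1", "p2", "p3", "out")).d
        d21 = patterson_d(af, ("p2", "p1", "p3", "out")).d
        assert d12 == pytest.approx(-d21)

    def test_dmin_not_larger_than_reported_arrangement(self):
        rng = np.random.default_rng(7)
        af = make_af(rng.random((100, 4)), ["p1", "p2", "p3", "out"])
        rec = patterson_d(af, ("p1", "p2", "p3", "out"))
        assert rec.dmin <= abs(rec.d) + 1e-12

    def test_duplicate_taxa_rejected(self):
        af = make_af([[0.5] * 5])
        with pytest.raises(ValueError):
            patterson_d(af, ("slenderA", "slenderA", "stoutA", "stoutB"))
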