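"""Assumption gatekeeping, multi-group tests with compact letters,
correlation, dispersion and ordination."""

import itertools

import numpy as np
import pandas as pd
import pytest

from endoflow.errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)
from endoflow.groupstats import (
    compact_letter_display,
    compare_groups,
    cv_across_species,
    dunn_test,
    gatekeep,
    pca_centered,
    spearman_matrix,
    standardize,
)


class TestGatekeep:
    def test_clean_gaussian_groups_go_parametric(self, rng):
        groups = [rng.normal(10 + i, 2.0, 20) for i in range(4)]
        assert gatekeep(groups) == "anova_tukey"

    def test_heavy_tailed_group_goes_nonparametric(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            groups = [r.normal(10, 1, 20) for _ in range(3)]
            groups.append(r.lognormal(2.0, 1.0, 20))
            hits += gatekeep(groups) == "kruskal_dunn_bh"
        assert hits >= 90

    def test_constant_group_is_degenerate_normality_fail(self, rng):
        groups = [rng.normal(0, 1, 10), np.full(10, 3.0)]
        assert gatekeep(groups) == "kruskal_dunn_bh"

    def test_unequal_variances_fail_levene(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            groups = [r.normal(0, 1, 30), r.normal(0, 6, 30)]
            hits += gatekeep(groups) == "kruskal_dunn_bh"
        assert hits >= 45

    def test_small_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            gatekeep([rng.normal(0, 1, 10), rng.normal(0, 1, 2)])


class TestCompareGroups:
    def test_null_two_groups_rarely_significant(self):
        """Two groups from one distribution: adjusted p > 0.05 in >= 90 of
        100 seeded draws (n = 50 each)."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            v = np.concatenate([r.normal(0, 1, 50), r.normal(0, 1, 50)])
            lab = np.array(["a"] * 50 + ["b"] * 50)
            res = compare_groups(v, lab, method="kruskal_dunn_bh")
            hits += min(res.pairwise.values()) > 0.05
        assert hits >= 90

    def test_separated_groups_all_letters_distinct(self, rng):
        v = np.concatenate([rng.normal(10 * i, 2.0, 20) for i in range(4)])
        lab = np.repeat(list("abcd"), 20)
        for method in ("anova_tukey", "kruskal_dunn_bh"):
            res = compare_groups(v, lab, method=method)
            assert res.pvalue < 0.05
            assert all(p < 0.05 for p in res.pairwise.values())
            letters = list(res.letters.values())
            assert len(set(letters)) == 4
            assert all(len(x) == 1 for x in letters)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_groups(np.ones(20), np.repeat(["a", "b"], 10))

    def test_dunn_bh_null_calibration(self):
        """Family-wise false-positive proportion <= 10 % over 1000 null
        seeds (4 identical groups, n = 20, BH-adjusted Dunn at 0.05)."""
        false_pos = 0
        for seed in range(1000):
            r = np.random.default_rng(seed)
            v = r.normal(0, 1, 80)
            lab = np.repeat(list("abcd"), 20)
            res = compare_groups(v, lab, method="kruskal_dunn_bh")
            false_pos += min(res.pairwise.values()) < 0.05
        assert false_pos / 1000 <= 0.10

    def test_letter_display_soundness(self, rng):
        """Groups share a letter exactly when their adjusted p >= alpha."""
        for _ in range(20):
            shifts = rng.choice([0.0, 0.0, 3.0, 8.0], size=4)
            v = np.concatenate([rng.normal(s, 1.0, 15) for s in shifts])
            lab = np.repeat(list("wxyz"), 15)
            res = compare_groups(v, lab, method="kruskal_dunn_bh")
            for (g1, g2), padj in res.pairwise.items():
                shared = set(res.letters[g1]) & set(res.letters[g2])
                assert bool(shared) == (padj >= res.alpha)

    def test_dunn_matches_known_small_example(self):
        # hand-checked: mean ranks 3, 8, 13 for three groups of 5 (no ties)
        v = np.arange(1.0, 16.0)
        lab = np.repeat(["a", "b", "c"], 5)
        raw = dunn_test(v, lab)
        se = np.sqrt(15 * 16 / 12 * (1 / 5 + 1 / 5))
        from scipy.stats import norm

        assert raw[("a", "b")] == pytest.approx(2 * norm.sf(5 / se), rel=1e-12)
        assert raw[("a", "c")] == pytest.approx(2 * norm.sf(10 / se), rel=1e-12)


class TestCompactLetters:
    def test_no_significance_single_letter(self):
        letters = compact_letter_display(list("abc"), set())
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        groups = list("abcd")
        sig = {frozenset(p) for p in itertools.combinations(groups, 2)}
        letters = compact_letter_display(groups, sig)
        assert len(set(letters.values())) == 4

    def test_chain_structure(self):
        # a ~ b, b ~ c, but a vs c significant: b bridges with two letters
        letters = compact_letter_display(["a", "b", "c"], {frozenset("ac")})
        assert set(letters["a"]) != set(letters["c"])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])


class TestSpearman:
    def test_perfect_monotone_pair(self):
        df = pd.DataFrame({"x": np.arange(12.0), "y": np.arange(12.0) ** 3})
        m = spearman_matrix(df)
        assert m.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({"x": r.normal(size=500), "y": r.normal(size=500)})
            hits += abs(spearman_matrix(df).loc["x", "y"]) < 0.1
        assert hits >= 45

    def test_ei_mcv_strongly_correlated_over_study_range(self, prop_table):
        """EI and MCV computed on samples spanning the study's proportion
        range are rank-correlated at r >= 0.90."""
        from endoflow import simulate
        from endoflow.indices import endoreduplication_index, mean_c_value

        rng = np.random.default_rng(7)
        templates = prop_table.to_dict("records")
        eis, mcvs = [], []
        for i in range(500):
            row = templates[i % len(templates)]
            p = np.array([row[f"{c}C"] for c in (2, 4, 8, 16, 32, 64)])
            c = simulate.simulate_counts(p / p.sum(), 1000, rng)
            eis.append(endoreduplication_index(c))
            mcvs.append(mean_c_value(c))
        m = spearman_matrix(pd.DataFrame({"ei": eis, "mcv": mcvs}))
        assert m.loc["ei", "mcv"] >= 0.90

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        assert np.isnan(spearman_matrix(df).loc["x", "y"])


class TestDispersion:
    def test_published_genome_size_cv(self):
        d = cv_across_species([3.176, 2.311, 2.687, 2.963], parameter="GS")
        assert d.cv_percent == pytest.approx(13.41, abs=0.05)

    @pytest.mark.parametrize(
        "means, cv", [([2.0, 2.0, 2.0], 0.0), ([1.0, 3.0], 70.710678)]
    )
    def test_simple_cases(self, means, cv):
        assert cv_across_species(means).cv_percent == pytest.approx(cv, abs=1e-6)

    def test_scale_invariant_not_shift_invariant(self, rng):
        x = rng.uniform(1, 5, 6)
        base = cv_across_species(x).cv_percent
        assert cv_across_species(3.7 * x).cv_percent == pytest.approx(base)
        assert cv_across_species(x + 10).cv_percent != pytest.approx(base)


class TestPCA:
    def test_rank_one_matrix_pc1_explains_all(self):
        u = np.array([1.0, 2.0, 3.0, 5.0])
        v = np.array([0.5, 1.0, 2.0])
        m = pd.DataFrame(np.outer(u, v))
        res = pca_centered(m)
        assert res.explained_percent[0] == pytest.approx(100.0)

    def test_mirrored_copy_same_variance_profile(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 4)))
        res1 = pca_centered(m)
        res2 = pca_centered(-m)
        np.testing.assert_allclose(
            res1.explained_percent, res2.explained_percent, atol=1e-9
        )

    def test_oracle_eigendecomposition(self, rng):
        """Variance explained matches a brute-force eigendecomposition of
        the column-centred covariance to 1e-8."""
        X = rng.normal(size=(80, 4))
        res = pca_centered(pd.DataFrame(X))
        C = np.cov((X - X.mean(axis=0)).T)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(
            res.explained_percent, 100 * eig / eig.sum(), atol=1e-8
        )

    def test_variance_conservation(self, rng):
        res = pca_centered(pd.DataFrame(rng.normal(size=(25, 4))))
        assert res.explained_percent.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(res.explained_percent) <= 1e-12)

    def test_missing_cells_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(DomainError):
            pca_centered(m)


class TestStandardize:
    def test_simple_triple(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(
            standardize(2.5 + 1.7 * x), standardize(x), atol=1e-12
        )

    def test_zero_sd_rejected(self):
        with pytest.raises(DomainError):
            standardize([2.0, 2.0, 2.0])

    def test_size_vs_endopolyploidy_trend_negative(self, gs_table, param_table):
        """Standardized per-organ species EI means correlate negatively (by
        rank) with standardized genome sizes in root, stem, calyx, corolla."""
        from scipy.stats import spearmanr

        gs = dict(zip(gs_table.species, gs_table.c2_pg))
        for organ in ("root", "stem", "calyx", "corolla"):
            sub = param_table[param_table.organ == organ]
            ei_z = standardize(sub.ei.to_numpy(float))
            gs_z = standardize(np.array([gs[s] for s in sub.species]))
            assert spearmanr(ei_z, gs_z).statistic < 0
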