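"""Permutation statistics, block ANOVA, PCA scoring, Wilcoxon tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from larksong import stats as st
from larksong import synth

FEATURE_COLS = list(synth.REFERENCE_PHASE_STATS)


def two_cloud_table(n=20, d=3, delta=10.0, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"x{i}" for i in range(d)]
    a = rng.standard_normal((n, d))
    b = rng.standard_normal((n, d)) + delta
    df = pd.DataFrame(np.vstack([a, b]), columns=cols)
    df["phase"] = ["A"] * n + ["B"] * n
    return df, cols


class TestFisherLDA:
    def test_separated_clouds_fully_classified(self):
        table, cols = two_cloud_table(delta=10.0)
        res = st.fisher_lda(table, cols)
        assert res.n_correct == res.n_total == 40

    def test_identical_distributions_near_chance(self):
        rates = []
        for seed in range(30):
            table, cols = two_cloud_table(n=20, delta=0.0, seed=seed)
            res = st.fisher_lda(table, cols)
            rates.append(res.n_correct / res.n_total)
        # in-sample fit keeps the rate slightly above 0.5, but far from 1
        assert 0.45 <= float(np.mean(rates)) <= 0.75

    def test_one_dimensional_axis_is_the_coordinate(self):
        table, cols = two_cloud_table(d=1, delta=3.0)
        res = st.fisher_lda(table, cols)
        assert res.axis.shape == (1,)
        assert res.axis[0] != 0

    def test_matches_sklearn_predictions(self):
        """Independent cross-check: sklearn's LDA assigns the same classes."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        table, cols = two_cloud_table(n=25, d=4, delta=1.0, seed=3)
        res = st.fisher_lda(table, cols)
        sk = LinearDiscriminantAnalysis().fit(table[cols], table["phase"])
        assert (sk.predict(table[cols]) == res.predicted).mean() > 0.97

    def test_missing_values_rejected(self):
        table, cols = two_cloud_table()
        table.loc[0, cols[0]] = np.nan
        with pytest.raises(ValueError):
            st.fisher_lda(table, cols)


class TestPDFA:
    def test_p_floor_is_one_over_nperm_plus_one(self):
        tab = synth.simulate_phase_feature_table(12, 2, effect="reference", seed=1)
        res = st.pdfa_crossed(tab, FEATURE_COLS, n_permutations=200, seed=1,
                              exclude=("gap_ms",))
        assert res.p_value >= 1 / 201 - 1e-12
        assert res.p_value == pytest.approx(1 / 201)

    def test_scale_invariance_of_p(self):
        """LDA is affine-invariant, so rescaling a column leaves p unchanged."""
        tab = synth.simulate_phase_feature_table(8, 2, effect="null", seed=4)
        res1 = st.pdfa_crossed(tab, FEATURE_COLS, n_permutations=50, seed=9)
        tab2 = tab.copy()
        tab2["tempo"] = tab2["tempo"] * 1000.0
        res2 = st.pdfa_crossed(tab2, FEATURE_COLS, n_permutations=50, seed=9)
        assert res1.p_value == res2.p_value
        assert res1.n_correct == res2.n_correct

    def test_excluded_parameters_recorded(self):
        tab = synth.simulate_phase_feature_table(8, 2, seed=2)
        res = st.pdfa_crossed(tab, FEATURE_COLS, n_permutations=20, seed=2,
                              exclude=("gap_ms",))
        assert res.excluded_parameters == ("gap_ms",)
        assert "gap_ms" not in res.discriminant_coefficients

    def test_uncrossed_design_rejected(self):
        tab = synth.simulate_phase_feature_table(6, 2, seed=3)
        tab = tab[~((tab.individual_id == "M00") & (tab.phase == "level"))]
        with pytest.raises(ValueError):
            st.pdfa_crossed(tab, FEATURE_COLS, n_permutations=10, seed=0)

    def test_normality_screen_flags_skewed_column(self):
        tab = synth.simulate_phase_feature_table(10, 4, seed=5)
        rng = np.random.default_rng(0)
        tab["gap_ms"] = np.exp(3 * rng.standard_normal(len(tab)))
        screen = st.normality_screen(tab, FEATURE_COLS)
        assert screen["gap_ms"] < 0.05
        assert screen["tempo"] > 0.05


def brute_force_paired_p(d):
    """Exact two-tailed sign-flip p for the mean difference."""
    n = len(d)
    obs = abs(np.mean(d))
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        if abs(np.mean(np.array(signs) * d)) >= obs - 1e-12:
            count += 1
    return count / 2**n


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        assert st.paired_permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_three_equal_differences(self):
        # all 8 sign patterns; only (+,+,+) and (-,-,-) reach |mean| = 1
        p = st.paired_permutation_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0], mode="exact")
        assert p == pytest.approx(2 / 8)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        p = st.paired_permutation_test(x, y, mode="exact")
        assert p == pytest.approx(brute_force_paired_p(x - y))

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal(9), rng.standard_normal(9)
        p_exact = st.paired_permutation_test(x, y, mode="exact")
        p_mc = st.paired_permutation_test(x, y, mode="monte_carlo", n_mc=10000, seed=1)
        assert abs(p_exact - p_mc) <= 0.02

    def test_monte_carlo_p_never_zero(self):
        x = np.arange(1.0, 31.0)
        p = st.paired_permutation_test(x, np.zeros(30), mode="monte_carlo",
                                       n_mc=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_exact_mode_cap_enforced(self):
        with pytest.raises(ValueError):
            st.paired_permutation_test(np.ones(30), np.zeros(30), mode="exact",
                                       exact_cap=2**20)


class TestWithinSubjectTest:
    def table(self, n_subj=10, shift=0.0, noise=1.0, seed=0, reps=1):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            base = rng.standard_normal() * 2
            for phase, mu in (("ascending", shift), ("level", 0.0)):
                for r in range(reps):
                    rows.append({"individual_id": f"S{s}", "phase": phase,
                                 "y": base + mu + noise * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_identical_phase_means_give_f_zero(self):
        df = self.table(shift=0.0, noise=0.0)
        f, p = st.within_subject_phase_test(df, "y")
        assert f == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_large_effect_detected(self):
        f, p = st.within_subject_phase_test(self.table(n_subj=20, shift=1.0, noise=0.1), "y")
        assert p < 1e-3

    def test_equals_paired_t_squared(self):
        """For two phases the block-ANOVA F is the square of the paired t."""
        df = self.table(n_subj=12, shift=0.4, seed=5)
        f, p = st.within_subject_phase_test(df, "y")
        wide = df.pivot_table(index="individual_id", columns="phase", values="y")
        t, p_t = scipy.stats.ttest_rel(wide["ascending"], wide["level"])
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(p_t)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        df = self.table(n_subj=8, shift=0.5, seed=7)
        f, p = st.within_subject_phase_test(df, "y")
        res = AnovaRM(df, "y", "individual_id", within=["phase"]).fit()
        assert f == pytest.approx(float(res.anova_table["F Value"].iloc[0]))
        assert p == pytest.approx(float(res.anova_table["Pr > F"].iloc[0]))

    def test_replicates_averaged_within_cells(self):
        df = self.table(n_subj=8, shift=0.5, seed=9, reps=3)
        f, p = st.within_subject_phase_test(df, "y")
        cell = df.groupby(["individual_id", "phase"], as_index=False)["y"].mean()
        f2, p2 = st.within_subject_phase_test(cell, "y")
        assert f == pytest.approx(f2)

    def test_type_i_error_near_nominal(self):
        rejections = 0
        n_reps = 400
        for seed in range(n_reps):
            _, p = st.within_subject_phase_test(self.table(n_subj=20, seed=seed), "y")
            rejections += p <= 0.05
        assert 0.035 <= rejections / n_reps <= 0.065

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            st.within_subject_phase_test(self.table(n_subj=2), "y")


class TestDedupMeasures:
    def test_duplicate_column_dropped(self):
        df = synth.simulate_responses(10, seed=1)
        reduced, dropped = st.dedup_measures(df, list(synth.RESPONSE_MEASURES),
                                             count_floor=5)
        assert "time_10_5_s" not in reduced.columns
        assert "time_5_0_s" not in reduced.columns
        assert "movement_10_5_duration_s" in reduced.columns
        assert any("n_calls" in d for d in dropped)

    def test_distinct_random_columns_untouched(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        reduced, dropped = st.dedup_measures(df, list("abcd"))
        assert dropped == []
        assert list(reduced.columns) == list("abcd")

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.standard_normal(10), "z": np.zeros(10)})
        reduced, dropped = st.dedup_measures(df, ["a", "z"])
        assert "z" not in reduced.columns
        assert any("zero variance" in d for d in dropped)

    def test_anticorrelated_duplicate_dropped(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(15)
        df = pd.DataFrame({"a": a, "b": -2.0 * a + 3.0})
        _, dropped = st.dedup_measures(df, ["a", "b"])
        assert any(d.startswith("b") for d in dropped)


class TestResponsePCA:
    def test_two_perfectly_correlated_measures(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(30)
        df = pd.DataFrame({"a": a, "b": 2 * a + 1})
        scores = st.response_pca(df, ["a", "b"])
        assert scores.eigenvalues[0] == pytest.approx(2.0)
        assert scores.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        assert scores.retained == (0,)

    def test_loading_sign_convention(self):
        df = synth.simulate_responses(20, seed=3)
        reduced, _ = st.dedup_measures(df, list(synth.RESPONSE_MEASURES), count_floor=5)
        kept = [m for m in synth.RESPONSE_MEASURES if m in reduced.columns]
        scores = st.response_pca(reduced, kept)
        for comp in scores.loadings.columns:
            load = scores.loadings[comp]
            assert load.iloc[np.argmax(np.abs(load.to_numpy()))] > 0

    def test_two_latent_factors_retain_two_components(self):
        """Responses driven by two latent factors keep exactly two
        components (eigenvalue > 1) in the large majority of replicates."""
        hits = 0
        for seed in range(30):
            df = synth.simulate_responses(20, seed=seed)
            reduced, _ = st.dedup_measures(df, list(synth.RESPONSE_MEASURES),
                                           count_floor=5)
            kept = [m for m in synth.RESPONSE_MEASURES if m in reduced.columns]
            scores = st.response_pca(reduced, kept)
            assert np.all(np.diff(scores.eigenvalues) <= 1e-12)
            hits += len(scores.retained) == 2
        assert hits >= 24

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(ValueError):
            st.response_pca(df, ["a", "b"])

    def test_independent_measures_flagged_unstable(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
        scores = st.response_pca(df, list("abcd"))
        assert scores.unstable_retention


def brute_force_wilcoxon_p(d):
    """Two-tailed signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = max(ranks[d > 0].sum(), ranks[d < 0].sum())
    dev_obs = abs(w_obs - total / 2)
    count = 0
    for signs in itertools.product((1, 0), repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - total / 2) >= dev_obs - 1e-9:
            count += 1
    return count / 2 ** len(d)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        w, p = st.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0],
                                       [1.0, 2.0, 3.0, 4.0, 5.0])
        assert p == 1.0

    def test_all_positive_differences_minimal_p(self):
        x = np.arange(1.0, 11.0)
        w, p = st.wilcoxon_signed_rank(x + 10, x)
        assert w == pytest.approx(55.0)
        assert p == pytest.approx(2 / 1024)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # half-integer values provoke ties in |d|
        x = np.round(rng.standard_normal(9) * 2) / 2
        y = np.round(rng.standard_normal(9) * 2) / 2
        if np.all(x - y == 0):
            return
        _, p = st.wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(brute_force_wilcoxon_p(x - y))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        _, p = st.wilcoxon_signed_rank(x, y)
        p_scipy = scipy.stats.wilcoxon(x, y, method="exact").pvalue
        assert p == pytest.approx(p_scipy)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        y = x + 0.5 + rng.standard_normal(40)
        _, p = st.wilcoxon_signed_rank(x, y)
        p_scipy = scipy.stats.wilcoxon(x, y, method="approx", correction=False).pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)


class TestPlaybackAnalysis:
    def test_identical_scores_give_f_zero(self):
        df = synth.simulate_responses(8, seed=6)
        reduced, _ = st.dedup_measures(df, list(synth.RESPONSE_MEASURES), count_floor=5)
        kept = [m for m in synth.RESPONSE_MEASURES if m in reduced.columns]
        scores = st.response_pca(reduced, kept)
        # overwrite scores with a per-subject constant: S1 == S2 everywhere
        forced = scores.scores.copy()
        subj_code = reduced["subject"].astype("category").cat.codes.to_numpy(float)
        for comp in forced.columns:
            forced[comp] = subj_code
        forced_scores = st.PCScores(
            eigenvalues=scores.eigenvalues, retained=scores.retained,
            variance_fraction=scores.variance_fraction, loadings=scores.loadings,
            scores=forced,
        )
        res = st.playback_analysis(forced_scores, reduced)
        assert np.allclose(res["F_stimulus"], 0.0)

    def test_vocal_effect_detected_on_song_component(self):
        df = synth.simulate_responses(12, vocal_effect=2.5, seed=7)
        reduced, _ = st.dedup_measures(df, list(synth.RESPONSE_MEASURES), count_floor=5)
        kept = [m for m in synth.RESPONSE_MEASURES if m in reduced.columns]
        scores = st.response_pca(reduced, kept)
        res = st.playback_analysis(scores, reduced)
        song_comp = scores.loadings.loc["song_duration_s"].abs().idxmax()
        row = res[res["component"] == song_comp].iloc[0]
        assert row["p_stimulus"] < 0.05
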