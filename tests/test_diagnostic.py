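import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats

import mspanel as mp
from mspanel._search import CombinationScore, ModelSpec, SearchReport
from mspanel.diagnostic import _rank_auc

from .conftest import make_panel, make_subjects
from .oracles import auc_pair_counting


class TestFolds:
    def test_157_subjects_into_4_folds(self, paper_like_cohort):
        cohort, _ = paper_like_cohort
        folds = mp.make_folds(cohort.subjects, k=4, seed=0)
        sizes = sorted((np.bincount(list(folds.fold_of.values()))[1:]).tolist(),
                       reverse=True)
        assert sizes == [40, 39, 39, 39]

    def test_same_seed_identical(self, paper_like_cohort):
        cohort, _ = paper_like_cohort
        a = mp.make_folds(cohort.subjects, seed=3)
        b = mp.make_folds(cohort.subjects, seed=3)
        assert a.fold_of == b.fold_of

    def test_stratification_balances_groups(self, paper_like_cohort):
        cohort, _ = paper_like_cohort
        folds = mp.make_folds(cohort.subjects, k=4, seed=1)
        ms_ids = {s.subject_id for s in cohort.subjects if s.is_ms}
        for f in range(1, 5):
            ids = folds.test_ids(f)
            n_ms = sum(1 for i in ids if i in ms_ids)
            assert abs(n_ms - 77 / 4) <= 1
            assert abs((len(ids) - n_ms) - 80 / 4) <= 1

    def test_small_stratum_rejected(self):
        subjects = make_subjects([1, 1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="stratum"):
            mp.make_folds(subjects, k=4)


class TestLogistic:
    def test_null_features_have_null_slopes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(600, 3))
        y = rng.integers(0, 2, size=600).astype(float)
        scorer = mp.fit_logistic(X, y)
        for b, se in zip(scorer.coef[1:], scorer.se[1:]):
            assert abs(b) < 3 * se

    def test_recovers_planted_log_odds_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
        y = (rng.random(5000) < p).astype(float)
        scorer = mp.fit_logistic(x[:, None], y)
        assert abs(scorer.coef[1] - 1.0) < 3 * scorer.se[1]

    def test_matches_statsmodels_mle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 0])))).astype(float)
        ours = mp.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(ours.coef, ref.params, atol=1e-6)
        assert np.allclose(ours.se, ref.bse, rtol=1e-4)

    def test_separation_triggers_ridge_fallback(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        scorer = mp.fit_logistic(x[:, None], x)
        assert scorer.ridged
        assert scorer.warnings and "ridge" in scorer.warnings[0]
        assert np.isfinite(scorer.coef).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            mp.fit_logistic(np.zeros((4, 1)), np.ones(4))


class TestAuc:
    def test_worked_example(self):
        assert mp.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == \
            pytest.approx(0.75)

    def test_perfect_and_degenerate(self):
        assert mp.roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert mp.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            mp.roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(25))
    def test_identities_auc_u_rank_pairs(self, seed):
        """roc_auc == U/(n1 n0) == rank formula == brute-force pairs."""
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 20, size=2)
        scores = np.round(rng.normal(size=n1 + n0), 1)   # force some ties
        labels = np.concatenate([np.ones(n1), np.zeros(n0)])
        auc = mp.roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n1 * n0))
        assert auc == pytest.approx(_rank_auc(scores, labels))
        assert auc == pytest.approx(auc_pair_counting(scores, labels))


class TestEvaluateCombination:
    def test_single_shifted_marker_hits_binormal_auc(self):
        """Group shift d=1 SD: cross-validated AUC ~ Phi(1/sqrt(2))."""
        aucs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = 2000
            labels = np.concatenate([np.zeros(n), np.ones(n)])
            z = rng.normal(size=2 * n) + labels
            subjects = make_subjects(labels.astype(int), rng=rng)
            panel = make_panel({("M", "CSF"): z}, [s.subject_id for s in subjects])
            folds = mp.make_folds(subjects, k=4, seed=seed)
            score = mp.evaluate_combination(
                ModelSpec((("M", "CSF"),)), panel, subjects, folds)
            aucs.append(score.mean_test)
        target = stats.norm.cdf(1 / np.sqrt(2))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - target) < 3 * se

    def test_noise_marker_auc_is_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            labels = rng.integers(0, 2, 300)
            z = rng.normal(size=300)
            subjects = make_subjects(labels, rng=rng)
            panel = make_panel({("M", "CSF"): z}, [s.subject_id for s in subjects])
            folds = mp.make_folds(subjects, k=4, seed=seed)
            score = mp.evaluate_combination(
                ModelSpec((("M", "CSF"),)), panel, subjects, folds)
            aucs.append(score.mean_test)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_age_sex_structure_alone_separates_groups(self, standardized,
                                                      paper_like_cohort):
        """Covariates-only baseline is materially above chance, as the
        age/sex imbalance between the groups implies."""
        cohort, _ = paper_like_cohort
        _, panel = standardized
        folds = mp.make_folds(cohort.subjects, k=4, seed=2)
        score = mp.evaluate_combination(ModelSpec(()), panel, cohort.subjects,
                                        folds)
        assert score.mean_test > 0.65

    def test_complete_case_count(self, standardized, paper_like_cohort):
        cohort, _ = paper_like_cohort
        _, panel = standardized
        folds = mp.make_folds(cohort.subjects, k=4, seed=2)
        key = panel.markers()[0]
        score = mp.evaluate_combination(ModelSpec((key,)), panel,
                                        cohort.subjects, folds)
        assert score.n_complete == int(panel.features[key].notna().sum())


class TestSearch:
    def _tiny_instance(self, seed=0, m=6, informative=2):
        rng = np.random.default_rng(seed)
        n = 300
        labels = np.concatenate([np.zeros(n // 2), np.ones(n // 2)]).astype(int)
        cols = {}
        for j in range(m):
            shift = 1.2 if j < informative else 0.0
            cols[(f"M{j}", "CSF")] = rng.normal(size=n) + shift * labels
        subjects = make_subjects(labels, rng=rng)
        panel = make_panel(cols, [s.subject_id for s in subjects])
        folds = mp.make_folds(subjects, k=4, seed=seed)
        return panel, subjects, folds

    def test_exhaustive_subset_count(self):
        panel, subjects, folds = self._tiny_instance(m=3)
        report = mp.search_diagnostic(list(panel.markers()), panel, subjects,
                                      folds, strategy="exhaustive")
        assert len(report.scores) == 7

    def test_greedy_matches_per_size_on_well_separated_instance(self):
        panel, subjects, folds = self._tiny_instance(seed=3)
        cands = list(panel.markers())
        full = mp.search_diagnostic(cands, panel, subjects, folds,
                                    strategy="per_size_exhaustive", max_size=3)
        greedy = mp.search_diagnostic(cands, panel, subjects, folds,
                                      strategy="greedy_forward", max_size=3)
        assert mp.select_optimum(full) == mp.select_optimum(greedy)

    def test_per_size_best_matches_brute_force(self):
        panel, subjects, folds = self._tiny_instance(seed=4, m=5)
        cands = list(panel.markers())
        report = mp.search_diagnostic(cands, panel, subjects, folds,
                                      max_size=2)
        import itertools
        for size in (1, 2):
            best = max(
                (mp.evaluate_combination(ModelSpec(tuple(sorted(c))), panel,
                                         subjects, folds)
                 for c in itertools.combinations(cands, size)),
                key=lambda s: s.mean_test)
            assert report.best_by_size[size].mean_test == \
                pytest.approx(best.mean_test)

    def test_oversized_exhaustive_refused(self):
        panel, subjects, folds = self._tiny_instance()
        cands = [(f"X{i}", "CSF") for i in range(30)]
        with pytest.raises(ValueError, match="per_size_exhaustive"):
            mp.search_combinations(cands, lambda s: None, strategy="exhaustive")


def _fake_report(means):
    scores = {}
    for size, mean in means.items():
        markers = tuple((f"M{j}", "CSF") for j in range(size))
        scores[size] = CombinationScore(ModelSpec(markers), [mean], [mean], 100)
    return SearchReport(scores=list(scores.values()), best_by_size=scores)


class TestSelectOptimum:
    def test_stops_when_gain_below_delta(self):
        report = _fake_report({1: 0.80, 2: 0.85, 3: 0.855})
        assert mp.select_optimum(report, delta=0.01).size == 2
        assert report.selection_trace[-1][0] == 2

    def test_single_size_selected(self):
        report = _fake_report({1: 0.8})
        assert mp.select_optimum(report).size == 1

    def test_runs_to_max_size_when_gains_large(self):
        report = _fake_report({1: 0.6, 2: 0.7, 3: 0.8})
        assert mp.select_optimum(report, delta=0.01).size == 3

    @given(st.lists(st.floats(min_value=0.5, max_value=1.0), min_size=1,
                    max_size=8))
    def test_selected_size_non_increasing_in_delta(self, means):
        by_size = {i + 1: m for i, m in enumerate(means)}
        sizes = []
        for delta in (0.001, 0.01, 0.05, 0.2):
            report = _fake_report(by_size)
            sizes.append(mp.select_optimum(report, delta=delta).size)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestStability:
    def test_single_rep_reproducible(self, standardized, paper_like_cohort):
        cohort, _ = paper_like_cohort
        _, panel = standardized
        spec = ModelSpec((("sCD27", "CSF"),))
        a = mp.stability_reruns(spec, panel, cohort.subjects, n_reps=1, seed=9)
        b = mp.stability_reruns(spec, panel, cohort.subjects, n_reps=1, seed=9)
        assert a.test_aucs[0] == b.test_aucs[0]

    def test_strong_panel_consistent_with_cv_estimate(self, standardized,
                                                      paper_like_cohort):
        cohort, _ = paper_like_cohort
        _, panel = standardized
        spec = ModelSpec((("sCD27", "CSF"), ("NfL", "CSF")))
        folds = mp.make_folds(cohort.subjects, k=4, seed=0)
        cv = mp.evaluate_combination(spec, panel, cohort.subjects, folds)
        stab = mp.stability_reruns(spec, panel, cohort.subjects, n_reps=200,
                                   seed=0)
        assert abs(np.mean(stab.test_aucs) - cv.mean_test) < 0.05

    def test_noise_panel_centres_on_half(self):
        # reps within one dataset are correlated, so average over
        # independent datasets and take the SE across datasets
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 50)
            labels = rng.integers(0, 2, 400)
            subjects = make_subjects(labels, rng=rng)
            panel = make_panel({("M", "CSF"): rng.normal(size=400)},
                               [s.subject_id for s in subjects])
            stab = mp.stability_reruns(ModelSpec((("M", "CSF"),)), panel,
                                       subjects, n_reps=20, seed=seed)
            means.append(np.mean(stab.test_aucs))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) < 3 * se
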