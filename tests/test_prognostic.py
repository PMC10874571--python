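import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index

import mspanel as mp
from mspanel._search import ModelSpec

from .conftest import make_panel
from .oracles import concordance_pairs


def _ms(sid="A", fu=8.0, relapses=(), dmt=None, baseline=2.0, visits=()):
    return mp.Subject(subject_id=sid, group=mp.MS, age_at_sampling=40.0,
                      sex="F", followup_years=fu, baseline_edss=baseline,
                      dmt_start_years=dmt, dmt_ever=dmt is not None,
                      relapse_times=list(relapses), edss_visits=list(visits))


class TestRelapseOutcome:
    def test_relapse_before_dmt_is_event(self):
        o = mp.derive_relapse_outcome(_ms(relapses=[2.0], dmt=3.0))
        assert (o.time, o.event, o.censor_reason) == (2.0, True, "NONE")

    def test_dmt_before_relapse_censors(self):
        o = mp.derive_relapse_outcome(_ms(relapses=[2.0], dmt=1.0))
        assert (o.time, o.event, o.censor_reason) == (1.0, False, "DMT_START")

    def test_no_event_censors_at_followup(self):
        o = mp.derive_relapse_outcome(_ms(fu=7.0))
        assert (o.time, o.event, o.censor_reason) == (7.0, False, "END_FOLLOWUP")

    def test_control_rejected(self):
        control = mp.Subject("C", mp.CONTROL, 30.0, "F")
        with pytest.raises(ValueError):
            mp.derive_relapse_outcome(control)


class TestEdss6Outcome:
    def test_baseline_at_six_excluded(self):
        o = mp.derive_edss6_outcome(_ms(baseline=6.5))
        assert o.excluded and "sampling" in o.exclude_reason

    def test_confirmed_event(self):
        o = mp.derive_edss6_outcome(
            _ms(visits=[(3.0, 4.0), (4.0, 6.0), (4.6, 6.5)]))
        assert (o.time, o.event) == (4.0, True)

    def test_unsustained_spike_not_event(self):
        o = mp.derive_edss6_outcome(
            _ms(fu=8.0, visits=[(4.0, 6.0), (4.3, 5.5), (5.0, 5.5)]))
        assert not o.event and o.time == 8.0

    def test_second_run_qualifies_after_failed_first(self):
        o = mp.derive_edss6_outcome(
            _ms(visits=[(4.0, 6.0), (4.3, 5.5), (6.0, 6.0), (6.8, 6.5)]))
        assert (o.time, o.event) == (6.0, True)

    def test_sustained_to_end_of_followup_counts(self):
        o = mp.derive_edss6_outcome(_ms(fu=5.0, visits=[(4.0, 6.0)]))
        assert (o.time, o.event) == (4.0, True)

    def test_tail_too_short_for_confirmation_censors(self):
        o = mp.derive_edss6_outcome(_ms(fu=4.2, visits=[(4.0, 6.0)]))
        assert not o.event and o.time == 4.2

    def test_visits_within_relapse_window_ignored(self):
        # the only >= 6 reading is 20 days after a relapse: discarded
        o = mp.derive_edss6_outcome(
            _ms(fu=8.0, relapses=[4.0],
                visits=[(3.0, 4.0), (4.0 + 20 / 365.25, 6.5), (5.0, 4.5)]))
        assert not o.event

    def test_no_eligible_visits_flagged_degenerate(self):
        o = mp.derive_edss6_outcome(_ms(visits=[]))
        assert o.degenerate and not o.event


class TestHarrellC:
    def test_perfect_ordering(self):
        assert mp.harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_all_risk_ties_is_half(self):
        assert mp.harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_worked_censored_example(self):
        c = mp.harrell_c([5, 1, 4, 2], [2, 4, 3, 5], [1, 1, 0, 1])
        assert c == pytest.approx(0.75)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            mp.harrell_c([1, 2], [1, 2], [0, 0])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        times = rng.exponential(size=n)
        events = rng.random(n) < 0.7
        risk = np.round(rng.normal(size=n), 1)
        if not events.any():
            events[0] = True
        assert mp.harrell_c(risk, times, events) == pytest.approx(
            concordance_pairs(risk, times, events))

    def test_matches_lifelines_on_untied_times(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(size=40)
        events = rng.random(40) < 0.6
        events[0] = True
        risk = rng.normal(size=40)
        ours = mp.harrell_c(risk, times, events)
        ref = concordance_index(times, -risk, events)
        assert ours == pytest.approx(ref)

    def test_uncensored_negative_time_risk_is_perfect(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(size=25)
        assert mp.harrell_c(-times, times, np.ones(25, bool)) == 1.0


def _sim_survival(n, beta, censor_frac=0.2, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * z))
    c = np.quantile(t, 1 - censor_frac) * np.ones(n) if censor_frac else np.inf
    time = np.minimum(t, c)
    event = t <= c
    return pd.DataFrame({"time": time, "event": event.astype(float), "z": z})


class TestFitCox:
    def test_recovers_planted_beta(self):
        frame = _sim_survival(2000, 0.7, seed=3)
        res = mp.fit_cox(frame, ["z"], [])
        assert abs(res.beta("z") - 0.7) < 3 * res.se("z")
        assert res.n == 2000 and res.n_events == int(frame["event"].sum())

    def test_null_marker_test_concordance_half(self):
        # held-out concordance: the apparent statistic of a fitted
        # model is optimistically biased even under the null
        cs = []
        for seed in range(15):
            frame = _sim_survival(300, 0.0, seed=seed)
            train, test = frame.iloc[:150], frame.iloc[150:]
            res = mp.fit_cox(train, ["z"], [])
            cs.append(mp.harrell_c(res.beta("z") * test["z"],
                                   test["time"], test["event"] > 0))
        se = np.std(cs, ddof=1) / np.sqrt(len(cs))
        assert abs(np.mean(cs) - 0.5) < 3 * se

    def test_rank_invariance_under_time_scaling(self):
        frame = _sim_survival(300, 0.5, seed=5)
        res1 = mp.fit_cox(frame, ["z"], [])
        frame2 = frame.assign(time=frame["time"] * 2.0)
        res2 = mp.fit_cox(frame2, ["z"], [])
        assert res1.beta("z") == pytest.approx(res2.beta("z"), rel=1e-8)
        assert res1.concordance == pytest.approx(res2.concordance)

    def test_monotone_time_transform_preserves_beta(self):
        frame = _sim_survival(300, 0.5, seed=6)
        res1 = mp.fit_cox(frame, ["z"], [])
        frame2 = frame.assign(time=np.sqrt(frame["time"]))
        res2 = mp.fit_cox(frame2, ["z"], [])
        assert res1.beta("z") == pytest.approx(res2.beta("z"), rel=1e-6)

    def test_zero_events_rejected(self):
        frame = _sim_survival(20, 0.0, censor_frac=0.0, seed=7)
        frame["event"] = 0.0
        with pytest.raises(ValueError, match="events"):
            mp.fit_cox(frame, ["z"], [])

    def test_lr_p_null_uniformish(self):
        ps = [mp.fit_cox(_sim_survival(120, 0.0, seed=s), ["z"], []).lr_p
              for s in range(40)]
        assert np.mean(np.asarray(ps) < 0.05) < 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / 40)


class TestCoxSearch:
    def test_three_candidates_exhaustive_evaluates_seven(self, recovery_cohort):
        cohort, _ = recovery_cohort
        _, panel = mp.standardize_cohort(cohort)
        outcomes = mp.derive_outcomes(cohort.subjects, "relapse")
        ms = [s for s in cohort.subjects if s.is_ms]
        folds = mp.make_folds(ms, k=4, seed=0, stratify="none")
        cands = list(panel.markers())[:3]
        report = mp.search_prognostic(cands, panel, cohort.subjects, outcomes,
                                      folds, strategy="per_size_exhaustive",
                                      max_size=3)
        assert len(report.scores) == 7

    def test_planted_relapse_marker_selected(self, recovery_cohort):
        cohort, truth = recovery_cohort
        _, panel = mp.standardize_cohort(cohort)
        outcomes = mp.derive_outcomes(cohort.subjects, "relapse")
        ms = [s for s in cohort.subjects if s.is_ms]
        folds = mp.make_folds(ms, k=4, seed=1, stratify="none")
        report = mp.search_prognostic(list(panel.markers()), panel,
                                      cohort.subjects, outcomes, folds,
                                      strategy="greedy_forward", max_size=3)
        selected = mp.select_optimum(report)
        assert set(truth.informative_relapse) <= set(selected.markers)

    def test_event_bookkeeping_matches_complete_cases(self, recovery_cohort):
        cohort, _ = recovery_cohort
        _, panel = mp.standardize_cohort(cohort)
        outcomes = mp.derive_outcomes(cohort.subjects, "relapse")
        key = panel.markers()[0]
        spec = ModelSpec((key,))
        res = mp.refit_full_cox(spec, panel, cohort.subjects, outcomes)
        expected = sum(
            1 for o in outcomes
            if o.event and not o.excluded
            and np.isfinite(panel.features[key].get(o.subject_id, np.nan)))
        assert res.n_events == expected

    def test_edss6_outcome_forces_dmt_covariate(self, recovery_cohort):
        cohort, _ = recovery_cohort
        _, panel = mp.standardize_cohort(cohort)
        outcomes = mp.derive_outcomes(cohort.subjects, "edss6")
        ms = [s for s in cohort.subjects if s.is_ms]
        folds = mp.make_folds(ms, k=4, seed=2, stratify="none")
        report = mp.search_prognostic(list(panel.markers())[:2], panel,
                                      cohort.subjects, outcomes, folds,
                                      strategy="greedy_forward", max_size=1,
                                      outcome_name="edss6")
        assert all(s.spec.covariates == ("age", "sex", "dmt_ever")
                   for s in report.scores)
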