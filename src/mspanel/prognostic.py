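"""Prognostic panel modelling: outcome construction, Cox regression,
Harrell's concordance and the concordance-objective combination search.

Two outcomes are supported for MS subjects:

* time from sampling to next relapse, censored at disease-modifying
  therapy (DMT) start (DMT suppresses relapses) or end of follow-up;
* time from sampling to EDSS 6 sustained for at least six months,
  using only EDSS scores measured more than 30 days after a relapse,
  excluding subjects already at EDSS >= 6 at sampling.

Candidate models are Cox proportional-hazards fits of the outcome on
panel Z-scores with age and sex (plus ever-DMT for the EDSS outcome)
always included; models are compared by the mean Harrell concordance
of the train-fold linear predictor evaluated on the test fold, and the
panel grows under the same delta < 0.01 stopping rule as the
diagnostic search.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from ._search import (CombinationScore, Marker, ModelSpec, SearchReport,
                      search_combinations, select_optimum)
from .cohort import Subject
from .diagnostic import FoldAssignment
from .preprocess import StandardizedPanel

__all__ = ["SurvivalOutcome", "CoxResult", "derive_relapse_outcome",
           "derive_edss6_outcome", "fit_cox", "harrell_c",
           "evaluate_combination_cox", "search_prognostic", "select_optimum",
           "RELAPSE", "EDSS6"]

RELAPSE = "relapse"
EDSS6 = "edss6"

DMT_START = "DMT_START"
END_FOLLOWUP = "END_FOLLOWUP"
NONE = "NONE"

DAYS_PER_YEAR = 365.25


@dataclass
class SurvivalOutcome:
    subject_id: str
    time: float | None
    event: bool
    censor_reason: str               # DMT_START | END_FOLLOWUP | NONE
    excluded: bool = False
    exclude_reason: str | None = None
    degenerate: bool = False


def derive_relapse_outcome(subject: Subject) -> SurvivalOutcome:
    """Time to next relapse, censored at DMT start or end of follow-up."""
    if not subject.is_ms:
        raise ValueError(f"{subject.subject_id}: relapse outcome is defined "
                         "for MS subjects only")
    first_relapse = subject.relapse_times[0] if subject.relapse_times else np.inf
    dmt = subject.dmt_start_years if subject.dmt_start_years is not None else np.inf
    censor_at = min(dmt, subject.followup_years)
    if first_relapse <= censor_at:
        return SurvivalOutcome(subject.subject_id, float(first_relapse), True, NONE)
    reason = DMT_START if dmt <= subject.followup_years else END_FOLLOWUP
    return SurvivalOutcome(subject.subject_id, float(censor_at), False, reason)


def _eligible_visits(subject: Subject, relapse_window_days: float
                     ) -> list[tuple[float, float]]:
    window = relapse_window_days / DAYS_PER_YEAR
    out = []
    for t, e in subject.edss_visits:
        if any(0.0 <= t - r <= window for r in subject.relapse_times):
            continue
        out.append((t, e))
    return out


def derive_edss6_outcome(subject: Subject, sustain_years: float = 0.5,
                         relapse_window_days: float = 30.0) -> SurvivalOutcome:
    """Time to EDSS >= 6 sustained for at least ``sustain_years``.

    Visits within ``relapse_window_days`` after any relapse are
    discarded (transient relapse-related disability).  An eligible
    visit at EDSS >= 6 is an event when every later eligible visit
    within the sustain window is also >= 6 and either a confirming
    eligible visit at least ``sustain_years`` later is >= 6, or
    follow-up extends at least ``sustain_years`` further with no
    dissenting eligible visit.  Subjects already at EDSS >= 6 at
    sampling are excluded.
    """
    if not subject.is_ms:
        raise ValueError(f"{subject.subject_id}: EDSS-6 outcome is defined "
                         "for MS subjects only")
    if subject.baseline_edss is not None and subject.baseline_edss >= 6.0:
        return SurvivalOutcome(subject.subject_id, None, False, NONE,
                               excluded=True,
                               exclude_reason="EDSS >= 6 at sampling")
    eligible = _eligible_visits(subject, relapse_window_days)
    if not eligible:
        return SurvivalOutcome(subject.subject_id, 1e-6, False, END_FOLLOWUP,
                               degenerate=True)
    for i, (t, e) in enumerate(eligible):
        if e < 6.0:
            continue
        rest = eligible[i + 1:]
        if any(e2 < 6.0 for t2, e2 in rest if t2 < t + sustain_years):
            continue
        confirming = [(t2, e2) for t2, e2 in rest if t2 >= t + sustain_years]
        if confirming:
            if confirming[0][1] >= 6.0:
                return SurvivalOutcome(subject.subject_id, float(t), True, NONE)
            continue
        if subject.followup_years >= t + sustain_years:
            return SurvivalOutcome(subject.subject_id, float(t), True, NONE)
    return SurvivalOutcome(subject.subject_id, float(subject.followup_years),
                           False, END_FOLLOWUP)


def derive_outcomes(subjects: list[Subject], which: str,
                    sustain_years: float = 0.5,
                    relapse_window_days: float = 30.0) -> list[SurvivalOutcome]:
    ms = [s for s in subjects if s.is_ms]
    if which == RELAPSE:
        return [derive_relapse_outcome(s) for s in ms]
    if which == EDSS6:
        return [derive_edss6_outcome(s, sustain_years, relapse_window_days)
                for s in ms]
    raise ValueError(f"unknown outcome {which!r}")


def outcomes_frame(outcomes: list[SurvivalOutcome]) -> pd.DataFrame:
    return pd.DataFrame([vars(o) for o in outcomes])


# ---------------------------------------------------------------------------
# Concordance


def harrell_c(risk, times, events) -> float:
    """Harrell's concordance of a risk score against censored times.

    A pair is comparable when the strictly shorter time ends in an
    event; it is concordant when that subject has the higher risk, with
    risk ties counted 1/2.  Pairs with equal times are omitted.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("concordance requires at least one event")
    # pair (i, j) comparable iff event[i] and t[j] > t[i] (strict, so
    # i == j and tied times drop out automatically)
    comparable = events[:, None] & (times[None, :] > times[:, None])
    den = comparable.sum()
    if den == 0:
        raise ValueError("no comparable pairs")
    num = (comparable & (risk[:, None] > risk[None, :])).sum() \
        + 0.5 * (comparable & (risk[:, None] == risk[None, :])).sum()
    return float(num / den)


# ---------------------------------------------------------------------------
# Cox fitting (lifelines, Efron ties)


@dataclass
class CoxResult:
    coefficients: dict[str, tuple[float, float]]   # term -> (beta, se)
    concordance: float
    lr_p: float
    n: int
    n_events: int
    log_likelihood: float

    def beta(self, term: str) -> float:
        return self.coefficients[term][0]

    def se(self, term: str) -> float:
        return self.coefficients[term][1]


def _cox_fit(frame: pd.DataFrame, cols: list[str]) -> CoxPHFitter:
    fitter = CoxPHFitter()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        fitter.fit(frame[cols + ["time", "event"]], duration_col="time",
                   event_col="event")
    return fitter


def fit_cox(frame: pd.DataFrame, marker_cols: list[str],
            covariate_cols: list[str]) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling.

    ``frame`` must carry ``time`` and ``event`` columns plus the model
    terms; rows with any missing term are dropped (complete cases).
    The likelihood-ratio p compares against the covariates-only model
    on the same subjects (chi-squared, df = number of markers); the
    concordance is Harrell's C of the fitted linear predictor.
    """
    cols = marker_cols + covariate_cols
    data = frame[cols + ["time", "event"]].dropna()
    n_events = int(data["event"].sum())
    if n_events == 0:
        raise ValueError("no events among complete cases")
    try:
        full = _cox_fit(data, cols)
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    lp = data[cols].to_numpy() @ full.params_.reindex(cols).to_numpy()
    concordance = harrell_c(lp, data["time"].to_numpy(),
                            data["event"].to_numpy().astype(bool))
    if marker_cols:
        if covariate_cols:
            base = _cox_fit(data, covariate_cols)
            lr = 2.0 * (full.log_likelihood_ - base.log_likelihood_)
        else:
            # covariates-only reduces to the null model (all betas 0)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                lr = float(full.log_likelihood_ratio_test().test_statistic)
        lr_p = float(stats.chi2.sf(max(lr, 0.0), df=len(marker_cols)))
    else:
        lr_p = np.nan
    coeffs = {c: (float(full.params_[c]), float(full.standard_errors_[c]))
              for c in cols}
    return CoxResult(coefficients=coeffs, concordance=float(concordance),
                     lr_p=lr_p, n=len(data), n_events=n_events,
                     log_likelihood=float(full.log_likelihood_))


# ---------------------------------------------------------------------------
# Cross-validated combination scoring


def _cox_design(panel: StandardizedPanel, subjects: list[Subject],
                outcomes: list[SurvivalOutcome],
                markers: tuple[Marker, ...],
                covariates: tuple[str, ...]) -> tuple[pd.DataFrame, list[str]]:
    by_id = {s.subject_id: s for s in subjects}
    rows = {}
    for o in outcomes:
        if o.excluded or o.time is None:
            continue
        s = by_id[o.subject_id]
        row = {"time": o.time, "event": float(o.event)}
        for cov in covariates:
            if cov == "age":
                row["age"] = s.age_at_sampling
            elif cov == "sex":
                row["male"] = 1.0 if s.sex == "M" else 0.0
            elif cov == "dmt_ever":
                row["dmt_ever"] = 1.0 if s.dmt_ever else 0.0
            else:
                raise ValueError(f"unknown covariate {cov!r}")
        rows[o.subject_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    cov_cols = [c for c in frame.columns if c not in ("time", "event")]
    for m in markers:
        frame[f"{m[1]}[{m[0]}]"] = panel.features[m].reindex(frame.index)
    return frame.dropna(), cov_cols


def evaluate_combination_cox(spec: ModelSpec, panel: StandardizedPanel,
                             subjects: list[Subject],
                             outcomes: list[SurvivalOutcome],
                             folds: FoldAssignment,
                             apparent: bool = False) -> CombinationScore:
    """Score one marker set by cross-validated test-fold concordance.

    Per fold, a Cox model (markers + forced covariates) is fitted on
    the train folds and its linear predictor is scored by Harrell's C
    on both the train and the held-out fold.  With ``apparent=True``
    the whole-data concordance is reported instead (no
    cross-validation), for comparison with apparent statistics.
    A fold without events, or an unfittable fold, invalidates the
    score.
    """
    frame, cov_cols = _cox_design(panel, subjects, outcomes, spec.markers,
                                  spec.covariates)
    marker_cols = [f"{m[1]}[{m[0]}]" for m in spec.markers]
    cols = marker_cols + cov_cols
    warnings: list[str] = []
    if apparent:
        try:
            res = fit_cox(frame, marker_cols, cov_cols)
            return CombinationScore(spec, [res.concordance], [res.concordance],
                                    n_complete=len(frame))
        except ValueError as exc:
            return CombinationScore(spec, [], [], n_complete=len(frame),
                                    fit_warnings=[str(exc)], valid=False)
    train_cs, test_cs = [], []
    valid = True
    for f in range(1, folds.k + 1):
        in_fold = frame.index.to_series().map(folds.fold_of) == f
        train, test = frame[~in_fold], frame[in_fold]
        try:
            if train["event"].sum() == 0 or test["event"].sum() == 0:
                raise ValueError("fold without events")
            fitter = _cox_fit(train, cols)
            beta = fitter.params_.reindex(cols).to_numpy()
            train_cs.append(harrell_c(train[cols].to_numpy() @ beta,
                                      train["time"].to_numpy(),
                                      train["event"].to_numpy().astype(bool)))
            test_cs.append(harrell_c(test[cols].to_numpy() @ beta,
                                     test["time"].to_numpy(),
                                     test["event"].to_numpy().astype(bool)))
        except (ValueError, ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.append(f"fold {f}: {exc}")
            valid = False
    return CombinationScore(spec=spec, per_fold_train=train_cs,
                            per_fold_test=test_cs, n_complete=len(frame),
                            fit_warnings=warnings, valid=valid)


def search_prognostic(candidates: list[Marker], panel: StandardizedPanel,
                      subjects: list[Subject], outcomes: list[SurvivalOutcome],
                      folds: FoldAssignment, *,
                      strategy: str = "greedy_forward", max_size: int = 8,
                      covariates: tuple[str, ...] | None = None,
                      outcome_name: str = RELAPSE) -> SearchReport:
    """Concordance-objective combination search.

    Age and sex are forced into every model; the EDSS-6 outcome
    additionally forces ever-DMT exposure.
    """
    if covariates is None:
        covariates = ("age", "sex", "dmt_ever") if outcome_name == EDSS6 \
            else ("age", "sex")
    return search_combinations(
        candidates,
        lambda spec: evaluate_combination_cox(spec, panel, subjects,
                                              outcomes, folds),
        strategy=strategy, max_size=max_size, covariates=covariates,
        objective="CONCORDANCE")


def refit_full_cox(spec: ModelSpec, panel: StandardizedPanel,
                   subjects: list[Subject],
                   outcomes: list[SurvivalOutcome]) -> CoxResult:
    frame, cov_cols = _cox_design(panel, subjects, outcomes, spec.markers,
                                  spec.covariates)
    marker_cols = [f"{m[1]}[{m[0]}]" for m in spec.markers]
    return fit_cox(frame, marker_cols, cov_cols)
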