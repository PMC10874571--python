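"""Model/Results front end over the panel-search machinery.

`DiagnosticPanelModel` and `PrognosticPanelModel` are built from a
standardized panel plus subject records; `fit()` runs the
cross-validated combination search with the delta stopping rule and
returns a Results object carrying the selected panel, its
cross-validated performance, full-data refit coefficients with
standard errors, and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._search import Marker, ModelSpec, SearchReport, select_optimum
from .cohort import Subject
from .diagnostic import (FoldAssignment, LogisticScorer, StabilityResult,
                         make_folds, refit_full, search_diagnostic,
                         stability_reruns)
from .preprocess import StandardizedPanel
from .prognostic import (EDSS6, RELAPSE, CoxResult, SurvivalOutcome,
                         derive_outcomes, refit_full_cox, search_prognostic)


def _search_frame(report: SearchReport) -> pd.DataFrame:
    rows = []
    for s in report.scores:
        rows.append({
            "markers": s.spec.label(), "size": s.spec.size,
            "n_complete": s.n_complete,
            **{f"train_fold{i + 1}": v for i, v in enumerate(s.per_fold_train)},
            **{f"test_fold{i + 1}": v for i, v in enumerate(s.per_fold_test)},
            "mean_train": s.mean_train, "mean_test": s.mean_test,
            "valid": s.valid,
            "warnings": "; ".join(s.fit_warnings),
        })
    return pd.DataFrame(rows).sort_values(
        ["valid", "mean_test"], ascending=[False, True]).reset_index(drop=True)


def _trace_lines(report: SearchReport, metric: str) -> list[str]:
    lines = [f"{'size':>4}  {'best mean test ' + metric:>22}  {'gain':>8}"]
    for size, best, gain in report.selection_trace:
        gain_s = f"{gain:8.4f}" if np.isfinite(gain) else "     ---"
        lines.append(f"{size:>4}  {best:>22.4f}  {gain_s}")
    return lines


class DiagnosticPanelModel:
    """MS-vs-control panel selection by cross-validated AUC.

    Parameters
    ----------
    panel : StandardizedPanel
        Z-scored feature matrix from the preprocessing pipeline.
    subjects : list of Subject
        Cohort records supplying group labels plus the forced age/sex
        covariates.
    candidates : list of (analyte, compartment), optional
        Candidate pool; defaults to every marker in the panel.
    """

    def __init__(self, panel: StandardizedPanel, subjects: list[Subject],
                 candidates: list[Marker] | None = None):
        self.panel = panel
        self.subjects = subjects
        self.candidates = list(candidates) if candidates else panel.markers()

    def fit(self, *, k: int = 4, seed: int = 0,
            strategy: str = "per_size_exhaustive", max_size: int = 8,
            delta: float = 0.01,
            folds: FoldAssignment | None = None) -> "DiagnosticPanelResults":
        if folds is None:
            folds = make_folds(self.subjects, k=k, seed=seed)
        report = search_diagnostic(self.candidates, self.panel, self.subjects,
                                   folds, strategy=strategy, max_size=max_size)
        selected = select_optimum(report, delta=delta)
        scorer, frame = refit_full(selected, self.panel, self.subjects)
        return DiagnosticPanelResults(model=self, folds=folds, report=report,
                                      selected=selected, scorer=scorer,
                                      delta=delta)


@dataclass
class DiagnosticPanelResults:
    model: DiagnosticPanelModel
    folds: FoldAssignment
    report: SearchReport
    selected: ModelSpec
    scorer: LogisticScorer
    delta: float

    @property
    def best(self):
        return self.report.best_score()

    @property
    def cv_test_auc(self) -> float:
        return self.best.mean_test

    @property
    def cv_train_auc(self) -> float:
        return self.best.mean_train

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.scorer.params())

    @property
    def bse(self) -> pd.Series:
        return pd.Series(dict(zip(["intercept"] + self.scorer.columns,
                                  self.scorer.se)))

    def search_frame(self) -> pd.DataFrame:
        return _search_frame(self.report)

    def stability(self, n_reps: int = 1000, train_frac: float = 0.75,
                  seed: int = 0) -> StabilityResult:
        return stability_reruns(self.selected, self.model.panel,
                                self.model.subjects, n_reps=n_reps,
                                train_frac=train_frac, seed=seed)

    def summary(self) -> str:
        best = self.best
        lines = [
            "Diagnostic panel selection (cross-validated AUC)",
            "=" * 58,
            f"Selected panel : {self.selected.label()}",
            f"Complete cases : {best.n_complete}",
            f"Mean train AUC : {best.mean_train:.3f}",
            f"Mean test AUC  : {best.mean_test:.3f}",
            f"Folds          : k={self.folds.k}, seed={self.folds.seed}, "
            f"stratified by {self.folds.stratified_by}",
            f"Stopping rule  : delta={self.delta}",
            "",
            "Selection trace:",
            *_trace_lines(self.report, "AUC"),
            "",
            "Full-data refit (log-odds scale):",
            f"{'term':>24}  {'coef':>9}  {'se':>8}",
        ]
        for term, coef, se in zip(["intercept"] + self.scorer.columns,
                                  self.scorer.coef, self.scorer.se):
            lines.append(f"{term:>24}  {coef:>9.3f}  {se:>8.3f}")
        if self.scorer.ridged:
            lines.append("note: ridge fallback used (quasi-separation)")
        return "\n".join(lines)


class PrognosticPanelModel:
    """Time-to-event panel selection by cross-validated concordance.

    ``outcome`` is "relapse" (time to next relapse, DMT-censored) or
    "edss6" (time to sustained EDSS 6, ever-DMT forced as covariate).
    """

    def __init__(self, panel: StandardizedPanel, subjects: list[Subject],
                 outcome: str = RELAPSE,
                 candidates: list[Marker] | None = None,
                 sustain_years: float = 0.5,
                 relapse_window_days: float = 30.0):
        if outcome not in (RELAPSE, EDSS6):
            raise ValueError(f"unknown outcome {outcome!r}")
        self.panel = panel
        self.subjects = subjects
        self.outcome = outcome
        self.candidates = list(candidates) if candidates else panel.markers()
        self.outcomes: list[SurvivalOutcome] = derive_outcomes(
            subjects, outcome, sustain_years, relapse_window_days)

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.outcomes])

    def fit(self, *, k: int = 4, seed: int = 0,
            strategy: str = "greedy_forward", max_size: int = 8,
            delta: float = 0.01,
            folds: FoldAssignment | None = None) -> "PrognosticPanelResults":
        if folds is None:
            ms = [s for s in self.subjects if s.is_ms]
            folds = make_folds(ms, k=k, seed=seed, stratify="none")
        report = search_prognostic(self.candidates, self.panel, self.subjects,
                                   self.outcomes, folds, strategy=strategy,
                                   max_size=max_size,
                                   outcome_name=self.outcome)
        selected = select_optimum(report, delta=delta)
        cox = refit_full_cox(selected, self.panel, self.subjects, self.outcomes)
        return PrognosticPanelResults(model=self, folds=folds, report=report,
                                      selected=selected, cox=cox, delta=delta)


@dataclass
class PrognosticPanelResults:
    model: PrognosticPanelModel
    folds: FoldAssignment
    report: SearchReport
    selected: ModelSpec
    cox: CoxResult
    delta: float

    @property
    def best(self):
        return self.report.best_score()

    @property
    def cv_test_concordance(self) -> float:
        return self.best.mean_test

    @property
    def params(self) -> pd.Series:
        return pd.Series({t: b for t, (b, _) in self.cox.coefficients.items()})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({t: s for t, (_, s) in self.cox.coefficients.items()})

    def search_frame(self) -> pd.DataFrame:
        return _search_frame(self.report)

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.model.outcomes])

    def summary(self) -> str:
        best = self.best
        lines = [
            f"Prognostic panel selection ({self.model.outcome}, "
            "cross-validated concordance)",
            "=" * 58,
            f"Selected panel       : {self.selected.label()}",
            f"Complete cases       : {best.n_complete}",
            f"Events (full refit)  : {self.cox.n_events} / {self.cox.n}",
            f"Mean test concordance: {best.mean_test:.3f}",
            f"Full-data concordance: {self.cox.concordance:.3f}",
            f"LR p vs covariates   : {self.cox.lr_p:.3g}",
            f"Stopping rule        : delta={self.delta}",
            "",
            "Selection trace:",
            *_trace_lines(self.report, "C"),
            "",
            "Full-data Cox refit (log-hazard scale):",
            f"{'term':>24}  {'coef':>9}  {'se':>8}",
        ]
        for term, (beta, se) in self.cox.coefficients.items():
            lines.append(f"{term:>24}  {beta:>9.3f}  {se:>8.3f}")
        return "\n".join(lines)
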