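"""Diagnostic panel modelling: logistic scoring, ROC/AUC, the 4-fold
cross-validated combination search and the stability resampling.

Every candidate model is a logistic regression of MS status on the
panel Z-scores with age and sex always included as covariates.  Models
are compared by mean test AUC over a stratified k-fold partition
(default k=4); panel growth stops when the best model one size larger
gains less than delta=0.01 mean test AUC.  Reliability is probed by
re-fitting the selected panel on many random stratified train/test
splits (default 1000 at 75% train).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._search import (CombinationScore, Marker, ModelSpec, SearchReport,
                      search_combinations, select_optimum)
from .cohort import Subject
from .preprocess import StandardizedPanel

__all__ = ["FoldAssignment", "make_folds", "LogisticScorer", "fit_logistic",
           "roc_auc", "evaluate_combination", "search_diagnostic",
           "select_optimum", "stability_reruns", "StabilityResult",
           "ModelSpec", "CombinationScore", "SearchReport"]


# ---------------------------------------------------------------------------
# Fold assignment


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]          # subject_id -> fold in {1..k}
    k: int
    seed: int
    stratified_by: str               # "group" | "none"

    def test_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f != fold]


def make_folds(subjects: list[Subject], k: int = 4, seed: int = 0,
               stratify: str = "group") -> FoldAssignment:
    """Randomly partition subjects into k roughly equal folds.

    Stratified by MS/control status by default so every fold carries a
    near-proportional share of each group.  Deterministic under seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if stratify not in ("group", "none"):
        raise ValueError(f"unknown stratification {stratify!r}")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for s in subjects:
        key = s.group if stratify == "group" else "all"
        strata.setdefault(key, []).append(s.subject_id)

    fold_of: dict[str, int] = {}
    for key in sorted(strata):
        ids = sorted(strata[key])
        if len(ids) < k:
            raise ValueError(f"stratum {key!r} has {len(ids)} subjects < k={k}")
        rng.shuffle(ids)
        folds = np.array_split(ids, k)
        for f, chunk in enumerate(folds, start=1):
            for sid in chunk:
                fold_of[sid] = f
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed, stratified_by=stratify)


# ---------------------------------------------------------------------------
# Logistic scorer (IRLS with ridge fallback on separation)


@dataclass
class LogisticScorer:
    """Fitted logistic model: coefficients, SEs and a probability scorer."""

    coef: np.ndarray                 # intercept first
    se: np.ndarray
    columns: list[str]
    converged: bool
    ridged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X1 = np.column_stack([np.ones(len(X)), X])
        return X1 @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def params(self) -> dict[str, float]:
        return dict(zip(["intercept"] + self.columns, self.coef))


def _irls(X1: np.ndarray, y: np.ndarray, ridge: float, tol: float,
          max_iter: int) -> tuple[np.ndarray, bool, int]:
    n, p = X1.shape
    beta = np.zeros(p)
    penalty = np.zeros((p, p))
    if ridge > 0:
        penalty = ridge * np.eye(p)
        penalty[0, 0] = 0.0          # intercept unpenalised
    for it in range(1, max_iter + 1):
        eta = np.clip(X1 @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X1.T @ (y - mu) - penalty @ beta
        hess = (X1 * w[:, None]).T @ X1 + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False, it
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True, it
    return beta, False, max_iter


def fit_logistic(X: np.ndarray, y: np.ndarray, columns: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 100,
                 ridge_fallback: float = 1e-4) -> LogisticScorer:
    """Maximum-likelihood logistic fit via IRLS.

    On quasi-separation (non-convergence or runaway coefficients) the
    fit falls back to a small ridge penalty (lambda=1e-4 by default,
    intercept unpenalised) and records a warning instead of failing:
    small CV folds with strong markers separate routinely and a
    finite scorer is still well-defined there.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("labels must be 0/1")
    columns = columns or [f"x{j}" for j in range(X.shape[1])]
    X1 = np.column_stack([np.ones(len(X)), X])

    beta, converged, n_iter = _irls(X1, y, 0.0, tol, max_iter)
    warnings: list[str] = []
    ridged = False
    if not converged or np.max(np.abs(beta)) > 30:
        beta, converged, n_iter = _irls(X1, y, ridge_fallback, tol, max_iter)
        ridged = True
        warnings.append(f"quasi-separation: refit with ridge lambda={ridge_fallback}")

    eta = np.clip(X1 @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X1 * w[:, None]).T @ X1
    if ridged:
        pen = ridge_fallback * np.eye(X1.shape[1])
        pen[0, 0] = 0.0
        info = info + pen
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X1.shape[1], np.nan)
    return LogisticScorer(coef=beta, se=se, columns=list(columns),
                          converged=converged, ridged=ridged, n_iter=n_iter,
                          warnings=warnings)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: P(score_case > score_control) + ties/2."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # midrank formula for the hot search loop; equals roc_auc (tested)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Cross-validated combination scoring


def _design(panel: StandardizedPanel, subjects: list[Subject],
            markers: tuple[Marker, ...],
            covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Complete-case design frame: marker Zs + covariates + label."""
    cols = {}
    if "age" in covariates:
        cols["age"] = [s.age_at_sampling for s in subjects]
    if "sex" in covariates:
        cols["male"] = [1.0 if s.sex == "M" else 0.0 for s in subjects]
    cols["label"] = [1.0 if s.is_ms else 0.0 for s in subjects]
    frame = pd.DataFrame(cols, index=[s.subject_id for s in subjects])
    for m in markers:
        frame[f"{m[1]}[{m[0]}]"] = panel.features[m].reindex(frame.index)
    return frame.dropna()


class _DesignCache:
    """Precomputed arrays shared across the many fits of one search."""

    def __init__(self, panel: StandardizedPanel, subjects: list[Subject],
                 folds: FoldAssignment):
        ids = [s.subject_id for s in subjects]
        feats = panel.features.reindex(ids)
        self.marker_index = {m: j for j, m in enumerate(feats.columns)}
        self.Z = feats.to_numpy(dtype=float)
        self.age = np.array([s.age_at_sampling for s in subjects], dtype=float)
        self.male = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])
        self.label = np.array([1.0 if s.is_ms else 0.0 for s in subjects])
        self.fold = np.array([folds.fold_of.get(sid, -1) for sid in ids])
        self.k = folds.k

    def evaluate(self, spec: ModelSpec) -> CombinationScore:
        cols = [self.marker_index[m] for m in spec.markers]
        sub = self.Z[:, cols]
        complete = ~np.isnan(sub).any(axis=1)
        parts, names = [sub], [f"{m[1]}[{m[0]}]" for m in spec.markers]
        for cov in spec.covariates:
            if cov == "age":
                parts.append(self.age[:, None])
                names.append("age")
            elif cov == "sex":
                parts.append(self.male[:, None])
                names.append("male")
            else:
                raise ValueError(f"unknown covariate {cov!r}")
        X = np.column_stack(parts) if names else np.empty((len(sub), 0))
        warnings: list[str] = []
        train_aucs, test_aucs = [], []
        valid = True
        for f in range(1, self.k + 1):
            tr = complete & (self.fold != f) & (self.fold > 0)
            te = complete & (self.fold == f)
            try:
                scorer = fit_logistic(X[tr], self.label[tr], columns=names)
                warnings.extend(f"fold {f}: {w}" for w in scorer.warnings)
                train_aucs.append(_rank_auc(scorer.linear_predictor(X[tr]),
                                            self.label[tr]))
                test_aucs.append(_rank_auc(scorer.linear_predictor(X[te]),
                                           self.label[te]))
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.append(f"fold {f}: {exc}")
                valid = False
        return CombinationScore(spec=spec, per_fold_train=train_aucs,
                                per_fold_test=test_aucs,
                                n_complete=int((complete & (self.fold > 0)).sum()),
                                fit_warnings=warnings, valid=valid)


def evaluate_combination(spec: ModelSpec, panel: StandardizedPanel,
                         subjects: list[Subject],
                         folds: FoldAssignment) -> CombinationScore:
    """Score one marker set by k-fold cross-validated train/test AUC.

    Complete cases only (subjects with every marker in the set
    non-missing); per fold, the model is fitted on the other k-1 folds
    and AUC is computed on both the fitting set and the held-out fold.
    A fold whose training set cannot be fitted, or whose test set lacks
    one class, invalidates the score.
    """
    return _DesignCache(panel, subjects, folds).evaluate(spec)


def search_diagnostic(candidates: list[Marker], panel: StandardizedPanel,
                      subjects: list[Subject], folds: FoldAssignment, *,
                      strategy: str = "per_size_exhaustive",
                      max_size: int = 8) -> SearchReport:
    """Run the combination search with the diagnostic AUC objective."""
    cache = _DesignCache(panel, subjects, folds)
    return search_combinations(candidates, cache.evaluate, strategy=strategy,
                               max_size=max_size, objective="AUC")


def refit_full(spec: ModelSpec, panel: StandardizedPanel,
               subjects: list[Subject]) -> tuple[LogisticScorer, pd.DataFrame]:
    """Refit the selected model on all complete cases (for reporting)."""
    frame = _design(panel, subjects, spec.markers, spec.covariates)
    feature_cols = [c for c in frame.columns if c != "label"]
    scorer = fit_logistic(frame[feature_cols].to_numpy(),
                          frame["label"].to_numpy(), columns=feature_cols)
    return scorer, frame


# ---------------------------------------------------------------------------
# Stability resampling


@dataclass
class StabilityResult:
    train_aucs: np.ndarray           # train data scored as test
    test_aucs: np.ndarray
    n_skipped: int
    train_frac: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vals in (("train", self.train_aucs), ("test", self.test_aucs)):
            rows.append({
                "set": name, "n_reps": len(vals),
                "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
                "p2.5": float(np.percentile(vals, 2.5)),
                "p50": float(np.percentile(vals, 50)),
                "p97.5": float(np.percentile(vals, 97.5)),
            })
        return pd.DataFrame(rows)


def stability_reruns(spec: ModelSpec, panel: StandardizedPanel,
                     subjects: list[Subject], n_reps: int = 1000,
                     train_frac: float = 0.75, seed: int = 0) -> StabilityResult:
    """Re-fit a fixed panel on many random stratified train/test splits.

    Each rep draws a stratified split at ``train_frac`` (default 0.75),
    fits on the train part, and records the AUC on the train part
    (train used as test) and on the held-out part.  Degenerate reps
    (a part missing one class, or an unfittable train set) are skipped
    and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    frame = _design(panel, subjects, spec.markers, spec.covariates)
    feature_cols = [c for c in frame.columns if c != "label"]
    X = frame[feature_cols].to_numpy()
    y = frame["label"].to_numpy()
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)

    train_aucs, test_aucs = [], []
    n_skipped = 0
    for _ in range(n_reps):
        tr = np.concatenate([
            rng.choice(idx_pos, size=int(round(train_frac * len(idx_pos))),
                       replace=False),
            rng.choice(idx_neg, size=int(round(train_frac * len(idx_neg))),
                       replace=False)])
        mask = np.zeros(len(y), dtype=bool)
        mask[tr] = True
        try:
            scorer = fit_logistic(X[mask], y[mask], columns=feature_cols)
            train_aucs.append(_rank_auc(scorer.linear_predictor(X[mask]), y[mask]))
            test_aucs.append(_rank_auc(scorer.linear_predictor(X[~mask]), y[~mask]))
        except (ValueError, np.linalg.LinAlgError):
            n_skipped += 1
    return StabilityResult(train_aucs=np.asarray(train_aucs),
                           test_aucs=np.asarray(test_aucs),
                           n_skipped=n_skipped, train_frac=train_frac)
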