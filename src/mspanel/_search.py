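"""Shared combination-search machinery.

Both the diagnostic (AUC) and prognostic (concordance) searches
enumerate candidate marker subsets, score each by a cross-validated
test metric supplied by the caller, keep the best model of each size,
and stop growing the panel when the best model one size larger improves
the mean test metric by less than a configured delta (default 0.01).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

Marker = tuple[str, str]

STRATEGIES = ("exhaustive", "per_size_exhaustive", "greedy_forward")
MAX_EXHAUSTIVE_SUBSETS = 2 ** 22


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an ordered marker set plus forced covariates."""

    markers: tuple[Marker, ...]
    covariates: tuple[str, ...] = ("age", "sex")
    objective: str = "AUC"            # AUC | CONCORDANCE

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in model spec")

    @property
    def size(self) -> int:
        return len(self.markers)

    def label(self) -> str:
        if not self.markers:
            return "(covariates only)"
        return " + ".join(f"{c}[{a}]" for a, c in self.markers)


@dataclass
class CombinationScore:
    spec: ModelSpec
    per_fold_train: list[float]
    per_fold_test: list[float]
    n_complete: int
    fit_warnings: list[str] = field(default_factory=list)
    valid: bool = True

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.per_fold_train)) if self.per_fold_train else np.nan

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.per_fold_test)) if self.per_fold_test else np.nan


def _sort_key(score: CombinationScore):
    # higher mean test metric wins; ties -> smaller model, then lexicographic
    return (-score.mean_test, score.spec.size, score.spec.markers)


@dataclass
class SearchReport:
    scores: list[CombinationScore]
    best_by_size: dict[int, CombinationScore]
    selected: ModelSpec | None = None
    selection_trace: list[tuple[int, float, float]] = field(default_factory=list)

    def ranking(self) -> list[CombinationScore]:
        """All valid scores ordered from lowest to highest mean test metric."""
        return sorted((s for s in self.scores if s.valid),
                      key=_sort_key, reverse=True)

    def best_score(self) -> CombinationScore:
        if self.selected is None:
            raise RuntimeError("run select_optimum first")
        return self.best_by_size[self.selected.size]


def search_combinations(candidates: list[Marker], evaluate, *,
                        strategy: str = "per_size_exhaustive",
                        max_size: int = 8,
                        covariates: tuple[str, ...] = ("age", "sex"),
                        objective: str = "AUC") -> SearchReport:
    """Enumerate and score marker subsets.

    ``evaluate`` maps a ModelSpec to a CombinationScore.  Strategies:
    ``exhaustive`` (every subset; refused beyond 2^22), ``per_size_exhaustive``
    (every subset of each size up to ``max_size``) and ``greedy_forward``
    (forward stepwise: grow the best panel one marker at a time).
    Deterministic given deterministic folds; ties break toward smaller
    models, then lexicographic marker names.
    """
    if not candidates:
        raise ValueError("candidate pool is empty")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    max_size = min(max_size, len(candidates))
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    candidates = sorted(candidates)

    def make_spec(markers) -> ModelSpec:
        return ModelSpec(tuple(sorted(markers)), covariates, objective)

    scores: list[CombinationScore] = []
    best_by_size: dict[int, CombinationScore] = {}

    def record(score: CombinationScore) -> None:
        scores.append(score)
        if not score.valid or not np.isfinite(score.mean_test):
            return
        size = score.spec.size
        cur = best_by_size.get(size)
        if cur is None or _sort_key(score) < _sort_key(cur):
            best_by_size[size] = score

    if strategy == "exhaustive":
        if 2 ** len(candidates) > MAX_EXHAUSTIVE_SUBSETS:
            raise ValueError(
                f"exhaustive search over {len(candidates)} candidates exceeds "
                f"2^22 subsets; use per_size_exhaustive or greedy_forward")
        max_size = len(candidates)

    if strategy in ("exhaustive", "per_size_exhaustive"):
        for size in range(1, max_size + 1):
            for markers in itertools.combinations(candidates, size):
                record(evaluate(make_spec(markers)))
    else:  # greedy_forward
        current: tuple[Marker, ...] = ()
        for _ in range(max_size):
            step = [evaluate(make_spec(current + (m,)))
                    for m in candidates if m not in current]
            valid = [s for s in step if s.valid and np.isfinite(s.mean_test)]
            for s in step:
                record(s)
            if not valid:
                break
            current = min(valid, key=_sort_key).spec.markers

    return SearchReport(scores=scores, best_by_size=best_by_size)


def select_optimum(report: SearchReport, delta: float = 0.01) -> ModelSpec:
    """Apply the stopping rule: grow the panel while the best model one
    size larger gains at least ``delta`` on the mean test metric.

    Walks sizes from the smallest evaluated; stops at the first size s
    where the size-(s+1) best improves by less than delta (or at the
    largest size evaluated).  Records the full trace on the report.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not report.best_by_size:
        raise ValueError("no valid combinations to select from")
    sizes = sorted(report.best_by_size)
    trace: list[tuple[int, float, float]] = []
    chosen = sizes[0]
    for s in sizes:
        best = report.best_by_size[s]
        nxt = report.best_by_size.get(s + 1)
        gain = (nxt.mean_test - best.mean_test) if nxt is not None else np.nan
        trace.append((s, best.mean_test, gain))
        chosen = s
        if nxt is None or gain < delta:
            break
    report.selected = report.best_by_size[chosen].spec
    report.selection_trace = trace
    return report.selected
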