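"""Plain plotting helpers for the fitted panel models.

Matplotlib-only convenience wrappers: a violin of predicted MS
probability by group with an ROC curve for the diagnostic model, a
stability-AUC histogram, and a risk-versus-time scatter for the
prognostic model.  All return the Axes so callers can restyle.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from sklearn.metrics import roc_curve  # noqa: E402


def plot_diagnostic(results, ax=None):
    """Violin of predicted probability by group plus the ROC curve."""
    from .diagnostic import _design
    frame = _design(results.model.panel, results.model.subjects,
                    results.selected.markers)
    feature_cols = [c for c in frame.columns if c != "label"]
    proba = results.scorer.predict_proba(frame[feature_cols].to_numpy())
    y = frame["label"].to_numpy()
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 4))
    ax[0].violinplot([proba[y == 0], proba[y == 1]], showmedians=True)
    ax[0].set_xticks([1, 2], ["control", "MS"])
    ax[0].set_ylabel("predicted P(MS)")
    fpr, tpr, _ = roc_curve(y, proba)
    ax[1].plot(fpr, tpr)
    ax[1].plot([0, 1], [0, 1], ls="--", color="grey")
    ax[1].set_xlabel("false positive rate")
    ax[1].set_ylabel("true positive rate")
    ax[1].set_title(f"mean test AUC {results.cv_test_auc:.2f}")
    return ax


def plot_stability(stability, ax=None):
    """Histograms of train-as-test and test AUC over the reruns."""
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for a, vals, title in zip(ax, (stability.train_aucs, stability.test_aucs),
                              ("train data as test", "test data")):
        a.hist(vals, bins=30)
        a.set_title(title)
        a.set_xlabel("AUC")
    return ax


def plot_risk_vs_time(results, ax=None):
    """Linear risk predictor against observed time, events filled."""
    from .prognostic import _cox_design
    frame, cov_cols = _cox_design(results.model.panel, results.model.subjects,
                                  results.model.outcomes,
                                  results.selected.markers,
                                  results.selected.covariates)
    cols = [f"{m[1]}[{m[0]}]" for m in results.selected.markers] + cov_cols
    beta = np.array([results.cox.beta(c) for c in cols])
    lp = frame[cols].to_numpy() @ beta
    event = frame["event"].to_numpy().astype(bool)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(frame["time"][event], lp[event], marker="o", label="event")
    ax.scatter(frame["time"][~event], lp[~event], marker="x", label="censored")
    ax.set_xlabel("time (years)")
    ax.set_ylabel("linear risk predictor")
    ax.legend()
    return ax
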