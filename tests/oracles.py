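"""Independent brute-force oracles used to pin expected values.

Each function is a deliberately naive reimplementation (enumeration or
pair counting) kept free of any code path it is used to check.
"""

from itertools import combinations

import numpy as np


def auc_pair_counting(scores, labels):
    """AUC by direct (case, control) pair counting, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def mann_whitney_exact(x, y):
    """Exact two-sided Mann-Whitney test by labeling enumeration.

    Enumerates every assignment of the pooled (tie-free) sample into a
    group of size len(x); p is the fraction of assignments whose U is
    at least as extreme (two-sided, about the null mean n_x*n_y/2).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    nx, ny = len(x), len(y)

    def u_of(group_x):
        rest = [v for v in pooled if v not in group_x]
        return sum(1.0 for a in group_x for b in rest if a > b)

    u_obs = u_of(x)
    centre = nx * ny / 2.0
    extreme = 0
    total = 0
    for combo in combinations(pooled, nx):
        total += 1
        if abs(u_of(combo) - centre) >= abs(u_obs - centre) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def bh_step_up(p_values):
    """Hand application of the Benjamini-Hochberg step-up formula."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def concordance_pairs(risk, times, events):
    """Harrell's C by explicit double loop over subject pairs."""
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if not events[i] or times[j] <= times[i]:
                continue
            den += 1.0
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
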