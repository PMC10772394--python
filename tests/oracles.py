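"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle re-derives a quantity from first principles, by exhaustive
enumeration or a literal transcription of the defining formula, and never
calls the implementation it checks.
"""

import itertools

import numpy as np


def naive_complete_linkage(d: np.ndarray):
    """O(n^3) agglomeration: repeatedly merge the pair of clusters with the
    smallest maximum pairwise distance (ties: lowest cluster indices first).

    Returns a list of (frozenset of leaf ids, merge height), in merge order.
    """
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = max(d[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        merges.append((merged, h))
    return merges


def linkage_to_merges(Z: np.ndarray):
    """Canonical (frozenset, height) merge list from a scipy linkage matrix."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _s) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append((merged, float(h)))
    return merges


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: sort ascending, q_i = p_i * m / i, enforce
    monotone non-increasing from the largest p downward, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return np.minimum(q, 1.0)


def km_hand(times, events):
    """Literal product-limit: S(t) = prod_{u <= t, event time} (1 - d_u/n_u).

    Returns (unique event/censor times ascending, survival at each).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    grid = np.unique(t)
    s = 1.0
    out = []
    for u in grid:
        n_at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        if d > 0:
            s *= 1.0 - d / n_at_risk
        out.append(s)
    return grid, np.array(out)


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood (equals Efron's when event times are
    unique): sum over events of b*x_i - log(sum_{j in risk set} exp(b*x_j))."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_coef(times, events, x, lo=-8.0, hi=8.0):
    """1-D grid maximization of the partial likelihood, refined twice."""
    grid = np.linspace(lo, hi, 2001)
    for _ in range(3):
        ll = np.array([cox_partial_loglik(b, times, events, x) for b in grid])
        best = grid[np.argmax(ll)]
        width = grid[1] - grid[0]
        grid = np.linspace(best - 2 * width, best + 2 * width, 2001)
    return float(best)


def youden_bruteforce(values, labels):
    """Exhaustive (cut, J) over all midpoint thresholds, explicit loops."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    distinct = np.unique(v)
    candidates = [-np.inf]
    for a, b in zip(distinct[:-1], distinct[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(np.inf)
    best = None
    for c in candidates:
        tp = int(((v >= c) & (y == 1)).sum())
        fn = int(((v < c) & (y == 1)).sum())
        tn = int(((v < c) & (y == 0)).sum())
        fp = int(((v >= c) & (y == 0)).sum())
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if best is None or j > best[1] + 1e-15:
            best = (c, j)
    return float(best[0]), float(best[1])


def bernoulli_loglik(p, k, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = k * np.log(p) + (n - k) * np.log(1 - p)
    return np.where(np.isnan(ll), -np.inf, ll)


def logistic_group_lr(k1, n1, k0, n0):
    """LR statistic for a binary covariate in logistic regression, from the
    closed-form group MLEs (the brute-force grid limit)."""
    def ll(k, n):
        if k in (0, n):
            return 0.0 if k == 0 or k == n else None
        p = k / n
        return k * np.log(p) + (n - k) * np.log(1 - p)

    full = ll(k1, n1) + ll(k0, n0)
    k, n = k1 + k0, n1 + n0
    red = ll(k, n)
    return 2.0 * (full - red)
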