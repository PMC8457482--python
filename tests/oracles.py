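"""Independent brute-force oracles used by both unit and acceptance tests.

Everything here is deliberately naive — O(n^2) scans, exhaustive enumeration,
plain double loops — so it shares no code path with the implementation it
checks.
"""

from itertools import combinations

import numpy as np


def brute_force_distance(feature_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs minimum centre-to-centre distance to a feature cell."""
    rows, cols = np.nonzero(feature_mask)
    out = np.empty(feature_mask.shape)
    for i in range(feature_mask.shape[0]):
        for j in range(feature_mask.shape[1]):
            d2 = (rows - i) ** 2 + (cols - j) ** 2
            out[i, j] = cell_size * np.sqrt(d2.min())
    return out


def naive_use_avail_loglik(beta, X_used, X_avail) -> float:
    """Two-loop evaluation of the use-availability log-likelihood."""
    def w(x):
        eta = beta[0] + sum(b * v for b, v in zip(beta[1:], x[1:]))
        return 1.0 / (1.0 + np.exp(-eta))

    denom = sum(w(x) for x in X_avail) / len(X_avail)
    return float(sum(np.log(w(x)) - np.log(denom) for x in X_used))


def pair_counting_auc(scores, labels) -> float:
    """AUC as the fraction of concordant (used, available) pairs, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def max_independent_set_size(xy: np.ndarray, min_distance: float) -> int:
    """Exhaustive maximum independent set of the < min_distance proximity graph."""
    n = len(xy)
    close = np.zeros((n, n), dtype=bool)
    for a, b in combinations(range(n), 2):
        if np.hypot(*(xy[a] - xy[b])) < min_distance:
            close[a, b] = close[b, a] = True
    best = 0
    for mask in range(2 ** n):
        members = [i for i in range(n) if mask >> i & 1]
        if len(members) <= best:
            continue
        if all(not close[a, b] for a, b in combinations(members, 2)):
            best = len(members)
    return best


def grid_search_mle(X_used, X_avail, b0_range, b1_range, n_grid=200):
    """Dense grid maximiser of the use-availability likelihood (2 parameters)."""
    b0s = np.linspace(*b0_range, n_grid)
    b1s = np.linspace(*b1_range, n_grid)
    best, arg = -np.inf, (None, None)
    xu = X_used[:, 1]
    xa = X_avail[:, 1]
    for b0 in b0s:
        eta_u = b0 + np.outer(b1s, xu)
        eta_a = b0 + np.outer(b1s, xa)
        wu = 1.0 / (1.0 + np.exp(-eta_u))
        wa = 1.0 / (1.0 + np.exp(-eta_a))
        ll = np.log(wu).sum(axis=1) - len(xu) * np.log(wa.mean(axis=1))
        j = int(np.argmax(ll))
        if ll[j] > best:
            best, arg = ll[j], (b0, b1s[j])
    steps = (b0s[1] - b0s[0], b1s[1] - b1s[0])
    return arg, steps, best
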