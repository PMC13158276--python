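"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives a quantity by exhaustive enumeration or a closed
form, deliberately sharing no code with the implementation it checks.
"""

import itertools

import numpy as np


def brute_force_otsu(image: np.ndarray) -> int:
    """Exhaustive search over all 256 thresholds for max between-class variance."""
    hist = np.bincount(image.astype(np.uint8).ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    best_t, best_var = 0, -1.0
    for t in range(255):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * p[: t + 1]).sum() / w0
        mu1 = (levels[t + 1 :] * p[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def mwu_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(first, second):
        u = 0.0
        for x in first:
            for y in second:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed = u_of(a, b)
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n1):
        first = [pooled[i] for i in idx]
        second = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_of(first, second))
    us = np.asarray(us)
    p_low = np.mean(us <= observed + 1e-12)
    p_high = np.mean(us >= observed - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def ks_exact_p(a, b) -> float:
    """Exact two-sample KS p: P(D >= observed) over all assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n1 = len(a)

    def d_of(first, second):
        grid = np.unique(pooled)
        cdf1 = np.searchsorted(np.sort(first), grid, side="right") / len(first)
        cdf2 = np.searchsorted(np.sort(second), grid, side="right") / len(second)
        return np.abs(cdf1 - cdf2).max()

    observed = d_of(np.asarray(a, float), np.asarray(b, float))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        first = pooled[list(idx)]
        second = pooled[[i for i in range(len(pooled)) if i not in idx]]
        total += 1
        if d_of(first, second) >= observed - 1e-12:
            count += 1
    return count / total


def auc_pair_counting(scores, labels) -> float:
    """(concordant + half-ties) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))
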