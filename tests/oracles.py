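"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: UPGMA recomputes every
cross-pair average from the raw distance matrix at each merge; BH applies the
step-up definition literally; the NRR oracle enumerates all conditioning
subsets and obtains each partial correlation from regression residuals; the
hypergeometric tail is summed term by term from binomial coefficients.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def upgma_bruteforce(D: np.ndarray):
    """UPGMA where every inter-cluster distance is recomputed from scratch.

    Returns merge heights in merge order together with the merged leaf sets.
    """
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        merges.append((d, clusters[a] | clusters[b]))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def bh_bruteforce(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Literal step-up rule: q_(i) = min over j >= i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, p.size)]
        q[idx] = min(1.0, min(candidates))
    return q


def partial_corr_residuals(data: np.ndarray, i: int, j: int, Q) -> float:
    """Partial correlation via residuals of OLS on the conditioning set."""
    Q = list(Q)
    if not Q:
        return float(np.corrcoef(data[:, i], data[:, j])[0, 1])
    X = np.column_stack([np.ones(data.shape[0]), data[:, Q]])
    ri = data[:, i] - X @ np.linalg.lstsq(X, data[:, i], rcond=None)[0]
    rj = data[:, j] - X @ np.linalg.lstsq(X, data[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


def nrr_bruteforce(data: np.ndarray, i: int, j: int, q: int, alpha: float = 0.05) -> float:
    """NRR by exhaustive subset enumeration and residual-based partial corr."""
    n, p = data.shape
    pool = [v for v in range(p) if v not in (i, j)]
    df = n - q - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nonrej = 0
    subsets = list(combinations(pool, q))
    for Q in subsets:
        r = partial_corr_residuals(data, i, j, Q)
        t = abs(r) * math.sqrt(df / max(1.0 - r * r, 1e-300))
        nonrej += t <= tcrit
    return nonrej / len(subsets)


def hypergeom_tail_bruteforce(M: int, K: int, m: int, x: int) -> float:
    """Upper-tail hypergeometric probability from binomial coefficients."""
    total = math.comb(M, m)
    acc = 0
    for k in range(x, min(K, m) + 1):
        if m - k > M - K:
            continue
        acc += math.comb(K, k) * math.comb(M - K, m - k)
    return acc / total
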