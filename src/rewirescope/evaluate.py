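"""Cross-cutting evaluation utilities.

Hypergeometric (one-tailed Fisher's exact) enrichment of predicted target
sets in reported binding-assay targets, and growth-rate curves
``d(ln A595)/dt`` from optical-density time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EnrichmentResult", "fisher_enrichment", "enrichment_of_sets", "growth_rate"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One-tailed enrichment of m predictions against K reported targets in a
    universe of M genes, with overlap x."""

    universe: int
    reported: int
    predicted: int
    overlap: int
    p: float


def fisher_enrichment(universe: int, reported: int, predicted: int, overlap: int) -> float:
    """Upper-tail hypergeometric p-value (one-tailed Fisher's exact test).

    ``p = sum_{k=x}^{min(K,m)} C(K,k) C(M-K, m-k) / C(M,m)`` — the chance of
    seeing at least the observed overlap between a size-m prediction and K
    reported targets drawn from a size-M universe.
    """
    M, K, m, x = universe, reported, predicted, overlap
    if not (0 <= K <= M and 0 <= m <= M):
        raise ValueError("reported and predicted counts must be within the universe")
    if not 0 <= x <= min(K, m):
        raise ValueError("overlap exceeds the smaller margin")
    if m - x > M - K:
        raise ValueError("non-overlap exceeds the non-reported pool")
    # P(X >= x) for X ~ Hypergeometric(M, K, m)
    return float(stats.hypergeom.sf(x - 1, M, K, m))


def enrichment_of_sets(universe, reported, predicted) -> EnrichmentResult:
    """Enrichment of a predicted gene set in a reported target set."""
    universe = set(universe)
    reported = set(reported) & universe
    predicted = set(predicted) & universe
    x = len(reported & predicted)
    p = fisher_enrichment(len(universe), len(reported), len(predicted), x)
    return EnrichmentResult(len(universe), len(reported), len(predicted), x, p)


def growth_rate(time_h, a595) -> np.ndarray:
    """Instantaneous growth rate d(ln A595)/dt in h^-1.

    Centered finite differences at interior time points, one-sided at the
    endpoints (this is exactly ``numpy.gradient`` on ln A595 over a possibly
    non-uniform time grid). Requires strictly increasing times and positive
    absorbance readings.
    """
    t = np.asarray(time_h, dtype=float)
    a = np.asarray(a595, dtype=float)
    if t.size != a.size:
        raise ValueError("time and absorbance lengths differ")
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(a <= 0):
        raise ValueError("absorbance must be positive to take logarithms")
    return np.gradient(np.log(a), t)
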