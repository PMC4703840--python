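"""Network reverse engineering via limited-order partial correlations.

With far more genes (p) than samples (n), full-order Gaussian graphical
model estimation is impossible: partial correlations can only be computed
given conditioning sets of size q < n - 2. The *non-rejection rate* (NRR)
of a gene pair is the fraction of zero-partial-correlation t-tests, over
conditioning subsets of size q drawn from the remaining genes, that fail to
reject. Averaging the NRR over a set of orders q gives a linear measure of
direct association: a pair connected directly keeps a nonzero partial
correlation under every conditioning set and is rejected almost always
(average NRR near 0), while an indirect association is explained away as
soon as the conditioning set covers the mediating genes. Candidate
regulator->target pairs ranked by ascending average NRR are thresholded
against a gold-standard network via precision-recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .datatypes import GoldStandardNetwork

__all__ = [
    "partial_correlation",
    "nrr_pair",
    "average_nrr",
    "NRRTable",
    "precision_recall",
    "PrecisionRecallCurve",
    "network_at_precision",
    "InferredNetwork",
    "DEFAULT_Q_SET",
]

#: default conditioning orders; "every possible q" is prohibitive at scale,
#: sampling a spread of orders preserves the explaining-away behaviour
DEFAULT_Q_SET = (1, 5, 10, 20, 30)


def partial_correlation(data: np.ndarray, i: int, j: int, conditioning=()) -> float:
    """Sample partial correlation of variables i, j given a conditioning set.

    Computed by inverting the correlation submatrix over {i, j} ∪ Q:
    ``r = -P_ij / sqrt(P_ii P_jj)`` with P the inverse. ``data`` is an
    n x p sample matrix.
    """
    Q = list(conditioning)
    if i == j:
        raise ValueError("i and j must differ")
    if i in Q or j in Q:
        raise ValueError("conditioning set must not contain i or j")
    n = data.shape[0]
    if len(Q) > n - 3:
        raise ValueError("conditioning set too large for the sample size")
    idx = [i, j] + Q
    sub = np.corrcoef(data[:, idx], rowvar=False)
    return _pcor_from_corr(sub)


def _pcor_from_corr(sub: np.ndarray) -> float:
    """Partial correlation of the first two variables of a correlation matrix."""
    if abs(sub[0, 1]) >= 1.0 - 1e-12:
        # perfectly collinear pair: partial correlation is ±1 for any valid Q
        return float(np.sign(sub[0, 1]))
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular correlation submatrix: partial correlation is degenerate"
        ) from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError("degenerate precision submatrix")
    return float(np.clip(-prec[0, 1] / math.sqrt(denom), -1.0, 1.0))


def _nonrejection_tests(corr, n, i, j, subsets, alpha):
    """Fraction of zero-partial-correlation tests that fail to reject.

    ``subsets`` is a sequence of equal-size conditioning index tuples. The
    per-test statistic is ``t = r*sqrt((n-q-2)/(1-r^2))`` on n-q-2 df.
    """
    if not subsets:
        raise ValueError("no conditioning subsets")
    q = len(subsets[0])
    df = n - q - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    if abs(corr[i, j]) >= 1.0 - 1e-12:
        return 0.0  # collinear pair: |r|=1 under every conditioning set
    # batched inversion of the (q+2)x(q+2) correlation submatrices
    idx = np.array([[i, j] + list(Q) for Q in subsets])
    mats = corr[idx[:, :, None], idx[:, None, :]]
    try:
        prec = np.linalg.inv(mats)
    except np.linalg.LinAlgError:
        # fall back to per-subset inversion, skipping singular ones
        nonrej = total = 0
        for Q in subsets:
            sub = corr[np.ix_([i, j] + list(Q), [i, j] + list(Q))]
            try:
                r = _pcor_from_corr(sub)
            except np.linalg.LinAlgError:
                continue
            total += 1
            with np.errstate(divide="ignore"):
                t = abs(r) * math.sqrt(df / max(1.0 - r * r, 1e-300))
            nonrej += t <= tcrit
        if total == 0:
            raise
        return nonrej / total
    denom = prec[:, 0, 0] * prec[:, 1, 1]
    r = np.clip(-prec[:, 0, 1] / np.sqrt(denom), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return float(np.mean(t <= tcrit))


def _draw_subsets(pool, q, n_subsets, rng):
    """Conditioning sets of size q: exhaustive when few, else sampled."""
    total = comb(len(pool), q, exact=True)
    if total <= n_subsets:
        return [tuple(c) for c in combinations(pool, q)]
    seen = set()
    out = []
    while len(out) < n_subsets:
        cand = tuple(sorted(rng.choice(pool, size=q, replace=False)))
        if cand in seen:
            continue
        seen.add(cand)
        out.append(cand)
    return out


def nrr_pair(
    data: np.ndarray,
    i: int,
    j: int,
    q: int,
    n_subsets: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    others=None,
) -> float:
    """Non-rejection rate of pair (i, j) at conditioning order q.

    Conditioning sets are drawn uniformly from the other variables
    (exhaustively enumerated when there are at most ``n_subsets`` of them).
    Deterministic given ``seed``.
    """
    n, p = data.shape
    if q >= n - 2:
        raise ValueError("order q must satisfy q < n - 2")
    if n_subsets < 1:
        raise ValueError("need at least one conditioning subset")
    rng = np.random.default_rng(seed)
    pool = np.array([v for v in (others if others is not None else range(p)) if v not in (i, j)])
    if q > pool.size:
        raise ValueError("order q exceeds the number of available variables")
    corr = np.corrcoef(data, rowvar=False)
    subsets = _draw_subsets(pool, q, n_subsets, rng)
    return _nonrejection_tests(corr, n, i, j, subsets, alpha)


@dataclass
class NRRTable:
    """Ranked candidate regulator->target associations.

    ``table`` is indexed by (regulator, gene) with one ``nrr_q{q}`` column
    per order, the ``avg_nrr`` mean, and a 1-based ``rank`` ascending in
    average NRR (low NRR = strong direct association), ties broken by
    (regulator id, gene id).
    """

    table: pd.DataFrame
    q_set: tuple

    def ranked_pairs(self) -> list:
        return list(self.table.sort_values("rank").index)


def average_nrr(
    data: np.ndarray,
    candidate_pairs,
    q_set=DEFAULT_Q_SET,
    n_subsets: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    variables=None,
) -> NRRTable:
    """Average NRR over orders for each candidate pair, ranked ascending.

    ``candidate_pairs`` are (regulator index, gene index) tuples (typically
    every regulator x gene combination); ``variables`` optionally names the
    columns of ``data`` so the table is indexed by gene id instead of column
    position. The per-(pair, q) subset draws are seeded independently from
    ``seed`` so results do not depend on pair order or on the q_set order.
    """
    pairs = list(candidate_pairs)
    if not pairs:
        raise ValueError("empty candidate pair set")
    n, p = data.shape
    q_set = tuple(sorted(set(int(q) for q in q_set)))
    for q in q_set:
        if not 1 <= q <= n - 3:
            raise ValueError(f"order {q} outside the valid range [1, n-3]")
        if q > p - 2:
            raise ValueError(f"order {q} exceeds the number of other variables")
    corr = np.corrcoef(data, rowvar=False)
    root = np.random.SeedSequence(seed)

    rows = {}
    for i, j in pairs:
        per_q = {}
        for q in q_set:
            # one child seed per (pair, q): invariant to enumeration order
            child = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(i, j, q))
            )
            pool = np.array([v for v in range(p) if v not in (i, j)])
            subsets = _draw_subsets(pool, q, n_subsets, child)
            per_q[f"nrr_q{q}"] = _nonrejection_tests(corr, n, i, j, subsets, alpha)
        rows[(i, j)] = per_q

    table = pd.DataFrame.from_dict(rows, orient="index")
    table["avg_nrr"] = table[[f"nrr_q{q}" for q in q_set]].mean(axis=1)
    if variables is not None:
        table.index = pd.MultiIndex.from_tuples(
            [(variables[i], variables[j]) for i, j in table.index],
            names=["regulator", "gene"],
        )
    else:
        table.index = pd.MultiIndex.from_tuples(table.index, names=["regulator", "gene"])
    # ascending average NRR, ties broken by (regulator id, gene id)
    table = table.sort_index(kind="stable").sort_values(by="avg_nrr", kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return NRRTable(table=table, q_set=q_set)


# ---------------------------------------------------------------------------
# evaluation against a gold standard
# ---------------------------------------------------------------------------

@dataclass
class PrecisionRecallCurve:
    """Precision/recall (percent) along the ranked prediction list.

    ``points`` has columns k, tp, eligible, precision, recall. Precision is
    computed only over *eligible* predictions — those whose both endpoints
    appear in at least one gold-standard interaction — mirroring the
    convention that genes absent from the reference cannot be scored.
    """

    points: pd.DataFrame

    def precision_at(self, k: int) -> float:
        return float(self.points.loc[self.points["k"] == k, "precision"].iloc[0])


def _gold_sets(gold: GoldStandardNetwork):
    undirected = {frozenset((r, t)) for r, t, _, _ in gold.edges}
    nodes = gold.node_set()
    return undirected, nodes


def precision_recall(ranking: NRRTable, gold: GoldStandardNetwork) -> PrecisionRecallCurve:
    """Walk the ranking, accumulating TP / eligible counts at every k.

    A predicted (regulator, gene) pair is a true positive when the unordered
    pair matches a gold edge; recall is over all gold edges; precision and
    recall are percentages.
    """
    if len(gold) == 0:
        raise ValueError("empty gold standard")
    pairs = ranking.ranked_pairs()
    if not pairs:
        raise ValueError("empty ranking")
    undirected, nodes = _gold_sets(gold)
    rows = []
    eligible = 0
    matched: set = set()  # distinct gold edges hit (a re-prediction of the
    # same undirected edge under the opposite orientation is not a new TP)
    for k, (reg, gene) in enumerate(pairs, start=1):
        if reg in nodes and gene in nodes:
            eligible += 1
            key = frozenset((reg, gene))
            if key in undirected:
                matched.add(key)
        tp = len(matched)
        precision = 100.0 * tp / eligible if eligible else math.nan
        recall = 100.0 * tp / len(undirected)
        rows.append((k, tp, eligible, precision, recall))
    return PrecisionRecallCurve(
        points=pd.DataFrame(rows, columns=["k", "tp", "eligible", "precision", "recall"])
    )


@dataclass
class InferredNetwork:
    """Undirected association network annotated regulator->target.

    ``edges`` are the (regulator, gene) predictions kept at the nominal
    precision; ``modules`` are the connected components of the undirected
    edge set.
    """

    edges: list
    nodes: set
    modules: list
    nominal_precision: float

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def network_at_precision(
    curve: PrecisionRecallCurve, ranking: NRRTable, nominal: float
) -> InferredNetwork:
    """Cut the ranking at the largest k whose precision >= ``nominal`` percent."""
    pts = curve.points
    ok = pts[(pts["precision"] >= nominal) & pts["precision"].notna()]
    if ok.empty:
        raise ValueError(f"nominal precision {nominal}% is never reached")
    k = int(ok["k"].max())
    edges = ranking.ranked_pairs()[:k]
    g = nx.Graph()
    g.add_edges_from((r, t) for r, t in edges)
    modules = [sorted(c) for c in nx.connected_components(g)]
    modules.sort(key=lambda c: (-len(c), c[0]))
    return InferredNetwork(
        edges=edges,
        nodes=set(g.nodes),
        modules=modules,
        nominal_precision=float(nominal),
    )
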