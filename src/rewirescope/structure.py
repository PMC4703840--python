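"""Co-expression structure discovery.

Three complementary views of the latent states of a perturbation panel:

* hierarchical clustering (UPGMA / unweighted average linkage) under the
  *uncentred* correlation distance ``1 - <x,y>/(||x||*||y||)`` — the classic
  microarray-clustering metric that, unlike Pearson distance, does not
  mean-center and therefore treats a flat profile at zero as dissimilar from
  any regulated profile;
* the Iterative Signature Algorithm (ISA), a biclustering method that
  alternates thresholded gene/construct signature updates to fixed points and
  allows genes to belong to several overlapping modules;
* PCA with the Kaiser criterion (retain components with correlation-matrix
  eigenvalue > 1) as a state-counting heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "Bicluster",
    "PcaSummary",
    "uncentred_correlation_distance",
    "uncentred_distance_matrix",
    "upgma",
    "display_filter",
    "isa_gene_prefilter",
    "isa_biclusters",
    "pca_kaiser",
]


# ---------------------------------------------------------------------------
# UPGMA under the uncentred correlation distance
# ---------------------------------------------------------------------------

def uncentred_correlation_distance(x, y) -> float:
    """d = 1 − Σx_i y_i / (√Σx_i² √Σy_i²), in [0, 2]; no mean centering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx = np.sqrt((x**2).sum())
    ny = np.sqrt((y**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentred correlation undefined for an all-zero vector")
    return float(1.0 - (x @ y) / (nx * ny))


def uncentred_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise uncentred correlation distances between matrix rows."""
    X = np.asarray(profiles, dtype=float)
    norms = np.sqrt((X**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("uncentred correlation undefined for all-zero rows")
    d = 1.0 - (X @ X.T) / np.outer(norms, norms)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges`` lists (node_a, node_b, raw merge distance) in merge order;
    leaves are 0..n-1, internal node k is n+k. ``half_heights`` are the
    conventional tree heights (half the merge distance). ``leaf_order``
    follows the tighter-subtree-first convention: at every internal node the
    child with the smaller height comes first, ties broken by smallest leaf.
    """

    merges: list
    labels: list
    leaf_order: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def half_heights(self) -> list:
        return [h / 2.0 for _, _, h in self.merges]

    def to_newick(self) -> str:
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        rep = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            hh = h / 2.0
            la = h / 2.0 - height[a]
            lb = h / 2.0 - height[b]
            rep[n + k] = f"({rep[a]}:{la:.6g},{rep[b]}:{lb:.6g})"
            height[n + k] = hh
        return rep[n + len(self.merges) - 1] + ";"


def _leaf_order(merges, n):
    height = {i: 0.0 for i in range(n)}
    children = {}
    min_leaf = {i: i for i in range(n)}
    for k, (a, b, h) in enumerate(merges):
        node = n + k
        children[node] = (a, b)
        height[node] = h / 2.0
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
    order = []

    def visit(node):
        if node < n:
            order.append(node)
            return
        a, b = children[node]
        first, second = sorted((a, b), key=lambda c: (height[c], min_leaf[c]))
        visit(first)
        visit(second)

    visit(n + len(merges) - 1)
    return order


def upgma(distance: np.ndarray, labels=None) -> Dendrogram:
    """Unweighted average-linkage clustering of a full distance matrix.

    The inter-cluster distance is the unweighted mean of all cross-pair leaf
    distances; merge heights are therefore non-decreasing. Raw merge
    distances are recorded; tree heights use the half-distance convention.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if n < 2:
        raise ValueError("need at least two leaves")
    Z = linkage(squareform(D, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    dend = Dendrogram(merges=merges, labels=list(labels))
    dend.leaf_order = _leaf_order(merges, n)
    return dend


# ---------------------------------------------------------------------------
# display filter
# ---------------------------------------------------------------------------

def display_filter(
    fc: pd.DataFrame,
    deg_masks: pd.DataFrame,
    min_networks: int = 5,
    min_abs_sum: float = 4.0,
) -> pd.Index:
    """Genes differentially expressed in >= ``min_networks`` constructs whose
    signed log2FC sum has absolute value > ``min_abs_sum``."""
    masks = deg_masks.reindex(index=fc.index, columns=fc.columns)
    if masks.isna().any().any():
        raise ValueError("DEG masks are not aligned to the matrix")
    counts = masks.astype(bool).sum(axis=1)
    abs_sums = fc.sum(axis=1).abs()
    return fc.index[(counts >= min_networks) & (abs_sums > min_abs_sum)]


# ---------------------------------------------------------------------------
# Iterative Signature Algorithm
# ---------------------------------------------------------------------------

@dataclass
class Bicluster:
    """One transcription module: a gene set co-regulated over a construct set.

    Scores are the signature weights at the ISA fixed point; genes may appear
    in several biclusters.
    """

    genes: tuple
    constructs: tuple
    gene_scores: np.ndarray
    construct_scores: np.ndarray
    robustness: float = 0.0

    def __post_init__(self):
        if not self.genes or not self.constructs:
            raise ValueError("bicluster gene and construct sets must be non-empty")


def isa_gene_prefilter(fc: pd.DataFrame, cutoff: float = 0.25, min_points: int = 3) -> pd.DataFrame:
    """Keep genes with |log2FC| > cutoff in at least ``min_points`` constructs."""
    keep = (fc.abs() > cutoff).sum(axis=1) >= min_points
    return fc.loc[keep]


def _standardize(a: np.ndarray, axis: int) -> np.ndarray:
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    sd[sd == 0] = 1.0
    return (a - mean) / sd


def _isa_iterate(row_std, col_std, gene_seed, tg, tc, max_iter):
    """Alternate signature updates from one gene seed to a fixed point.

    Returns (genes, constructs, gene_scores, construct_scores) or None if the
    iteration dies out or fails to converge.
    """
    genes = np.sort(np.asarray(gene_seed))
    prev = None
    for _ in range(max_iter):
        c_scores = col_std[genes].mean(axis=0)
        sd_c = c_scores.std()
        if sd_c == 0:
            return None
        constructs = np.flatnonzero(np.abs(c_scores) > tc * sd_c)
        if constructs.size == 0:
            return None
        g_scores = row_std[:, constructs].mean(axis=1)
        sd_g = g_scores.std()
        if sd_g == 0:
            return None
        genes_new = np.flatnonzero(np.abs(g_scores) > tg * sd_g)
        if genes_new.size == 0:
            return None
        state = (tuple(genes_new), tuple(constructs))
        if state == prev:
            return genes_new, constructs, g_scores[genes_new], c_scores[constructs]
        prev = state
        genes = genes_new
    return None


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


def _robustness(b: Bicluster) -> float:
    # product of the gene- and construct-signature norms: rewards coherent
    # modules over small outlier coincidences (which win under mean |score|)
    return float(
        np.sqrt((b.gene_scores**2).sum()) * np.sqrt((b.construct_scores**2).sum())
    )


def _run_isa(row_std, col_std, tg, tc, n_seeds, seed_size, max_iter, rng, jaccard_cut,
             min_genes=2, min_constructs=2):
    n_genes = row_std.shape[0]
    found = []
    for _ in range(n_seeds):
        gene_seed = rng.choice(n_genes, size=min(seed_size, n_genes), replace=False)
        fp = _isa_iterate(row_std, col_std, gene_seed, tg, tc, max_iter)
        if fp is None:
            continue
        genes, constructs, gs, cs = fp
        # a single gene or single construct is not a module
        if genes.size < min_genes or constructs.size < min_constructs:
            continue
        bic = Bicluster(tuple(genes), tuple(constructs), gs, cs)
        bic.robustness = _robustness(bic)
        found.append(bic)
    # deduplicate by gene-set Jaccard, keeping the most robust representative
    found.sort(key=lambda b: (-b.robustness, b.genes))
    kept = []
    for b in found:
        gset = set(b.genes)
        if any(_jaccard(gset, set(k.genes)) >= jaccard_cut for k in kept):
            continue
        kept.append(b)
    return kept


def isa_biclusters(
    fc: pd.DataFrame,
    tg: float = 2.1,
    tc: float = 1.5,
    n_seeds: int = 200,
    seed_size: int = 10,
    max_iter: int = 50,
    jaccard_cut: float = 0.8,
    permutation_filter: bool = True,
    seed: int = 0,
) -> list:
    """Run ISA and return significant biclusters.

    Gene and construct thresholds ``tg``/``tc`` are in units of the standard
    deviation of the respective score vectors (defaults 2.1 and 1.5). Fixed
    points from ``n_seeds`` random gene seeds are deduplicated at gene-set
    Jaccard >= ``jaccard_cut``; with ``permutation_filter`` the modules must
    exceed the maximum robustness found on a within-column permuted matrix —
    a stand-in significance filter with no analytic null. Deterministic
    given ``seed``. Returns a (possibly empty) list of :class:`Bicluster`
    with index tuples resolved to gene/construct labels.
    """
    if tg <= 0 or tc <= 0:
        raise ValueError("thresholds must be positive")
    X = fc.to_numpy(dtype=float)
    if min(X.shape) < 2:
        raise ValueError("matrix too small for biclustering")
    rng = np.random.default_rng(seed)
    row_std = _standardize(X, axis=1)
    col_std = _standardize(X, axis=0)
    kept = _run_isa(row_std, col_std, tg, tc, n_seeds, seed_size, max_iter, rng, jaccard_cut)

    if permutation_filter and kept:
        # permute each gene's profile independently: preserves per-gene
        # marginal distributions (incl. heavy tails) while destroying the
        # across-gene construct alignment that defines a module
        perm = rng.permuted(X, axis=1)
        p_row = _standardize(perm, axis=1)
        p_col = _standardize(perm, axis=0)
        null = _run_isa(p_row, p_col, tg, tc, n_seeds, seed_size, max_iter, rng, jaccard_cut)
        threshold = max((b.robustness for b in null), default=0.0)
        kept = [b for b in kept if b.robustness > threshold]

    genes = list(fc.index)
    constructs = list(fc.columns)
    return [
        Bicluster(
            genes=tuple(genes[i] for i in b.genes),
            constructs=tuple(constructs[j] for j in b.constructs),
            gene_scores=b.gene_scores,
            construct_scores=b.construct_scores,
            robustness=b.robustness,
        )
        for b in kept
    ]


# ---------------------------------------------------------------------------
# PCA with the Kaiser criterion
# ---------------------------------------------------------------------------

@dataclass
class PcaSummary:
    """Eigen-spectrum of the variables' correlation matrix.

    ``retained`` counts eigenvalues strictly above 1 (Kaiser rule: a retained
    component must explain at least one original variable's worth of
    variance); ``cumulative_variance`` is their share of the total.
    """

    eigenvalues: np.ndarray
    retained: int
    cumulative_variance: float
    dropped_variables: tuple = ()


def pca_kaiser(fc: pd.DataFrame, variables_axis: str = "constructs") -> PcaSummary:
    """Eigen-decompose the correlation matrix of the chosen variables.

    With ``variables_axis="constructs"`` (default) each construct profile is
    a variable observed over genes; ``"genes"`` transposes the role. Zero-
    variance variables are dropped with a warning before decomposition.
    """
    if variables_axis == "constructs":
        X = fc.to_numpy(dtype=float)  # observations = genes, variables = constructs
        names = list(fc.columns)
    elif variables_axis == "genes":
        X = fc.to_numpy(dtype=float).T
        names = list(fc.index)
    else:
        raise ValueError("variables_axis must be 'constructs' or 'genes'")
    sd = X.std(axis=0)
    dropped = tuple(n for n, s in zip(names, sd) if s == 0)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance variables", stacklevel=2)
        X = X[:, sd > 0]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables with nonzero variance")
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    retained = int((eig > 1.0).sum())
    cumulative = float(eig[:retained].sum() / eig.sum()) if retained else 0.0
    return PcaSummary(
        eigenvalues=eig,
        retained=retained,
        cumulative_variance=cumulative,
        dropped_variables=dropped,
    )
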