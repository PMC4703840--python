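"""Gene-set state scores and correlation-based regulator ranking.

A *state score* for a construct is the sum of log2 fold changes over a fixed
gene set (e.g. the ribosomal-cluster or flagellar-cluster genes), with
candidate regulators excluded from the sum so that correlating regulator
expression against the score is not circular. Candidate regulators are
ranked by the Pearson correlation of their log2FC profile with the score
across constructs, with p-values from the ANOVA F-test of the corresponding
simple linear regression.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet

__all__ = [
    "geneset_score",
    "rank_regulators",
    "variance_explained",
    "antagonism",
    "read_geneset",
    "correlation_f_test",
]


def geneset_score(fc: pd.DataFrame, geneset: GeneSet) -> pd.Series:
    """Per-construct score: sum of log2FC over the set members.

    ``fc`` is the genes x constructs log2 fold-change matrix. Members listed
    in ``geneset.excluded`` never contribute (they are disjoint from members
    by construction); members absent from the matrix raise.
    """
    members = sorted(geneset.members)
    if not members:
        raise ValueError(f"gene set {geneset.name!r} has no members")
    missing = [g for g in members if g not in fc.index]
    if missing:
        raise KeyError(f"gene set members absent from matrix: {missing[:5]}")
    score = fc.loc[members].sum(axis=0)
    score.name = f"{geneset.name}_score"
    return score


def correlation_f_test(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson R with the ANOVA F-test p-value of the linear regression."""
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return math.nan, math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return r, 0.0
    f = r2 * (n - 2) / (1.0 - r2)
    return r, float(stats.f.sf(f, 1, n - 2))


def rank_regulators(
    fc: pd.DataFrame,
    score: pd.Series,
    candidates=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Rank candidate regulator genes by |correlation| with a state score.

    Returns a DataFrame indexed by gene with columns ``R``, ``p`` and
    ``rank``, sorted by descending |R|; ties in |R| and genes with undefined
    correlation (zero-variance profiles, reported as NaN and ranked last) are
    ordered by gene id for determinism.
    """
    score = score.reindex(fc.columns)
    if score.isna().any():
        raise ValueError("score does not cover all constructs in the matrix")
    if len(fc.columns) < 3:
        raise ValueError("need at least 3 constructs")
    genes = sorted(candidates) if candidates is not None else list(fc.index)
    missing = [g for g in genes if g not in fc.index]
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {missing[:5]}")

    y = score.to_numpy(dtype=float)
    sub = fc.loc[genes].to_numpy(dtype=float)
    if method == "spearman":
        y_r = stats.rankdata(y)
        sub = np.apply_along_axis(stats.rankdata, 1, sub)
    else:
        y_r = y
    n = len(y)
    yc = y_r - y_r.mean()
    xc = sub - sub.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    r2 = np.clip(r * r, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = r2 * (n - 2) / (1.0 - r2)
    p = stats.f.sf(f, 1, n - 2)
    p = np.where(r2 >= 1.0, 0.0, p)

    out = pd.DataFrame({"R": r, "p": p}, index=pd.Index(genes, name="gene"))
    absr = out["R"].abs()
    # NaN correlations sink to the bottom; ties broken lexicographically
    out = out.iloc[
        sorted(
            range(len(out)),
            key=lambda i: (-(absr.iloc[i] if np.isfinite(absr.iloc[i]) else -1.0), genes[i]),
        )
    ]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def variance_explained(score: pd.Series, predictors: pd.DataFrame | np.ndarray) -> float:
    """R^2 of the OLS fit of the score on predictor log2FC profiles.

    ``predictors`` is constructs x predictors (a DataFrame transposes gene
    rows via ``.T`` upstream). Rank-deficient designs are handled by the
    least-squares pseudoinverse; an R^2 is always returned.
    """
    y = np.asarray(score, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n != y.size:
        raise ValueError("predictor rows must match the number of constructs")
    if n <= k + 1:
        raise ValueError("need more constructs than predictors + 1")
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 1.0
    return float(np.clip(1.0 - float((resid**2).sum()) / tss, 0.0, 1.0))


def antagonism(fc: pd.DataFrame, gene_a, gene_b, constructs=None) -> tuple:
    """Correlation between two genes' log2FC profiles over a construct subset.

    Quantifies mutually exclusive states (e.g. a flagellar master regulator
    versus a ribosomal-state sensor): a strong negative R indicates the two
    genes move in opposition across the selected constructs.
    """
    cols = list(constructs) if constructs is not None else list(fc.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 constructs")
    a = fc.loc[gene_a, cols].to_numpy(dtype=float)
    b = fc.loc[gene_b, cols].to_numpy(dtype=float)
    if gene_a == gene_b:
        return 1.0, 0.0
    return correlation_f_test(a, b)


def read_geneset(path, name: str | None = None) -> GeneSet:
    """Read a gene-set file: one gene id per line, ``!`` prefix = excluded."""
    members, excluded = set(), set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g.startswith("!"):
                excluded.add(g[1:].strip())
            else:
                members.add(g)
    return GeneSet(
        name=name or str(path),
        members=frozenset(members - excluded),
        excluded=frozenset(excluded),
    )
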