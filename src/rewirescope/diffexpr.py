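"""Differential expression vs the wild-type control.

Implements the study's DEG rule — a gene is differentially expressed in a
construct when its Benjamini–Hochberg q-value is below 5% and its fold change
exceeds 1.2 — on top of an empirical-Bayes moderated two-sample t-test.
Variance moderation follows the standard hierarchical model in which gene
variances are exchangeable draws from a scaled inverse-chi-squared prior, so
that ``s_g^2 / s0^2 ~ F(d_g, d0)``; the prior parameters ``(d0, s0^2)`` are
estimated by matching the first two moments of the observed gene variances to
that F distribution, and each gene's posterior variance
``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` replaces the pooled variance in the t
statistic, tested on ``d0 + d_g`` degrees of freedom. ``shrink=False``
recovers the classical pooled two-sample t exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DEResult, ExpressionMatrix

__all__ = [
    "log2_fold_change",
    "moderated_t_test",
    "estimate_variance_prior",
    "benjamini_hochberg",
    "call_degs",
    "de_analysis",
    "perturbation_sizes",
    "association_with_design",
    "FDR_DEFAULT",
    "FC_DEFAULT",
]

FDR_DEFAULT = 0.05
FC_DEFAULT = 1.2


def _as_2d(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def log2_fold_change(case, control) -> np.ndarray:
    """Per-gene log2FC = mean(case log2 values) − mean(control log2 values).

    ``case`` and ``control`` are genes x replicates arrays (or vectors) of
    log2-scale expression over a matching gene universe.
    """
    case = _as_2d(case)
    control = _as_2d(control)
    if case.shape[0] != control.shape[0]:
        raise ValueError("case and control gene universes differ in size")
    if case.shape[1] < 1 or control.shape[1] < 1:
        raise ValueError("need at least one replicate on each side")
    return case.mean(axis=1) - control.mean(axis=1)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple:
    """Moment-matching estimate of the variance prior ``(d0, s0^2)``.

    Under the hierarchical model ``s2/s0^2 ~ F(df, d0)``. Matching the sample
    mean and variance of ``s2`` to the F moments gives a closed form for d0;
    when the observed variances are under-dispersed relative to pure
    chi-squared sampling noise, d0 is effectively infinite (complete
    shrinkage to a common variance) and is returned as ``math.inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 1.0
    m1 = float(np.mean(s2))
    m2 = float(np.var(s2, ddof=1))
    c = m2 / (m1 * m1)
    # Var/E^2 of F(df, d0) = 2*(df + d0 - 2) / (df*(d0 - 4))
    denom = c * df - 2.0
    if denom <= 0:
        return math.inf, m1
    d0 = (4.0 * c * df + 2.0 * df - 4.0) / denom
    if d0 <= 4.0 or not np.isfinite(d0):
        # moment solution outside the valid region: weak shrinkage fallback
        d0 = 4.0 + 1e-6 if denom > 0 else math.inf
    s0_2 = m1 * (d0 - 2.0) / d0 if np.isfinite(d0) else m1
    return float(d0), float(s0_2)


def moderated_t_test(case, control, shrink: bool = True, prior: tuple | None = None):
    """Two-sample t on log2 values with optional empirical-Bayes moderation.

    Returns ``(t, p)`` arrays. With ``shrink=False`` this is the ordinary
    pooled-variance two-sample t with ``n1+n2-2`` degrees of freedom; with
    ``shrink=True`` gene variances are shrunk toward the moment-matched prior
    and the null has ``d0 + d_g`` degrees of freedom. ``prior`` forces
    ``(d0, s0^2)`` (used to exercise the d0 -> inf limit).
    """
    case = _as_2d(case)
    control = _as_2d(control)
    n1, n2 = case.shape[1], control.shape[1]
    if shrink:
        if n1 < 2:
            raise ValueError("moderated test needs >= 2 case replicates")
    elif n1 < 2 or n2 < 2:
        raise ValueError("classical test needs >= 2 replicates per side")
    df = max(n1 - 1, 0) + max(n2 - 1, 0)
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    delta = case.mean(axis=1) - control.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) if n1 > 1 else np.zeros(case.shape[0])
    ss = ss + (control.var(axis=1, ddof=1) * (n2 - 1) if n2 > 1 else 0.0)
    s2 = ss / df
    scale = 1.0 / n1 + 1.0 / n2

    if not shrink:
        if np.all(s2 <= 0):
            raise ValueError("zero within-group variance for all genes")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(s2 * scale)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return t, p

    d0, s0_2 = prior if prior is not None else estimate_variance_prior(s2, df)
    if math.isinf(d0):
        post = np.full_like(s2, s0_2)
        df_total = 1e12  # normal limit
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(post * scale)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def benjamini_hochberg(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``q_(i) = min_{j>=i} p_(j) * m / j`` on sorted p-values, mapped back to
    the input order and clipped to [0, 1]. ``m`` defaults to the number of
    p-values but may be set to the size of the tested gene universe when some
    genes were excluded before testing.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m cannot be below the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_degs(result: DEResult, fdr: float = FDR_DEFAULT, fold_change: float = FC_DEFAULT):
    """Apply the DEG rule: q < fdr AND |log2FC| > log2(fold_change).

    Returns ``(deg_gene_index, perturbation_size)``.
    """
    t = result.table
    mask = (t["q"] < fdr) & (t["log2fc"].abs() > math.log2(fold_change))
    return t.index[mask], int(mask.sum())


def de_analysis(
    matrix: ExpressionMatrix,
    construct,
    shrink: bool = True,
    fdr: float = FDR_DEFAULT,
    fold_change: float = FC_DEFAULT,
    m: int | None = None,
) -> DEResult:
    """Full DE table for one construct vs the control replicates."""
    case_cols = matrix.construct_columns(construct)
    control_cols = matrix.control_columns()
    if not case_cols:
        raise ValueError(f"no samples for construct {construct!r}")
    if not control_cols:
        raise ValueError("matrix has no control samples")
    case = matrix.data[case_cols].to_numpy()
    control = matrix.data[control_cols].to_numpy()
    fc = log2_fold_change(case, control)
    t, p = moderated_t_test(case, control, shrink=shrink)
    q = benjamini_hochberg(p, m=m)
    table = pd.DataFrame(
        {"log2fc": fc, "t": t, "p": p, "q": q}, index=matrix.genes
    )
    table["deg"] = (table["q"] < fdr) & (table["log2fc"].abs() > math.log2(fold_change))
    return DEResult(table=table)


def perturbation_sizes(
    matrix: ExpressionMatrix,
    shrink: bool = True,
    fdr: float = FDR_DEFAULT,
    fold_change: float = FC_DEFAULT,
) -> pd.Series:
    """Number of called DEGs per construct (the construct's perturbation size)."""
    sizes = {}
    for c in matrix.constructs():
        res = de_analysis(matrix, c, shrink=shrink, fdr=fdr, fold_change=fold_change)
        sizes[c] = res.perturbation_size
    return pd.Series(sizes, name="perturbation_size")


def association_with_design(sizes, covariate) -> tuple:
    """Linear association of perturbation size with a construct property.

    Simple linear regression of ``sizes`` on ``covariate`` (promoter strength
    or ORF out-degree); returns ``(R, F, p)`` with R the Pearson correlation,
    ``F = R^2 (n-2) / (1 - R^2)`` and p the upper tail of F(1, n-2) — the
    ANOVA F-test of the regression slope.
    """
    y = np.asarray(sizes, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size != x.size:
        raise ValueError("length mismatch")
    if y.size < 3:
        raise ValueError("need at least 3 constructs")
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("non-finite inputs")
    if np.std(x) == 0:
        raise ValueError("zero-variance covariate: regression is degenerate")
    r = float(np.corrcoef(x, y)[0, 1])
    n = y.size
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return r, math.inf, 0.0
    f = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(f, 1, n - 2))
    return r, float(f), p
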