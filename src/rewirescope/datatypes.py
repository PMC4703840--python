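"""Core containers shared across the pipeline.

The central object is the gene x sample :class:`ExpressionMatrix` (log2-scale
expression or log2 fold change vs the wild-type control), together with a
directed regulator->target :class:`GoldStandardNetwork` used both as simulation
ground truth and as the evaluation reference for reverse engineering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GoldStandardNetwork",
    "ConstructDesign",
    "LatentState",
    "SimulationParams",
    "GgmSpec",
    "ExpressionMatrix",
    "DEResult",
    "GeneSet",
]


@dataclass(frozen=True)
class GoldStandardNetwork:
    """Directed regulator->target edge list with signs and effect weights.

    ``edges`` holds ``(regulator, target, sign, weight)`` tuples where ``sign``
    is +1 (activation) or -1 (repression) and ``weight`` is a unitless effect
    size on the log2 fold-change scale. Every edge regulator must be a member
    of ``regulators``; duplicate ordered pairs and (by default) self-edges are
    rejected.
    """

    regulators: frozenset
    edges: tuple
    allow_autoregulation: bool = False

    def __post_init__(self):
        seen = set()
        for reg, tgt, sign, weight in self.edges:
            if reg not in self.regulators:
                raise ValueError(f"edge regulator {reg!r} not in regulator set")
            if reg == tgt and not self.allow_autoregulation:
                raise ValueError(f"self-edge on {reg!r} without autoregulation flag")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +1/-1, got {sign!r}")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge {(reg, tgt)!r}")
            seen.add((reg, tgt))

    @property
    def edge_pairs(self) -> set:
        """Set of ordered (regulator, target) pairs."""
        return {(r, t) for r, t, _, _ in self.edges}

    def out_degree(self, gene) -> int:
        return sum(1 for r, _, _, _ in self.edges if r == gene)

    def targets_of(self, gene) -> list:
        """Outgoing edges of ``gene`` as (target, sign, weight) triples."""
        return [(t, s, w) for r, t, s, w in self.edges if r == gene]

    def node_set(self) -> set:
        nodes = set()
        for r, t, _, _ in self.edges:
            nodes.add(r)
            nodes.add(t)
        return nodes

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class ConstructDesign:
    """One rewiring construct: a promoter region fused to a regulator ORF.

    ``orf`` is ``None`` for promoter-only control constructs (the GFP-only
    clones). ``promoter_strength`` is a positive unitless activity scalar and
    ``orf_out_degree`` the ORF's out-degree in the gold-standard network.
    """

    construct: str
    promoter: str
    orf: object  # gene id or None
    promoter_strength: float
    orf_out_degree: int = 0

    def __post_init__(self):
        if not self.promoter_strength > 0:
            raise ValueError("promoter strength must be > 0")
        if self.orf is None and self.orf_out_degree != 0:
            raise ValueError("promoter-only construct cannot have ORF out-degree")
        if self.orf_out_degree < 0:
            raise ValueError("ORF out-degree must be nonnegative")


@dataclass(frozen=True)
class LatentState:
    """A self-reinforcing co-expression state (attractor-like).

    The state activates in a construct when the summed induced log2FC of its
    ``drivers`` exceeds ``threshold``; all ``members`` are then shifted by
    ``direction * amplitude`` log2 units.
    """

    name: str
    members: frozenset
    drivers: frozenset
    threshold: float
    direction: int = 1  # +1 up, -1 down
    amplitude: float = 1.0

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class SimulationParams:
    """Tunable knobs of the rewired-transcriptome simulator.

    Defaults emulate the study design: 3,891 genes x 85 constructs in
    biological triplicate against five control replicates, a dominant self-ORF
    upregulation (log-normal, median 13-fold), downstream propagation with
    per-depth attenuation, and hard-threshold latent-state activation.
    """

    n_genes: int = 3891
    n_constructs: int = 85
    replicates: int = 3
    control_replicates: int = 5
    # log-normal natural-log parameters of the ORF fold change (median 13-fold;
    # sigma spans the 2- to 600-fold 1st-99th percentile range)
    orf_log_fc_mu: float = float(np.log(13.0))
    orf_log_fc_sigma: float = float((np.log(600.0) - np.log(2.0)) / (2 * 2.326348))
    attenuation: float = 0.4
    max_depth: int = 3
    latent_states: tuple = ()
    # per-member, per-construct spread of the latent-state response magnitude
    # (relative sd of the shift multiplier; regulon members respond with
    # heterogeneous efficacy rather than uniformly)
    response_heterogeneity: float = 0.75
    replicate_noise_sd: float = 0.25
    biological_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.replicate_noise_sd < 0 or self.biological_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.response_heterogeneity < 0:
            raise ValueError("response heterogeneity must be >= 0")
        if not 0 < self.attenuation < 1:
            raise ValueError("attenuation must be in (0, 1)")


@dataclass(frozen=True)
class GgmSpec:
    """Zero pattern and strength of a Gaussian graphical model.

    ``edges`` lists the (i, j) index pairs with nonzero partial correlation;
    the implied precision matrix is made symmetric positive definite by
    diagonal dominance, so realized partial correlations are close to (but not
    exactly) ``magnitude``.
    """

    p: int
    edges: tuple
    magnitude: float = 0.3
    n: int = 100

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need at least 3 samples")
        if not 0 < self.magnitude < 1:
            raise ValueError("partial-correlation magnitude must be in (0, 1)")
        for i, j in self.edges:
            if i == j or not (0 <= i < self.p and 0 <= j < self.p):
                raise ValueError(f"bad edge {(i, j)!r}")


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with sample annotations.

    ``data`` rows are genes, columns are samples. ``sample_construct`` maps
    each sample id to its construct id (control samples map to the control
    label, flagged by ``is_control``). Values are log2-scale expression or
    log2 fold changes depending on provenance.
    """

    data: pd.DataFrame
    sample_construct: pd.Series
    is_control: pd.Series

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("non-finite expression values")
        missing = [s for s in self.data.columns if s not in self.sample_construct.index]
        if missing:
            raise ValueError(f"samples without construct mapping: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def control_columns(self) -> list:
        return [s for s in self.data.columns if bool(self.is_control.get(s, False))]

    def construct_columns(self, construct) -> list:
        return [
            s
            for s in self.data.columns
            if self.sample_construct[s] == construct and not bool(self.is_control.get(s, False))
        ]

    def constructs(self) -> list:
        """Non-control construct ids in column order, without duplicates."""
        out, seen = [], set()
        for s in self.data.columns:
            c = self.sample_construct[s]
            if bool(self.is_control.get(s, False)) or c in seen:
                continue
            seen.add(c)
            out.append(c)
        return out


@dataclass
class DEResult:
    """Per-gene differential-expression table for one construct vs control."""

    table: pd.DataFrame  # columns: log2fc, t, p, q, deg

    REQUIRED = ("log2fc", "t", "p", "q", "deg")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"missing column {col!r}")

    @property
    def deg_genes(self) -> pd.Index:
        return self.table.index[self.table["deg"].astype(bool)]

    @property
    def perturbation_size(self) -> int:
        return int(self.table["deg"].sum())


@dataclass(frozen=True)
class GeneSet:
    """Named gene set with an explicit exclusion list.

    ``excluded`` holds candidate regulators removed from score sums (e.g. the
    flagellar sigma factor is excluded from the flagellar-cluster score so
    that regulator ranking against the score is not circular).
    """

    name: str
    members: frozenset
    excluded: frozenset = frozenset()

    def __post_init__(self):
        if self.members & self.excluded:
            raise ValueError("members and excluded overlap")
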