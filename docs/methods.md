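# Methods

`rewirescope` analyses perturbation panels in which plasmid constructs fuse a
promoter regulatory region to a transcription-factor or sigma-factor open
reading frame (ORF), adding a new edge on top of a bacterial regulatory
network. This note describes the models and procedures the package
implements, the synthetic study generator used to validate them end to end,
and the numerical and design choices behind both.

## The synthetic study generator

Every downstream stage is exercised against simulated data with known ground
truth. The generator is first-class, tested code, and its defaults define the
study conditions used throughout the test suite and the acceptance script.

**Gold-standard network.** `simulate_gold_network` draws a directed
regulator→target network. Regulator out-degrees follow a power law
`P(K=k) ∝ k^(−a)` truncated at a maximum degree (defaults `a = 1.5`, max 600
at full scale), reproducing the hub structure of curated bacterial regulatory
databases. Edges carry a sign (+1 with probability 0.7) and a unitless weight
`U(0.5, 1)` on the log2 fold-change scale.

**Rewired constructs.** The default panel (`default_study`) has 3,891 genes
and 85 constructs — 77 promoter–ORF fusions and 8 promoter-only controls —
measured in biological triplicate against five control replicates, matching
the scale of a full rewiring compendium. Per construct:

- The ORF gene's fold change is log-normal. Published rewiring panels report
  self-upregulation of the rewired ORF spanning roughly 2- to 600-fold with a
  median near 13-fold; we treat that range as describing the *realized* fold
  change, promoter scaling included, and split the log-spread between the ORF
  draw and the promoter-activity distribution: the measured ORF log2FC is
  `log2(F) + log2(s)` with `ln F ~ N(ln 13, 1.226² − 0.6²)` and promoter
  strength `s ~ LogNormal(0, 0.6)`. A log-normal cannot match median 13 *and*
  1st/99th percentiles of exactly 2/600 (the log-midpoint of 2 and 600 is not
  13); we match the median exactly and the percentile span approximately.
- The *functional dose* driving downstream targets is `log2(F)·s`: ORFs
  largely set their own RNA levels, but the protein load a promoter delivers
  scales with its activity, so stronger promoters make disproportionately
  larger perturbations. This reproduces a positive association between
  promoter activity and perturbation size alongside the conserved fold range.
- The dose propagates breadth-first to network descendants, each edge
  transmitting `parent × attenuation × sign × weight` with attenuation 0.4,
  capped at depth 3 — beyond which attenuated contributions (≤ 0.4³ ≈ 6% of
  the source before weights) are negligible against replicate noise. The
  depth cap and attenuation are free parameters of the emulation, not
  inferred from data.
- About 20 latent co-expression states emulate attractor-like global
  responses. Each state has member genes, driver genes, a hard activation
  threshold on the summed induced driver level, and a direction. Above the
  gate the response magnitude is dose-dependent (proportional to the driver
  sum, saturating at 3× threshold) and each member responds with a
  heterogeneous nonnegative efficacy (multiplier `max(0, 1 + N(0, 0.75))`,
  drawn per member per construct). The graded response reflects the
  dose-dependent association between regulator levels and cluster expression
  seen in real panels; a purely binary response makes every antagonistic
  cluster member as score-correlated as the drivers themselves, which no
  correlation analysis could untangle. The two headline states are a
  125-member "ribosomal-like" up-state driven by three sensor genes wired
  downstream of ten hub regulators, and a 50-member "flagellar-like" state
  driven by one master regulator used in six constructs; the ribosomal
  drivers also repress the flagellar members, making the two states
  antagonistic.
- Replicates are `baseline + truth + biological noise + replicate noise`
  with baseline `N(8, 2)` per gene (log2 intensity scale), biological noise
  sd 0.05 shared across a construct's replicates, and replicate noise sd
  0.25. The true-DEG mask is `|true log2FC| > log2 1.2`, the fold-change arm
  of the calling rule.

**What the generator does not emulate.** No probe-level artifacts, no
normalization residue, no growth-rate feedback on expression, no correlated
(batch) noise, no promoter-sequence model. Promoter-only constructs are pure
nulls (the optional embedded-transcript channel is off by default), whereas
real promoter fragments occasionally carry expressed leaders. Passing the
recovery tests therefore demonstrates the statistical machinery under the
stated noise model, not robustness to array-specific artifacts. In
particular, the promoter-activity association emerges only through the dose
channel and is noisy at 25 promoters (R roughly 0 to 0.6 across seeds), and
the Kaiser component count at full scale (≈10) sits below the number of
planted states because small, rarely-activated states carry less than one
variable's worth of variance.

**Gaussian graphical model sampler.** `simulate_ggm` draws i.i.d. rows from
`N(0, Ω⁻¹)` where Ω has `−magnitude` at linked pairs and a diagonal inflated
to 1.1× strict dominance. Dominance guarantees positive definiteness at the
cost of realized partial correlations somewhat below `magnitude` for hubs;
`ggm_partial_correlations` exposes the realized values.

## Differential expression

Log2 fold change is the difference of replicate means on log2 scale. The
test is a two-sample pooled-variance t with optional empirical-Bayes variance
moderation: gene variances are modeled as exchangeable draws from a scaled
inverse-chi-squared prior, so `s_g²/s₀² ~ F(d_g, d₀)`; `(d₀, s₀²)` are
estimated by matching the first two moments of the observed variances, each
gene's posterior variance `(d₀s₀² + d_g s_g²)/(d₀ + d_g)` replaces `s_g²`,
and the null has `d₀ + d_g` degrees of freedom. Under-dispersed variance
distributions give `d₀ = ∞` (complete shrinkage); `shrink=False` recovers the
classical t exactly and is used for oracle comparisons. Benjamini–Hochberg
q-values use the step-up rule with `m` defaulting to the tested universe. A
gene is differentially expressed when `q < 0.05` and fold change `> 1.2`
(strict inequalities, applied to the observed log2FC); the DEG count is the
construct's perturbation size. Associations between perturbation size and
design covariates (promoter strength, ORF out-degree) are simple linear
regressions reported as Pearson R with the ANOVA F-test p-value,
`F = R²(n−2)/(1−R²)` on (1, n−2) df, computed on per-ORF or per-promoter
mean perturbations.

## State scores and regulator ranking

A gene-set state score is the per-construct sum of log2 fold changes over the
set's members; candidate regulators are excluded from the sum via an explicit
exclusion list (never inferred) so the subsequent ranking is not circular.
`rank_regulators` correlates every candidate gene's profile with the score
(Pearson by default, Spearman optional) and sorts by |R|, ties broken by gene
id; zero-variance profiles rank last with R = NaN. `variance_explained` is
the OLS R² of the score on a set of predictor profiles with intercept;
rank-deficient designs fall back to the least-squares pseudoinverse.
`antagonism` is the same correlation machinery for one gene pair over a
construct subset, used to quantify mutually exclusive states.

## Co-expression structure

**Clustering.** The uncentred correlation distance
`d = 1 − Σxy/(‖x‖‖y‖)` ∈ [0, 2] deliberately skips mean-centering: a flat
profile at zero shares no signal with a regulated one even if their shapes
match after centering. It is symmetric with `d(x, x) = 0` but does not
satisfy the triangle inequality. UPGMA (unweighted average linkage) is
delegated to `scipy.cluster.hierarchy.linkage(..., 'average')`, with raw
merge distances recorded and tree heights at half the merge distance; a
brute-force recomputation oracle guards the delegation in the tests. Leaf
ordering is deterministic, tighter-subtree-first (child of smaller height
first, ties by smallest leaf index). The display filter keeps genes
differentially expressed in ≥ 5 constructs with |Σ log2FC| > 4 — read as the
absolute value of the signed sum, not the sum of absolute values.

**ISA biclustering.** From random 10-gene seeds (200 by default), alternate:
construct scores = gene-set average of the column-standardized matrix, kept
at `|score| > 1.5·sd`; gene scores = construct-set average of the
row-standardized matrix, kept at `|score| > 2.1·sd`; iterate to a fixed point
(identical sets on consecutive iterations, max 50), discarding runs that die
out and fixed points smaller than 2×2 — a single gene or construct is not a
module. Fixed points are deduplicated at gene-set Jaccard ≥ 0.8, keeping the
most robust representative. Significance is a permutation filter: robustness
is the product of the gene- and construct-signature norms
`√Σg² · √Σc²` (a size-aware measure; the product of mean |scores| turned out
to rank two-by-two outlier coincidences above coherent planted modules), and
a module must exceed the maximum robustness found by an identical run on a
matrix with each gene's profile independently permuted — a null that
preserves per-gene marginals (including heavy tails) while destroying the
across-gene construct alignment that defines a module. With a single
permutation run this filter admits at most a stray spurious module on pure
noise; it has no analytic false-discovery guarantee. Genes enter ISA after
the prefilter |log2FC| > 0.25 in ≥ 3 constructs.

**PCA.** Variables default to constructs (an 85-variable correlation matrix
at full scale; with genes as variables the eigenvalue spectrum is degenerate
when genes ≫ samples). Zero-variance variables are dropped with a warning;
eigenvalues of the correlation matrix are clipped at zero; the Kaiser rule
retains components with eigenvalue strictly above 1, each thus explaining at
least one variable's worth of variance.

## Network inference by average non-rejection rates

With p genes and n ≪ p samples, partial correlations exist only for
conditioning sets of order `q < n − 2`. For a candidate pair, the
non-rejection rate at order q is the fraction of zero-partial-correlation
tests — `t = r√((n−q−2)/(1−r²))` against t with `n−q−2` df at level α = 0.05
— that fail to reject, over conditioning sets of size q drawn uniformly from
the other variables (exhaustively enumerated when there are at most `T`
subsets, else `T = 100` sampled without replacement). Partial correlations
come from inverting the correlation submatrix over `{i, j} ∪ Q`; perfectly
collinear pairs short-circuit to |r| = 1 (always rejected). A directly linked
pair keeps a nonzero partial correlation under every conditioning set and is
rejected almost always; an indirect association is explained away once the
conditioning set covers its mediators. The average NRR over a set of orders
(default q ∈ {1, 5, 10, 20, 30}; computing every order up to n−3 is
prohibitive beyond toy sizes, and a spread of orders preserves the
explaining-away behaviour — the full range remains available for small p)
ranks candidate regulator→gene pairs ascending, ties broken by gene ids.
Subset draws are seeded per (pair, q), so the table is invariant to pair and
order enumeration.

Note that a single pair's NRR under the null is nearly binary — the same
marginal correlation enters every subset test — so calibration statements
("NRR ≈ 1 − α") hold for the *mean over pairs*, which the acceptance checks
measure.

**Evaluation.** Walking down the ranking, a prediction is *eligible* when
both endpoints appear in at least one gold-standard interaction; a true
positive is a distinct undirected gold edge matched for the first time
(re-predicting a matched edge in the opposite orientation counts against
precision, not toward it). Precision = 100·TP/eligible, recall = 100·TP over
distinct undirected gold edges. `network_at_precision` cuts at the largest k
whose precision meets the nominal value and reports the edge set, node set
and connected components (modules, via networkx).

## Evaluation utilities

`fisher_enrichment` is the upper-tail hypergeometric probability (one-tailed
Fisher's exact test, "greater" only), delegated to `scipy.stats.hypergeom.sf`
and verified against coefficient-level enumeration in the tests.
`growth_rate` is `d(ln A595)/dt` by centered finite differences on a possibly
non-uniform time grid (one-sided at the endpoints), requiring strictly
increasing times and positive absorbance; no smoothing is applied before
differentiation.

## Pipeline and problem sizes

`run_pipeline` chains simulate → DE → scores → structure → inference →
evaluation with one seed controlling all randomness, writing TSV tables, a
JSON summary and a short report; re-running a config reproduces byte-identical
outputs. The default configuration runs simulation, DE, scoring and structure
at full study scale (3,891 × 85), clusters a variance-capped 400-gene subset
(full-matrix UPGMA is quadratic in genes), and runs network inference on a
reduced 30–36-variable planted model with n = 200 samples and q ∈ {1, 3, 5}:
an NRR sweep over every regulator × gene pair at full transcriptome scale is
a cluster-sized computation, and the reduced model exercises the identical
code path. The acceptance script uses the same sizes, plus a 15-variable /
10,000-sample null for calibration and ten 30-variable planted models for
edge-recovery summaries.

## Known limitations

- The moderated-t moment estimator is a simple two-moment fit; heavy-tailed
  variance distributions outside the scaled-F family push `d₀` toward its
  lower bound rather than failing gracefully.
- ISA significance is a stand-in permutation filter, not a calibrated test;
  the returned module count depends on seed count and the single-permutation
  threshold.
- The NRR ranking treats associations as undirected; regulator→target
  orientation is imposed by the candidate list, not inferred.
- Determinism is guaranteed for fixed seeds and library versions; BLAS-level
  differences may perturb partial correlations at the 1e-12 level, which can
  flip a test outcome only on razor-edge ties.
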