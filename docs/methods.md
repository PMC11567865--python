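# Methods

`peptinet` implements a multilayer signed partial-correlation network
analysis for targeted proteomics and neuropathology data, together with a
synthetic-data generator that provides ground-truth datasets of the same
shape as the motivating study design: 48 synaptic peptides, 4 SNARE
protein–protein interaction measures, 14 pathological (amyloid/tau)
peptides and 5 cellular-pathology densities measured on two physical-
activity groups of 220 subjects each.

## Network model

Measurements are modeled as a Gaussian copula: each variable is an unknown
monotone transform of a latent multivariate normal vector with sparse
precision matrix Θ.  The network of interest is the partial-correlation
graph

    w_ij = −Θ_ij / sqrt(Θ_ii Θ_jj),

an undirected, signed, weighted graph whose edges are conditional
dependence relations given all other variables.

Estimation proceeds in three steps:

1. **Nonparanormal transform.** Each column is Gaussianized by ranks: the
   value with (tie-averaged) rank k of m observed values maps to
   Φ⁻¹(k/(m+1)), rescaled to unit sample SD.  The k/(m+1) plateau is the
   standard shrunken-ECDF copula estimator; a Winsorized variant was
   considered and rejected because the shrunken form is already defined for
   every rank and is monotone-invariant, which the tests exploit.
2. **Pairwise-complete correlation.** Missing entries are handled by
   pairwise deletion (no imputation).  The resulting matrix can be
   indefinite; it is repaired by clipping eigenvalues at 1e−8 and
   re-normalizing to unit diagonal, with a logged warning.  The effective
   sample size passed downstream is the *minimum* pairwise-complete count —
   a conservative choice that guards against over-selection.  The transform
   is applied columnwise before correlation (transform-then-correlate); the
   alternative ordering is a known ambiguity of pairwise deletion and is
   noted for sensitivity analysis.
3. **Graphical lasso with EBIC selection.** The penalized problem
   max log det Θ − tr(RΘ) − λ Σ_{i≠j} |Θ_ij| is solved over a 100-point
   log-spaced λ grid from λ_max = max|R_ij| down to 0.01·λ_max, and the
   model minimizing EBIC = −2L + |E| log n + 4γ|E| log p with γ = 0.5 is
   selected.  |E| is counted on the penalized support (no refitting), the
   convention of the EBIC-glasso tooling this pipeline mirrors.

### Solver

The glasso subproblem is solved by ADMM: the Θ-step is the eigendecom-
position prox of −log det + tr(R·), the Z-step soft-thresholds the
off-diagonals (yielding exact zeros, which define the edge support), with
the standard adaptive-ρ schedule and warm starts along the λ path.
Default tolerance is 1e−6 on the scaled primal/dual residuals; the
permutation comparison uses 1e−4, which changes selected supports
negligibly while making tens of thousands of path fits affordable.  At
λ = 0 the analytic solution R⁻¹ is returned.  The solver is validated in
the test suite against an independent third-party implementation
(agreement ≈1e−10) and against closed-form inverses.

## Topology

Edge *lengths* are 1/|w_ij| (strong conditional dependence = short path).
Strength is Σ_j |w_ij|; expected influence is the signed sum Σ_j w_ij —
identical on all-positive networks, diverging when negative edges matter.
Closeness is 1/(Σ distances) within a node's connected component
(isolated nodes score 0); the "sum of reciprocal distances" (harmonic)
reading of closeness was considered and not used, matching the convention
of the psychometric network toolkits.  Betweenness is Brandes' algorithm
with fractional credit for tied shortest paths.  Hubs are nodes with
betweenness above mean + 2 sample SD.  Global connectivity is the sum of
absolute edge weights over unordered pairs; inter-layer connectivity
restricts that sum to pairs spanning two named layers, and the layer-pair
sums partition the global value exactly.  Diameter is reported under both
the 1/|w| and the hop-count conventions, because published values of this
quantity are often ambiguous about the convention.

Scale-free behavior is assessed on the strength (weighted degree)
distribution by the continuous power-law MLE with KS-minimizing x_min and
a semiparametric bootstrap p-value (large p = consistent with a power
law).  This is implemented in-package.

## Signed modules

Community detection runs on the synaptic-peptide-only re-estimated
network, not on the synaptic block of the multilayer fit.  The objective
is the signed Reichardt–Bornholdt Hamiltonian with configuration-model
nulls for the positive and negative parts (γ⁺ = γ⁻ = 1); optimization is
igraph's negative-weight spinglass simulated annealing, seeded through
Python's `random` module for determinism, best of 20 restarts by the
in-package Hamiltonian.  Module labels are canonicalized by descending
size, ties by smallest node index.  Reported alongside: the Gómez signed
modularity (weighted difference of positive- and negative-part Newman
modularities; the positive-part value is emitted too, since published
modularity values rarely state which variant they are), and transitivity
(3 × triangles / connected triples on the unweighted support).

## Structural balance

A triangle is balanced iff the product of its three edge signs is
positive.  Balance is computed on the estimated sparse support — triples
with an absent edge are not triangles — and only signs, not magnitudes,
enter the classification.  The unbalanced list is returned for motif
inspection (e.g., triangles touching the p-tau hub nodes).

## Group comparison

Subjects are split at the median of average daily actigraphy counts;
ties go to the lower group (a deterministic rule the "greater
than/less than median" wording leaves open).  Networks are estimated
independently per group and compared on: global connectivity, per-edge
weights over the union support of the two observed networks, per-node
strength, and per-layer-pair inter-layer connectivity.  The null
distribution reshuffles group labels (sizes preserved) and re-runs the
*entire* estimation pipeline — transform, correlation, EBIC-glasso — in
every permutation; re-estimating anything less inflates type-I error.
Two-sided p-values use absolute differences with the add-one correction
p = (1 + #{perm ≥ obs})/(n_perm + 1).  Holm–Bonferroni is applied within
the edge family and, separately, the centrality family.  Note the
arithmetic consequence of the add-one correction: the smallest attainable
p is 1/(n_perm+1), so Holm can only ever reject at family size m if
n_perm + 1 ≥ m/α.  Permutations whose estimation fails are redrawn; more
than 1% failures aborts the test.

## Network-informed regressions

Module scores are per-subject means of member columns (missing skipped).
Module–cognition associations are one OLS model per module:
cognition ~ score + age + sex + education, listwise deletion.  The
three-way moderation model regresses tangle burden on two p-tau peptides,
a synaptic module score and continuous activity, all implied two-way
products and both three-way products; predictors are mean-centered before
products are formed (centering changes lower-order terms'
interpretation but provably not the three-way coefficient, which a test
verifies numerically).  No additional covariates enter by default;
age/sex/education can be supplied.

## Synthetic data generator

The generator works backwards from a designed partial-correlation matrix
W̃.  The precision matrix realizing it is obtained by the fixed-point
iteration θ_ii = 1 + Σ_j |θ_ij|, θ_ij = −w̃_ij √(θ_ii θ_jj), which
converges whenever every row of |W̃| sums below 1 and produces a strictly
diagonally dominant (hence SPD) Θ whose implied partial correlations equal
the designed ones to machine precision.  Plain diagonal dominance alone
would preserve only the sign pattern while shrinking magnitudes; the fixed
point preserves both.  The row-sum bound is not an artifact: a node cannot
carry many strong partial correlations simultaneously (for an
equicorrelated k-clique, SPD forces |w| < 1/(k−1)), so realistic modules
concentrate strength in few edges per node.  Modules are therefore wired
as strong rings (each member two edges drawn from 0.30–0.42) plus weaker
chords, a design under which EBIC-glasso recovery is informative at the
study's sample sizes (pooled-sample F1 ≈ 0.75–0.82; per-group estimates at
n = 220 are visibly sparser — an honest reflection of what halving a
cohort does at p = 71).  Rows exceeding an 0.85 absolute-sum budget are
scaled down; budget for group-specific edges is reserved *before* capping
so their planted magnitudes survive exactly.

Defaults mirror the study conditions: 220 subjects per group; layers
48/4/14/5; six synaptic modules with 4–14 members; ten negative
between-module edges placed among the three large modules; one broker hub
node with spokes into every module (the small modules reach the rest of
the synaptic layer only through it, giving the hub unambiguous betweenness
centrality); a handful of inter-layer edges (positive synaptic↔PPI,
negative synaptic↔pathology, positive pathology↔cellular pathology); one
negative synaptic-to-p-tau edge (w = −0.4) present only in the
low-activity group; monotone marginal distortions (exp on 8 columns, cube
on 4); 5% MCAR missingness.  Activity counts are lognormal with moments
matched to the cohort's published mean 1.94, SD 1.14 (units: mean daily
counts ×10⁵); the high/low groups are defined by the realized median, so
the pipeline's median split reproduces the generating labels.  Cognition
is a weighted sum of standardized module means (weights 1.7 on module 2,
0.5 on module 1, matching the magnitudes reported for the cohort) plus
unit-SD noise.  Tangle burden follows the planted linear model with main
effects 1.08 / −0.97 / −1.11 (p-tau1 / p-tau2 / module), three-way
coefficient 0.65 on p-tau1 × module × activity, and noise SD 8 — chosen so
the three-way coefficient's standard error at n = 440 sits near 0.33, the
uncertainty scale of the reference analysis.

What the generator does *not* emulate: mass-spectrometry noise physics,
batch effects, informative missingness, longitudinal actigraphy
trajectories, or non-Gaussian tail dependence beyond what monotone
marginals induce.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the Gaussian-copula
assumption, not robustness to violations of it.

## Numerical choices and degenerate inputs

Edges with |w| ≤ 1e−12 are treated as absent everywhere (triangle and
degree counts need a crisp support).  Node order is fixed at load time and
preserved through all stages.  Constant columns, non-positive ratios
before log-transform, rank-deficient design matrices, all-identical
activity values, empty modules and unknown node ids raise named errors;
networks with no triangles report balance as missing with a warning
rather than NaN arithmetic.  Fruchterman–Reingold coordinates are computed
on |W| with a fixed seed and stored as node attributes so plots are
reproducible.

## Problem sizes used in the checks

The test suite exercises the permutation comparison at 10–12 nodes with
100–499 permutations (scaled down from the 10,000 of a full analysis run;
the procedure is identical, only the grid sizes differ), EBIC recovery at
p = 20 / n = 440 over 20 replicates, moderation coverage over 500
replicates, and one full 71-node end-to-end run with 100 permutations.
`scripts/acceptance.py` re-runs the complete default study once with 200
permutations.

## Known limitations

- EBIC(γ = 0.5) at n ≈ 220 and p = 71 is deliberately conservative; some
  per-group networks select few or no edges for unlucky seeds.  This is a
  property of the criterion at these sizes, not a solver failure.
- The spinglass optimizer requires a connected graph; detection runs on
  the largest component and leaves other components as their own modules.
- Balance, hub and module statistics are computed on point-estimate
  networks; no edge-stability bootstrap is provided.
- The permutation test assumes exchangeability of subjects under the
  null; covariate-adjusted network comparison is out of scope.
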