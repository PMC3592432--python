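# Methods

## Model

A pathway is a directed gene–gene graph. After topology preprocessing
(below) it becomes an undirected graph *G* on *P* genes, and the two
phenotype classes are modelled as graphical Gaussian models sharing *G*:

    class k:  x ~ N_P(mu_k, Sigma_k),   K_k = Sigma_k^{-1} in S+(G),  k = 1, 2

where S+(G) is the set of symmetric positive-definite matrices whose
entries vanish for every non-adjacent pair of *G*. Zeros of the
concentration matrix encode conditional independence given all other
genes, so *G* carries the pathway's topology into the likelihood.

The analysis asks two questions per pathway (step 1) — are the
concentration matrices equal (*K1 = K2*, "homoschedasticity"), and are the
mean vectors equal (*mu1 = mu2*)? — and then localizes the signal
(step 2) by scoring chains of cliques along the junction tree of *G*.

## Topology pipeline

1. **Self-loop removal.** Edges (v, v) are dropped.
2. **Cycle breaking.** Directed cycles are detected one at a time
   (deterministic DFS over lexicographically sorted nodes) and resolved by
   deleting the cycle edge whose endpoint expression profiles have the
   smallest absolute Pearson correlation, pooled over all samples of both
   classes. Pooling avoids class-dependent topology; absolute correlation
   treats strong negative co-expression as strong evidence for the edge.
   Only edges on some directed cycle are ever removed. If every
   correlation in a cycle is undefined (zero-variance genes) the run
   aborts with a diagnostic.
3. **Moralization.** Parents sharing a child are joined and directions
   dropped; the result is *G*.
4. **Triangulation.** Greedy minimum-fill with lexicographic tie-breaks.
   Min-fill keeps maximal cliques small, and the largest clique bounds the
   sample size at which clique-marginal covariances are estimable.
5. **Cliques and junction tree.** Maximal cliques of the triangulated
   graph; maximum-weight spanning tree on separator cardinality (Kruskal,
   lexicographic tie-break), which guarantees the running intersection
   property for chordal graphs. The root is the clique reached first along
   the maximum cardinality search (MCS) ordering, MCS starting from the
   lexicographically smallest node.

Disconnected moral graphs are split into connected components and each
component (≥ 2 genes) is analyzed as its own pathway component;
single-gene components are logged and skipped. All tie-breaks are
lexicographic, so the whole pipeline is a pure function of its inputs.

The zero pattern actually fitted is that of the **triangulated** graph:
the clique machinery requires chordality, and fill-in edges act as free
parameters. This is slightly more permissive than constraining to the
moral graph itself; with typical pathway graphs the difference is a few
fill-in entries.

## Estimation when P ≥ n

The unbiased sample covariance *S* is shrunk toward its diagonal,

    S* = lambda * diag(S) + (1 - lambda) * S,

with the analytic optimal intensity (ratio of the summed estimated
variances of the off-diagonal entries to their summed squares, clipped to
[0, 1]) re-estimated from whatever data enter a given fit. Variances are
left unshrunk. The result is positive definite whenever lambda > 0, which
covers every P > n case in practice.

The shrunken covariance is projected onto S+(G) by iterative proportional
scaling (IPS): starting from the independence model K = diag(1/S*_ii),
each clique step adds `inv(S*_CC) − inv(Sigma_CC)` to the corresponding
block of K, making the fitted covariance match S* on that clique. Sweeps
stop when the fitted covariance changes by less than `tol = 1e-8` (max
absolute entry) or after `max_iter = 5000` sweeps (then flagged
non-converged). For decomposable graphs — always the case here, as IPS
runs on the triangulation — a couple of sweeps reach the fixed point, and
the result equals the closed-form decomposable MLE assembled from clique
and separator blocks; the test suite verifies this equivalence to 1e-6 on
random decomposable graphs.

Profile log-likelihoods are computed as `(n/2)(log det K − tr(K S))`; the
`−(nP/2) log 2π` constant is dropped everywhere since only differences are
used.

## Step-1 tests

Shrinkage invalidates the asymptotic chi-square calibration of the
likelihood-ratio statistics, so every p-value is a permutation p-value:
class labels are permuted with a seeded generator, every quantity —
including the shrinkage intensity — is re-estimated within each
permutation, and the add-one estimator `p = (1 + #{perm ≥ obs}) / (B + 1)`
is reported (never zero; granularity 1/(B+1)). One permutation stream per
pathway calibrates all statistics (common random numbers). Default
B = 1000 for analyses; the simulation studies use B = 500.

Statistic forms (any monotone-equivalent form is valid under permutation
calibration; these are the ones implemented):

* **Concentration test.** `2[ l1(K̂1; S1) + l2(K̂2; S2) − (l1(K̂w; S1) +
  l2(K̂w; S2)) ]` where S1, S2 are class-centered shrunken covariances,
  K̂1, K̂2 their IPS fits, and K̂w the IPS fit to the pooled within-class
  shrunken covariance.
* **Mean test, homoschedastic variant.** `2[ l(K̂w; Sw, n) − l(K̂0; S0, n) ]`
  with Sw the class-centered and S0 the grand-mean-centered pooled
  shrunken covariance: the likelihood gain from allowing separate means
  under a common graph-constrained concentration.
* **Mean test, heteroschedastic variant.** The Behrens–Fisher-type
  quadratic form `d' (Σ̂1/n1 + Σ̂2/n2)^{-1} d` with d the difference of
  class means and Σ̂k the class IPS fits.
* **Variant selection.** The heteroschedastic variant is reported when the
  pathway's concentration test rejects at alpha, the homoschedastic one
  otherwise.
* **Clique tests.** The same concentration statistic on the clique's
  sub-data with a complete graph, i.e. shrunken covariances inverted
  directly, no IPS. A single-gene clique reduces to a two-sample variance
  LRT through the same formula. The per-clique shrinkage intensity is
  re-estimated on the clique sub-data.

Across pathways (and pathway components), mean and concentration p-values
are Bonferroni-adjusted separately. Step 2 runs on components whose
adjusted p-values are both below 0.05 (configurable: `always` / `never`).

## Step-2 scoring

Clique weights w are the clique-level concentration-test p-values (a
`mean` source is available as a config override); a clique is
*meaningful* when w < alpha (strict), default alpha = 0.05. Along each
root-to-leaf path, candidate sub-paths are (a) every maximal run of
consecutive meaningful cliques and (b) for each pair of runs separated by
exactly one non-meaningful clique, the bridged segment — both
granularities are kept as candidates.

Scoring (all formulas live on one `ScoringPolicy` object so an
alternative convention replaces a single code site):

    o_0 = 0,   o_i = o_{i-1} + (1 − 2 w_i),
    r  = max_i o_i,   m = first position attaining r,
    r* = r / m.

A weight of 0.5 is neutral; small weights push the running score up. Per
path the candidate with maximal r* wins (ties: longer sub-path, then
earlier start). Winners from different paths are de-duplicated and
collapsed: average-linkage hierarchical clustering of the dissimilarity

    d(A, B) = min(|A \ B| / |A|, |B \ A| / |B|)

(gene sets; nested sets get d = 0) cut at height t = 0.2, each cluster
represented by its maximum-r* member. Because no agglomerative cut bounds
*cross*-cluster pairs, a final greedy pass (best r* first) drops any
representative within d ≤ t of an already-kept one, so reported
representatives are pairwise more dissimilar than t.

## Synthetic data

`random_ggm` builds a concentration matrix on a given graph by assigning
random magnitudes in [0.1, 0.4] with random signs to edge entries and
setting each diagonal to the absolute row sum plus a conditioning constant
(0.1), so off-graph zeros are exact and the minimum eigenvalue is bounded
below by the conditioning constant (Gershgorin). Scenarios draw n1 and n2
samples from the two models with seeded generators; a master seed spawns
per-run substreams, so every run is independently reproducible.

The default study graph has 12 genes and a chain junction tree of 5
cliques (sizes 4, 4, 3, 3, 3; separators of 2, 1, 1, 1 genes), with
n1 = n2 = 20: small enough to simulate thousands of runs on one CPU,
large enough for multi-clique signal paths. The null study (1000 runs,
B = 500) draws both classes from the same freshly sampled model per run
and records rejection rates and top sub-path lengths; the alternative
study flips the sign of edge partial correlations inside two target
cliques and shifts their genes' means by 5 marginal standard deviations
(n = 50 per class), recording how often the selected sub-path overlaps the
targets.

The generator emulates exactly the model the tests assume: Gaussian data,
exact graph-constrained concentrations, exchangeable samples. It does not
emulate microarray or sequencing noise (probe effects, normalization
artifacts, heavy tails, outliers), gene-level correlation with unmodelled
covariates, or misspecified topologies, so passing simulations demonstrate
calibration and recovery under the model, not robustness to violations of
it.

## Numerical and degenerate-input choices

* IPS: `tol = 1e-8`, `max_iter = 5000`; non-convergence flagged per fit,
  and a pathway run aborts when more than 1% of its permutation fits fail
  to converge.
* Zero-variance genes abort shrinkage and cycle-breaking with named
  diagnostics.
* Single-clique junction trees yield one degenerate path of length 1.
* A path without meaningful cliques contributes no sub-path; a run where
  no path has one reports an empty result (top length 0).
* Statistics can dip microscopically below zero because the shrinkage
  intensities of the null and alternative fits differ; permutation
  calibration is unaffected.
* All user-facing randomness is a single integer seed; seeds derived
  internally stay below 2^31.

## Limitations

* The fitted zero pattern is the triangulated graph's, not the moral
  graph's (see above); heavily cyclic pathways acquire fill-in.
* Junction-tree roots and hence the path set depend on the MCS tie-break;
  a different root can re-partition sub-paths (representatives are
  typically stable because pruning collapses overlaps).
* The permutation tests assume exchangeable samples under the null —
  batch structure or covariates are not modelled.
* Clique weights lose their p-value interpretation once used as scores;
  relevance is an empirical ranking device, not an inferential quantity.
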