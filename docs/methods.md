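# Methods and design notes

## Scope and data model

`rhizonet` covers the statistical chain of a factorial rhizosphere
microbiome study downstream of ASV calling and taxonomic assignment: raw
taxon-by-sample integer counts in, normalized tables, diversity profiles,
distance-based tests, co-occurrence networks with topology summaries,
phenotype–taxon networks, and a composite-centrality prioritization report
out. Raw counts and normalized abundances are distinct types (`CountTable`
vs `NormalizedTable`) so a table can never be normalized twice. All
artifacts follow one canonical sample order (lexicographic by sample id),
which makes outputs byte-reproducible regardless of input ordering.
Samples with no positive counts (failed libraries, or extreme synthetic
draws) are dropped explicitly via `CountTable.drop_empty_samples`, with a
logged warning; CSS normalization refuses all-zero samples by contract.

## Normalization and diversity

**CSS.** For sample *j* with positive counts *x*₍₁₎ ≤ … ≤ *x*₍ₙ₎, the
quantile value is the nearest-rank *l*-quantile *q* = *x*₍⌈l·n⌉₎ (default
*l* = 0.5), the scaling factor is the sum of all counts ≤ *q*, and values
are rescaled to a common constant (default 1000). The quantile is fixed
rather than chosen by the adaptive instability search of the original CSS
method: the adaptive search is ill-behaved on small tables and makes runs
depend on the data in a way that is hard to document; a fixed, overridable
*l* is deterministic. CSS preserves zeros and within-sample rank order.

**α-diversity.** Chao1 uses the bias-corrected form
S_obs + f₁(f₁−1)/(2(f₂+1)), defined even when there are no doubletons;
Shannon H in nats; Simpson as 1 − Σp²; Pielou J = H/ln S_obs, undefined
(NaN) for fewer than two observed taxa. An all-zero sample is a contract
violation for the profile and NaN for Chao1 alone.

**Distances and PERMANOVA.** Bray–Curtis Σ|x−y|/Σ(x+y), Euclidean, and
Jaccard on presence/absence (whether abundance-weighted Jaccard was meant
is genuinely ambiguous in the field; the binary choice is recorded in the
distance matrix's `metric_tag`). PERMANOVA is the one-factor pseudo-F test:
SS_total = (1/n)Σ_{i<j}d²ᵢⱼ, SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ,
F = (SS_B/(a−1))/(SS_W/(n−a)). Permutations shuffle labels only within
strata when a stratum factor (field block) is supplied, so spatial
heterogeneity can never masquerade as a treatment effect. The p-value uses
the (1 + exceedances)/(1 + n_perm) estimator, never exactly zero; an exact
mode enumerates all distinct label arrangements (within strata) for small
n, where p is the plain exceedance fraction. Multi-factor models with
interactions are out of scope; factors are tested one at a time.
SS_W = 0 reports an infinite F with a permutation p rather than crashing.

**SIMPER.** Per taxon, the mean over between-group sample pairs of
|x_ij − x_ik| / Σ_t(x_tj + x_tk). Absolute contributions sum exactly to the
mean between-group Bray–Curtis dissimilarity (asserted to 1e-10 in tests);
permutation p-values use the same (1+c)/(1+n) estimator.

## Co-occurrence networks

Associations are computed for every unordered taxon pair: Spearman as the
product-moment correlation of average ranks, Pearson directly; two-sided
p-values from the t approximation with n−2 df (r = ±1 maps to p = 0); BH
q-values over all pairs tested in the run, so FDR is controlled within
each network's own association family (global or condition-specific).
Zero-variance taxa are excluded from testing with a logged warning. Edges
require |coefficient| > 0.6 **and** q < 0.05; since q ≥ p, the nominal
p < 0.05 screen is implied. Nodes are only the endpoints of retained
edges — isolated taxa are not network members, which is what makes the
degenerate published networks (all nodes degree ≥ 2) reproducible.

Topology metrics and their conventions:

- **Centralization** (Freeman): Σ(d_max − d_i)/((N−1)(N−2)); 0 by
  convention (logged) below three nodes. Zero for regular graphs, one for
  a star.
- **Walktrap communities**: Pons–Latapy random-walk agglomeration
  (python-igraph, walk length 4), run per connected component with the
  merge tree cut at maximum modularity, so components never share a
  community and the component count is never violated by the partition.
- **Modularity**: Q = Σ_c[m_c/m − (D_c/2m)²]; NaN for edgeless graphs.
  For c disjoint equal cliques under the clique partition Q = 1 − 1/c,
  which is how the two- and three-triangle fixtures pin 0.50 and 0.67.
- **Hub scores**: for a symmetric adjacency matrix the Kleinberg hub
  vector (dominant eigenvector of AAᵀ) coincides with the dominant
  eigenvector of A. It is computed by power iteration on A + I — the
  shift leaves eigenvectors unchanged and prevents oscillation on
  bipartite components — from the uniform start, sup-norm scaled
  (tolerance 1e-10). Iterating A² directly was rejected: its dominant
  eigenspace is degenerate on stars (eigenvalue 3 with multiplicity 2),
  where the uniform start freezes at all-ones instead of the
  (1, 1/√3, 1/√3, 1/√3) hub vector. On graphs whose components share the
  spectral radius (e.g. disjoint equal triangles) the uniform start
  converges to the symmetric all-ones limit. Hubs are nodes with score
  strictly above 0.2. Edge signs are ignored by all topology metrics.
- **Power-law fit**: discrete (zeta) maximum likelihood per candidate
  xmin, the xmin chosen to minimize the KS distance between empirical and
  fitted tail CDFs. The fit is reported undefined — not NaN-propagated —
  when fewer than two distinct degree values exist, which reproduces the
  published "NA" entries for regular networks.
- **Friedman rank test**: tie-corrected χ² on average ranks across
  methods within conditions, k−1 df; implemented in-package because the
  scipy routine requires at least three groups while two association
  methods must be comparable. Completely tied data return (0, 1).

## Phenotype–taxon networks and prioritization

Lasso (scikit-learn `LassoCV`, penalty at the minimum cross-validated MSE,
seeded fold assignment, internally standardized predictors) selects
phenotype-predictive taxa; the 1-SE rule was not used — the minimum-MSE
rule is the package's documented choice. An OLS refit with intercept (the
Gaussian identity-link GLM appropriate for continuous edaphic/agronomic
measures) supplies per-taxon coefficient, sign, and t-test p; collinear
columns are dropped left-to-right, and an over-wide selection is truncated
to the strongest lasso coefficients (logged). Phenotype edges are overlaid
on the supplied co-occurrence network; taxon–taxon edges are copied
verbatim and never invented.

Node roles follow the Guimerà–Amaral conventions: within-module degree
z-score with the population standard deviation and z = 0 for zero-spread
or singleton modules, and participation coefficient 1 − Σ(κ_is/k_i)² with
P = 0 for isolated nodes. The module partition comes from Walktrap on the
taxon–taxon subgraph; the phenotype node is excluded because the roles
describe microbial structure. Each of (z, P, hub) is min–max normalized
across the network's nodes — a metric constant across nodes maps to 0.5
everywhere so an uninformative metric pushes no node to either extreme —
and the composite is their unweighted mean. Prioritization filters to
prevalence ≥ 0.2, ranks by mean composite over the networks where a taxon
appears (appearance count reported; a zero-filled mean over all networks
is reported alongside, since either averaging convention is defensible),
and breaks ties by descending prevalence then identifier.

## Synthetic data

The generator emulates the study design the pipeline targets: 64 samples
as a 2 treatments × 2 cultivars × 4 growth stages factorial replicated in
4 field blocks (any multiple of 16 samples is accepted; the block count
scales), with genus-level eukaryote and species-level prokaryote taxon
panels.

Counts are drawn through a Gaussian copula with negative-binomial
marginals: a latent normal vector per sample with identity correlation
except on planted pairs (non-positive-definite plantings are a hard error
naming the pairs), plus a per-block scalar offset with sd `block_sd`;
the normal CDF maps latents to uniforms; the NB quantile function (mean
`nb_mean` = 50, dispersion `nb_dispersion` = 0.2) maps uniforms to counts.
Because every step is monotone, planted latent correlations survive as
rank correlations — exactly the quantity Spearman-based inference
estimates. With these defaults the NB's own at-zero mass is ≈ 35%, so most
sparsity arises inside the copula and is rank-preserving. An independent
Bernoulli mask then zeroes cells to reach `prevalence_target` (0.65) in
expectation; the keep-probability accounts for the block offset inflating
the latent marginal variance. At the defaults the natural zero mass
already exceeds the target's complement, so the mask is clamped off; it
engages when a sparser target is configured, and its rank-destroying
attenuation is a measured property of such configurations, not an assumed
one. Block effects enter both counts (latent shift) and phenotypes
(additive offset) so stratified permutation machinery is genuinely
exercised.

Phenotypes are Σ effect × log1p(count) over planted taxa plus the block
offset and Gaussian noise. The published interface takes the count table
and config; block offsets require the metadata, so it is an optional third
argument and offsets are zero when omitted.

`hub_scenario_config` plants a keystone: one taxon correlated (latent
0.85) with two tight three-taxon blocks (within 0.9). Positive
definiteness forces the cross-block correlation up to at least
2·0.85² − 1 ≈ 0.445; it is set to 0.55, whose attenuated rank correlation
sits well below the 0.6 edge threshold, so the keystone's bridging role
survives inference. Stronger hub-spoke values were rejected because the
PD floor then pushes cross-block rank correlations into the threshold
region and the realized network degenerates into a near-clique with tied
composite scores.

**What the generator does not emulate.** Compositional coupling between
taxa induced by sequencing depth (beyond a per-sample NB mean), taxonomic
assignment error, chimeras/contamination, phylogenetic correlation
structure, and overdispersion heterogeneity across taxa. Tests passing on
this generator therefore certify the statistical machinery — thresholds,
FDR control, permutation restriction, recovery of planted monotone
dependence — not robustness to compositionality artifacts, for which
dedicated inference methods exist and are out of scope.

## Numerical choices

- Permutation p-values are never 0: (1 + count)/(1 + n_perm).
- BH q-values use the step-up with enforced monotonicity, order-preserving.
- Power-law α is bounded in (1, 12] for the bounded scalar optimizer.
- HITS power iteration: tolerance 1e-10 in sup norm, max 10⁶ iterations.
- Bray–Curtis/Jaccard between two all-zero samples is defined as 0 with a
  logged warning.
- The pipeline expands one global seed into per-stage substreams via
  seed-sequence spawning, recorded in the run manifest, so stages rerun in
  isolation reproduce; manifests carry SHA-256 hashes of every artifact.

## Problem sizes in the test suite

The bundled experiments use desk-scale communities — 30–100 taxa, the
64-sample design, 20–100 seed replicates, 199–9999 permutations — chosen
so the full chain, including cross-validated lasso and permutation tests,
demonstrates its calibration claims (type-I error 0.05 ± 0.02,
precision/recall ≥ 0.9, exponent recovery ± 0.3) with comfortably
significant replicate counts.

## Known limitations

- PERMANOVA is single-factor (with strata); interaction terms require an
  external mixed-model workflow.
- Walktrap is a heuristic: it optimizes modularity only over its merge
  tree. It matches exhaustive search on the small structured graphs in the
  test oracle but carries no global guarantee.
- On disconnected graphs whose components have unequal spectral radii,
  hub scores concentrate on the dominant component (matching the standard
  eigenvector-centrality behavior); hub counts then describe that
  component only.
- Lasso selection with the minimum-MSE rule can admit a few noise taxa in
  any single run; the null-calibration guarantee is about the median over
  runs.
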