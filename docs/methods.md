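# Methods

This note documents the statistical models implemented in `otunet`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Synthetic communities

The generator produces an OTU count table over a factorial field design:
three habitats along a thaw gradient (palsa, bog, fen), six plant species
each restricted to the habitats where it grows, three compartments
(phyllosphere, rhizosphere, bulk peat), three sampling months, and three
locations. One sample is generated per (month, location, habitat,
plant-in-habitat, compartment) cell; bulk peat is sampled adjacent to each
plant so that peat samples carry a plant label and the plant factor is
estimable in every compartment.

Per sample *s* and OTU *k* the log basis abundance is

    z[s,k] = mu_k + b_hab[h(s),k] + b_plant[p(s),k] + b_comp[c(s),k]
           + b_month[m(s),k] + eps[s,k]

with `mu_k ~ N(0, basis_sd²)`, each factor effect drawn per level from
`N(0, sd_factor²)`, and `eps` unit-variance Gaussian noise. Defaults:
`basis_sd = 1.5` (a realistic log-normal spread of mean abundances,
yielding rank-abundance curves dominated by a few taxa), `habitat_sd = 0.8`,
`plant_sd = compartment_sd = 0.5`, `month_sd = 0.1` (habitat as the
strongest driver, season nearly null). Counts are a multinomial draw of the
sample's depth — uniform on 2,000–20,000 reads — from `softmax(z[s,:])`:
the compositional closure that the correlation stage must undo.

Correlation ground truth is planted in `eps` *before* closure:

* **Planted pairs** share a latent factor scaled so that
  `corr(eps_i, eps_j) = planted_rho` (sign supported). This is the signal a
  compositionality-robust estimator should recover and naive
  Pearson-on-proportions should distort.
* **Hub OTUs** split their latent variance equally across `hub_degree`
  partner OTUs: hub–partner correlation is `planted_rho/sqrt(hub_degree)`
  and partner–partner correlation is ≈ 0. The naive alternative — one
  factor shared by hub and all partners — gives partner–partner correlation
  `planted_rho²`, which makes every partner as connected as the hub and
  destroys the very degree asymmetry a hub is supposed to have. A hub here
  is an organism moderately correlated with many otherwise-unrelated
  partners, which is the network pattern a keystone detector must find.

`generate_community` realizes the factorial design; `generate_basis_table`
generates a flat `n_samples x n_otus` table (optionally with a single
grouping factor, a dominant OTU, pairs, and hubs) for calibration and
recovery studies where a specific flat sample size is needed.

Taxonomy strings follow the 7-rank `k__;p__;c__;o__;f__;g__;s__`
convention. A configurable fraction of OTUs (defaults 5% / 8%) receives
methanogen order or methanotroph family/order lineages so functional-group
subsetting is exercised; the remainder get generic lineages drawn from the
common soil phyla.

What the generator does **not** emulate: read-level artifacts (chimeras,
primer bias, the under-detection of Archaea by common 16S primer sets),
overdispersion beyond multinomial, sample-to-sample depth correlation,
phylogenetic signal in abundances (the random coalescent-style tree is
independent of the abundance model), and spatial autocorrelation between
locations. Passing tests therefore demonstrate correctness of the methods
under a clean compositional log-normal world, not robustness to every
artifact of real amplicon data.

## Filtering and rarefaction

* Organelle removal: case-insensitive substring match for "chloroplast" /
  "mitochondria" anywhere in the lineage.
* Rarefaction to 1,000 reads per sample by uniform subsampling without
  replacement (multivariate hypergeometric); samples below depth are
  dropped, because unequal depth defeats the purpose. Used for the
  distance/ordination/variance branch.
* Network prefilter: keep OTUs with ≥ 10 total counts **and** presence in
  ≥ 3 samples (both conditions conjunctive). The network branch runs on
  **un-rarefied** counts: rarefaction deletes low-abundance organisms whose
  importance exceeds their abundance, which is exactly the signal keystone
  analysis is after.

## Compositional correlations

Log-ratio variances `t_ij = Var_s[log(f_i/f_j)]` are computed from the
covariance identity `t_ij = v_i + v_j − 2c_ij` (sample covariances,
ddof=1). Under approximate sparsity of the true correlation matrix the
basis variances solve `(diag(d) + A) w² = (t∘A)·1` with `A` the
pair-inclusion indicator; then `ρ_ij = (w_i² + w_j² − t_ij)/(2w_iw_j)`,
clipped to [−1, 1]. The most strongly correlated pair with |ρ| above the
exclusion threshold (default 0.1) is removed from the system and the
variances re-solved, up to `max_exclusions` pairs (default 10% of all
pairs); exclusion also stops if it would leave a node with fewer than two
included partners. Each exclusion is a symmetric rank-one downdate
`M → M − (e_i+e_j)(e_i+e_j)ᵀ`, so the inverse is maintained by a
Sherman–Morrison update (O(D²) per exclusion instead of O(D³)); the update
is validated against a from-scratch solve in the test suite. Non-positive
basis-variance solutions are floored at 1e−6 (log-scale variance units).
Fewer than 4 OTUs leaves the system under-determined and raises an error
recommending plain Pearson at that scale.

The point estimate is the elementwise **median of 20 passes**, each pass
drawing sample fractions from the add-one Dirichlet posterior of the
counts (the standard zero-replacement for log-ratio methods). The median
suppresses the Dirichlet jitter; the test suite verifies that the
median-of-20 estimator has lower across-seed variance than a single pass
on fixed data.

**Permutation p-values.** Each of 100 null replicates destroys association
by permuting each OTU independently across samples, and is estimated with
the *same* median-of-20 estimator as the observed matrix;
`p = (1 + #{|ρ_null| ≥ |ρ_obs|})/(n_boot + 1)` (two-sided, add-one so p is
never 0). Two design details matter for calibration:

* Null replicates use the same number of estimation passes as the observed
  estimate (`n_iter_boot` defaults to `n_iter`). A cheaper 1-pass null has
  systematically wider dispersion than a median-of-20 observed statistic,
  which makes the p-values conservative; matching the estimators restores
  exchangeability. `n_iter_boot` remains a config switch for users who
  accept conservative p-values in exchange for a 20× faster bootstrap.
* The permutation is applied to each OTU's **posterior fractions**, not its
  raw counts. With heterogeneous sequencing depths, permuting counts
  detaches each value from its own sample's depth-dependent sampling noise
  and inflates the null log-ratio variances (again conservative).
  Fraction-level permutation preserves each OTU's marginal log-abundance
  distribution exactly — the intended null of "no association, same
  marginals" — and needs no renormalization because log-ratio variances
  are invariant to per-sample scaling.

## Networks, PageRank, keystones

Edges are OTU pairs with `p < alpha` (strict, default 0.05); the weight is
|ρ| and the sign is stored for reporting only — a strong negative
association binds a network as much as a positive one. Isolated nodes stay
in the node set so every filtered OTU has a score.

PageRank is computed by power iteration on the undirected weighted graph:
transition probability proportional to edge weight, damping d = 0.85 (the
standard default), teleport share (1−d)/N to every node, dangling
(isolated) nodes redistributing their mass uniformly; convergence is L1
change < 1e−10, and scores sum to one. Betweenness and closeness use
shortest paths with length 1/weight (strong correlation = short path),
unnormalized; closeness is the inverse mean distance within the node's
component (0 for isolates); transitivity is the local clustering
coefficient of the unweighted skeleton. The 1/weight transform is a config
choice; (1 − weight) is the noted alternative.

**Keystones** are nodes *strictly above* the linear-interpolation 99th
percentile of PageRank within their network. This convention is pinned by
its consequences: communities of 181 / 361 / 609 nodes with distinct
scores yield exactly 2 / 4 / 7 keystones. If massive ties leave the strict
rule empty, the maximal-score nodes are returned and logged. For
abundance-vs-importance comparisons, values are converted to within-sample
ranks (highest value = rank 1, ties averaged), since the two quantities
live on different scales.

## Dissimilarities, ordination, clustering

Bray–Curtis `Σ|x−y|/Σ(x+y)` and Jaccard (presence/absence) run on
per-sample relative abundances after rarefaction (rarefaction equalizes
totals, so closure is harmless). Weighted UniFrac sums branch lengths
weighted by |A_i − B_i|, the branch-wise difference in descendant
fraction; the normalized variant (default) divides by `Σ b_i (A_i + B_i)`,
keeping values in [0, 1] and comparable to Bray–Curtis.

NMDS minimizes Kruskal stress-1 by majorization (SMACOF) with isotonic
regression of the disparities; the first start is initialized from
classical metric MDS of the input (reproducible and usually near-optimal),
remaining starts are seeded random configurations, and the lowest-stress
solution is returned.

Hierarchical clustering defaults to average linkage (UPGMA); complete,
single and Ward are available. Entities are sorted lexicographically
before linkage so equal-height merges resolve deterministically.
Dendrograms export to newick with branch length = parent height − child
height. Importance profiles (per-group PageRank over the OTU union,
zero-filled) and abundance profiles (per-group mean relative abundance)
feed the same machinery, giving the abundance- vs importance-weighted
community comparison.

## PERMANOVA, dbRDA, variance partitioning

Both operate on the Gower-centered inner-product matrix `G = −½ C D² C`.
PERMANOVA's pseudo-F uses `tr(HGH)/q` over `tr((I−H)G(I−H))/(n−q−1)` with
H the hat matrix of centered dummy contrasts (reference level dropped);
p-values come from free permutation of sample labels,
`p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1)`. Nested or restricted
permutation schemes are out of scope; nesting is represented as model
structure only, and the report says so. Rank-deficient designs raise an
error naming the aliased columns.

dbRDA variance explained is `R² = tr(HGH)/tr(G)` with negative eigenvalues
of G retained in the trace (no Lingoes/Cailliez correction), and
`R²_adj = 1 − (1−R²)(n−1)/(n−q−1)`. The hat matrix is built by
pseudoinverse with `q` = matrix rank, so collinear factor groups — common
when plant species do not span all habitats — remain fittable; their
totals coincide and their uniques collapse toward zero, which is the
correct reading. Adjusted values may be slightly negative for null
factors and are reported as-is.

Variance partitioning reports, per factor group X: total adjusted R² (X
alone, with its marginal PERMANOVA p) and unique adjusted R²
(full model minus the model without X); "All" is the full model. Because
uniques are differences of adjusted values, they do not sum to the full
model when factors overlap — the gap is the shared fraction.

Distance inputs: UniFrac-based tables use dbRDA on the UniFrac matrix
identically to Bray–Curtis (constrained ordination of raw UniFrac
coordinates would require an embedding choice with no added value). Month
is an unordered categorical factor.

## Pipeline

Stage order: read/generate → organelle removal → (A) rarefy → distances →
NMDS → PERMANOVA/varpart on the full community and on keystone,
methanogen, and methanotroph subsets; (B) network prefilter (un-rarefied)
→ split by grouping keys (default habitat × compartment; the keys are
config because the natural grouping depends on the design) → SparCC →
networks → centralities → keystones → abundance- and importance-profile
clustering. Functional subsets reuse the same variance-partitioning code
path on row-subset tables; subsets with too few OTUs or samples are
skipped with a logged reason. Factors with a single observed level are
dropped from designs with a warning. All stage seeds are derived from one
master seed via `SeedSequence`; outputs are plain text (TSV, newick,
GraphML, JSON) and a manifest records every seed and threshold, so reruns
are bit-identical.

Methanogen lineages are matched by order against the configurable union
of the classic three-order list and the extended eight-order list
(Methanosarcinales, Methanobacteriales, Methanomicrobiales,
Methanococcales, Methanopyrales, Methanocellales,
Methanomassiliicoccales, Candidatus Methanophagales); methanotrophs by
order (Methylacidiphilales) or family (Beijerinckiaceae,
Hyphomicrobiaceae, Methylocystaceae, Crenotrichaceae, Methylococcaceae).
An OTU matching both lists is a configuration error.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` validate every kernel against
an independent oracle computed by a different route: PageRank against a
dense linear solve of the fixed point, betweenness against exhaustive
shortest-path enumeration on 8-node graphs, dbRDA R² against
PCoA-then-regression, weighted UniFrac against naive per-branch
summation, UPGMA against a from-scratch O(n³) agglomeration (cophenetic
comparison), and the Sherman–Morrison exclusion loop against repeated
full solves.

Statistical guarantees are checked at these scales, chosen to give stable
Monte-Carlo estimates at desk runtimes: correlation-test calibration on
20 null communities of 50 OTUs × 100 samples at 100 bootstrap replicates
(pooled edge rate within 3 binomial SE of nominal); planted-pair recovery
over 50 seeds at ρ = 0.9, 200 samples (top-2k rule, ≥ 95%); PERMANOVA
type-I error over 500 null datasets of n = 30 (within 3 SE of nominal)
and power at the permutation floor under a strong effect;
effect-size-ordering recovery over 50 seeds (25 per direction) on
factorial communities of 80 OTUs with habitat/plant SDs 1.5 vs 0.3.

## Known limitations

* The sparsity approximation behind the basis-variance system degrades
  when many OTUs are strongly inter-correlated; the exclusion loop
  mitigates but does not eliminate this.
* Permutation p-values inherit the granularity 1/(n_boot+1); at 100
  replicates the smallest attainable p is ~0.0099, so edge selection at
  α = 0.05 is coarse.
* Free permutation ignores the nesting of plants within habitats;
  p-values for nested factors are therefore liberal relative to a
  restricted scheme.
* Negative adjusted R² values are statistical noise around zero, not
  evidence of a negative effect.
* NMDS is a local optimizer; multiple starts reduce but cannot abolish
  the risk of a sub-optimal embedding, and stress values depend on the
  data at hand.
* The generator's clean multinomial noise understates real-data
  overdispersion; calibration results transfer to real data only insofar
  as the compositional log-normal model holds.
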