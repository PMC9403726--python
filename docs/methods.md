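# Methods

This note documents the models and procedures implemented in `neoconn`,
the parameters that matter, the design decisions taken where more than
one convention exists, and what the synthetic-data validation does and
does not establish.

## Data model

A connectome is a weighted undirected graph on N parcellation regions
(default N = 93, matching neonatal AAL-style atlases), stored as a
symmetric nonnegative matrix with zero diagonal. Edge weights are
streamline-derived connectivity values (sums of SIFT2 streamline
weights) and are treated as dimensionless. Matrices are read from
delimited text (`.csv`/`.tsv`), optionally with a node-id header row;
headered files are reordered to node-table order, headerless files are
assumed already ordered. Asymmetries up to a relative 1e-8 are averaged
away; anything larger is rejected as a corrupt or transposed input
rather than silently symmetrised. Missing covariate cells stay missing
(never zero) and subjects are dropped per-analysis (listwise deletion),
so each analysis uses the maximal complete-case sample.

## Graph measures and cost correction

Shortest paths use edge length `1/w` — the convention of the standard
brain-connectivity toolboxes, under which strong connections are short.
Global efficiency is the mean of `1/d(i,j)` over ordered pairs with
`1/∞ = 0`. Nodal efficiency of node v is the efficiency of the subgraph
induced by v's neighbours, using the original weights among the
neighbours (paths through v itself do not count), and is 0 for nodes
with fewer than two neighbours; local efficiency is its mean over nodes.
This per-node *local-efficiency* reading of "nodal efficiency" is a
deliberate choice; the alternative reading (inverse closeness
centrality) is a different measure and is not provided.

Proportional thresholding keeps the `k = round(d·N(N−1)/2)` strongest
edges at target density d (round half away from zero), retaining their
weights. Degree is counted on the binarized support of the thresholded
network; strength and the efficiencies use the surviving weights. Ties
in weight are broken by lexicographic node-pair order so thresholding is
deterministic. Cost correction evaluates every feature on thresholded
copies over a density grid — default 0.05 to 0.50 in steps of 0.01, 46
densities — and averages across the grid, removing between-subject
density differences as a confound. If a network is already at or below
a target density it enters that grid point unchanged.

## Core–periphery decomposition

The partition quality is the Borgatti–Everett correlation: the Pearson
correlation, over off-diagonal node pairs, between the observed weights
and the ideal pattern matrix that is 1 on core–core and core–periphery
pairs and 0 on periphery–periphery pairs. An additive variant
(core-adjacent weight minus periphery–periphery weight over total
weight) was considered and rejected: it is maximised by any labeling
with no periphery–periphery weight, including the degenerate all-core
labeling, so planted-partition recovery is ill-posed under it. Under
the correlation quality the degenerate labelings have zero pattern
variance and are excluded by construction.

The search is Kernighan–Lin-style: repeated tabu sweeps in which every
node is flipped exactly once in best-gain order and the best prefix of
the sweep is kept, iterated to a local optimum, over `n_restarts`
random initializations (default 100) with derived per-restart seeds.
A flip is scored in O(1) because the quality depends on the labeling
only through the periphery–periphery weight sum and the periphery size.
Ties between equal-quality optima break toward the lexicographically
smallest core set, making the result deterministic given (connectome,
seed, n_restarts). On planted core–periphery graphs up to 12 nodes the
search attains the enumerated global optimum (verified exhaustively in
the tests).

The pipeline partitions the group-mean connectome by default; a
majority-vote consensus across per-subject partitions is available as
an alternative (`core_periphery.mode: consensus`). Externally supplied
partitions (a `partition_label` column in the node table) are accepted
so published node classifications can be reproduced directly.

## Network-based statistics

At every analyzed edge an OLS model `weight ~ intercept + predictor +
covariates` is fit, vectorized across edges; the predictor t-statistic
(df = n − p) is thresholded in the hypothesized direction (default
`t = 3.1`, negative contrast: lower weight with higher score), and
maximal connected supra-threshold components are extracted. Family-wise
error over edges is controlled on component *extent* (edge count): the
null distribution of the maximum extent is built by Freedman–Lane
permutation — residualize the edge weights on the nuisance covariates
under the reduced model, permute those residuals across subjects, add
the nuisance fit back, refit the full model — which is the accepted
permutation scheme for GLMs with nuisance covariates. The FWE p-value
of a component of extent e is `(1 + #{null max ≥ e}) / (1 + B)`
(add-one form, so p > 0 always); default B = 10,000 and critical
p = 0.025, reflecting a two-outcome family.

Edges enter the analysis if they have positive weight in at least 90%
of the retained subjects (configurable `edge_presence_fraction`); a mask
is needed because all-zero edges yield degenerate regressions, and 90%
keeps edges with occasional dropouts while excluding sporadic noise
edges. Constant covariate columns (aliased with the intercept, e.g. a
factor with a single observed level in a small cohort) are dropped from
the design rather than reported as a rank error. Perfect fits are
reported at a t sentinel of 1e6. The sensitivity sweep re-scores the
same permutation stream at thresholds 2.5–3.5 (step 0.1), so per-
threshold results differ only by threshold.

## Behaviour statistics

Raw internalizing/externalizing problem scores are residualized on
corrected age at follow-up (OLS with intercept) and standardized to
mean 0, SD 1; all downstream associations use these age-adjusted
scores. A perfectly age-linear score vector has zero residual variance;
it is flagged and reported as zeros rather than dividing by zero.

Partial Spearman correlation is computed as rank-then-partial-Pearson:
average-rank transform x, y, and each covariate over complete cases,
residualize the ranked x and y on the ranked covariates, and correlate
the residuals; p-values use the t approximation with `n − 2 − k`
degrees of freedom. With no covariates this reduces exactly to plain
Spearman on tie-free data. Ties receive average ranks, which matters
because behaviour raw scores are small integers with frequent ties.

FDR correction is Benjamini–Hochberg step-up, applied within explicit
test families; the pipeline pools global features per outcome and all
nodal tests (nodes × metrics) per outcome. Kruskal–Wallis (tie-
corrected, chi-square p) serves for subgroup comparisons with uneven
group sizes; an all-identical sample has H = 0 by definition. T-scores
band as normal (< 60), borderline (60–63), clinical (> 63). White
matter injury grades by focus count/size: severe > 10 foci; moderate
4–10 foci or any focus > 2 mm; mild 1–3 foci all ≤ 2 mm; the overall
rating is moderate-severe iff WMI is moderate/severe or a cerebellar
haemorrhage exceeds 2 mm (isolated IVH stays none-mild).

## Synthetic cohort generator

The generator emulates the *structure* of a presurgical neonatal CHD
cohort with toddler follow-up; defaults are sized to such a study:
43 subjects, 93 nodes, 34 core regions.

Connectomes: a cohort-level backbone support is drawn once from block
presence probabilities (core–core : feeder : periphery–periphery
propensities 2.2 : 1.5 : 1, solved to hit an overall density of 0.6)
and shared by all subjects, emulating the common anatomical scaffold of
tractography cohorts; per-subject independent presence was rejected
because it leaves almost no edge present in ≥90% of subjects at
realistic densities, which neither matches real cohorts nor exercises
the NBS mask. Each backbone edge carries a persistent log-scale
baseline `μ_edge = μ_block + N(0, 0.7)` (block log-means 3.0 / 2.0 /
1.5); subject weights are log-normal around it with between-subject
σ = 0.3. The cross-edge weight distribution is therefore heavy-tailed
(like SIFT2 weight sums) while the between-subject variability of any
single edge is realistically modest (CV ≈ 0.3).

Covariates: gestational age ~ N(38.6, 0.5) weeks, scan at a small
positive lag, balanced sex, moderate-severe injury in 14% of infants,
cognitive composite ~ N(93.6, 10.2), a log-normal deprivation index,
and corrected follow-up age ~ N(22.1, 0.35) months. Behaviour raw
scores are negative-binomial counts (dispersion 4.5; means 8
internalizing, 13 externalizing) with a +1.5-per-month corrected-age
trend, so the age-residualization stage has genuine signal to remove.

The planted effect adds `β · z + N(0, noise_sd)` to each designated
edge's weight, where z is the subject's standardized behaviour score,
floored at 0 to preserve nonnegativity. Effect edges are forced into
the backbone and their baselines clamped to at least the block mean:
a planted association on an edge whose weight the floor truncates to
zero for many subjects is erased by the floor and by the presence mask,
which would make "planted" silently mean "absent". The reference
planted configuration used in validation is a connected 12-edge ring of
feeder-type edges with β = −4 (about 1.7 between-subject SDs of a
feeder edge), a strong effect by design. Everything is a pure function
of (config, seed); null ensembles derive one child seed per cohort.

What passing tests on synthetic cohorts do **not** show: the generator
has no spatial embedding, no distance-dependent connectivity, no
hemispheric symmetry, homoscedastic log-normal weights, and independent
covariates (no GA–injury or deprivation–cognition coupling). Type-I
calibration and planted-effect recovery therefore validate the
*inference machinery*, not the anatomical realism of any particular
dataset.

## Validation problem sizes

The statistical validation uses 200 null cohorts (40 subjects, 93
nodes) at 500 permutations each for false-positive calibration at
α ∈ {0.025, 0.05} (bound: α + 3 Monte-Carlo SE), and 50 planted-effect
replicates at 500 permutations for recovery (Jaccard > 0.5 against the
planted edge set in ≥80% of replicates). These sizes give Monte-Carlo
standard errors of ~1.5 percentage points on the calibration rates
while keeping the whole suite desk-scale; the analysis default of
10,000 permutations applies to real runs, where a single cohort is
tested once. Graph measures are checked for exact agreement with
brute-force oracles (Floyd–Warshall, explicit sort-and-cut, enumerated
neighbourhood efficiencies) on 200 random graphs of up to 8 nodes, and
the core–periphery search against exhaustive enumeration up to 12
nodes.

## Known limitations

* The observed FWE false-positive rate under the null sits well below
  nominal α: a max-extent statistic on a discrete extent scale is
  conservative at small α. This is the expected behaviour of
  extent-based NBS, not a calibration failure.
* Only two-group (core/periphery) partitions and extent-based (not
  mass-based) cluster statistics are provided.
* Partial Spearman p-values use the large-sample t approximation;
  for very small samples (n < 15) an exact permutation p would be
  preferable and is not currently implemented.
* The CLI's single-stage verbs rerun the pipeline with the same derived
  seeds rather than reusing cached intermediates.
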