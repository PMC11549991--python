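# Methods

This note records the statistical model behind each stage of `connstats`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

A subject's connectome is a symmetric nonnegative 82×82 matrix of
streamline-weight sums (SIFT2-style, unitless) over a fixed atlas of 41
cortical/subcortical regions per hemisphere; the diagonal is zero and the
3,321 upper-triangle entries are the analysis units. Matrices are
exchanged as dense delimited text in atlas order. Asymmetry up to 1e-8 is
treated as writer round-off and averaged away; anything larger is
rejected as genuinely directed input. The cohort table carries group
(`noPAE`, `PAE_T1`, `PAE_T1T3`), age (years), sex (0/1, female = 1) and
intracranial volume (ICV, cm³). The atlas node order (left hemisphere
then right, regions alphabetical) is a package convention: any consistent
order works as long as every matrix in a cohort shares it.

## Synthetic cohorts

The generator produces cohorts in which every downstream claim has a
known answer. One subject's expected weight matrix is a planted
block structure — `base_within` (default 1.0) inside each of 11 modules
(sizes 8×5 and 7×6 over 82 nodes), `base_between` (default 0.15)
elsewhere — with the rows/columns of 7 designated hub nodes multiplied by
`hub_boost` (default 2.0; hub–hub edges get the factor twice). Each edge
then receives i.i.d. multiplicative log-normal noise with mean 1 and
coefficient of variation `noise_cv` (default 0.25): streamline-weight
sums are positive and right-skewed, and 25% between-subject dispersion is
typical of the inter-subject variability seen in tractography-derived
edge weights. Covariates: age ~ U(6.8, 7.8) years and sex ~ Bernoulli(½),
matching a 6–8-year-old cohort; ICV ~ Normal with the per-group means/SDs
of the study demographics (1556 ± 139.4, 1519 ± 128.9, 1613 ± 121.5 cm³),
and all of a subject's weights are scaled by (ICV/1550)^1 so that ICV is
a real nuisance the covariate adjustment must remove — note the exposed
group has the *largest* ICV, so failing to adjust biases *against* the
planted deficit. The group effect multiplies a connected 20-edge set
inside module 1 by (1 − `effect_size`) (default 0.3) in `PAE_T1T3` only;
`noPAE` and `PAE_T1` share the null model.

What the generator does **not** emulate: spatially correlated noise,
distance-dependent connection probability, heavy-tailed weight
distributions across edges (orders-of-magnitude range in real SIFT2
connectomes), hemispheric asymmetries, and motion/site artefacts.
Passing recovery tests therefore show the *inference machinery* is
correct and calibrated — not that real-data effects of this size would be
detected with the same power.

## Density thresholding and centrality

Proportional thresholding keeps the ⌈density × n(n−1)/2⌉ largest-weight
edges, with weights retained, ties broken by (row, column) lexicographic
order; this makes the retained edge sets nested across densities and the
operation idempotent. The sweep is 5%–80% in 5% steps (16 levels); the
AUC is the plain unweighted sum of a node's metric across the 16 levels
(not trapezoidal integration).

Betweenness treats edge length as the reciprocal of weight — in
streamline-weighted networks a larger weight is a stronger connection,
so geodesics should prefer strong edges (the Brain Connectivity Toolbox
convention). Counting is fractional across tied geodesics with endpoints
excluded; unreachable pairs contribute zero. The computation is delegated
to igraph's weighted Brandes implementation and is tested against an
exhaustive path-enumeration oracle (all graphs ≤ 6 nodes) and against
networkx on larger graphs.

Eigenvector centrality is the entrywise-nonnegative leading eigenvector
of the weight matrix (unit Euclidean norm, via a dense symmetric
eigendecomposition); on a disconnected network it concentrates on the
dominant component, which is the behaviour we want under aggressive
thresholding. Because the vector is normalized, weakening one module
*redistributes* centrality towards the rest of the network — a real,
induced group difference in other modules, visible in the planted-effect
examples; null-model calibration is always checked with `effect_size=0`.

Hubs: AUC strictly greater than mean + 1 sample SD (n−1 denominator)
of the group-averaged node profile. Ranks: 1 = largest AUC, ties
averaged.

## Consensus modules

Community detection optimises weighted modularity (Leiden algorithm with
the RB-configuration objective; `gamma` = 1.0) with explicit seeds. The
consensus procedure pools all partitions from `n_runs` (default 100)
seeded runs on each subject of a balanced subsample (default 24 per
group — equal numbers avoid biasing the consensus toward the largest
group) into one co-assignment matrix; entries below `tau` = 0.4 are
zeroed, the permutation-expected co-assignment rate is subtracted
(preventing trivial single-module collapse when re-clustering a dense
consensus matrix), and the matrix is re-clustered until all runs agree
(binary co-assignment) or `max_iter` = 50. Defaults follow the
consensus-clustering literature; they are not sensitive on block-modular
inputs, where convergence typically takes one iteration.

## Edge-wise inference (NBS)

For a two-group contrast the design is (1, group, age, sex, ICV) over
the subjects of those groups; all 3,321 edges are fit at once by
vectorised OLS, and the one-tailed group t is contrast/SE with
df = n − 5. Residual variance at round-off level (identical responses)
yields t = 0. Components of the graph of edges with t > t₀ are ranked by
edge count ("extent"); significance compares each observed component's
extent with the permutation distribution of the *maximum* extent,
permuting only the group indicator while covariates stay attached to
subjects (simple exchangeability; Freedman–Lane residual permutation is
not implemented). p = (1 + #{perm ≥ obs})/(n_perm + 1) for sampled
permutations; when the requested permutation count reaches the number of
distinct relabelings C(n, n₁) the null is enumerated exhaustively and p
is exact. Default n_perm = 5000 (p resolution 2×10⁻⁴); the threshold
sweep covers t₀ = 2.1–3.0 in 0.1 steps.

A consequence of the lenient default thresholds worth knowing: at
t₀ = 2.3 about 1.3% of null edges are supra-threshold (≈ 42 of 3,321),
which puts the null random graph near its giant-component regime; null
maximum extents of 35–45 edges are common. A planted effect touching
only 20 edges is therefore detected with ≈ 80% power at the study's
sample sizes — detection requires the signal component to merge with
enough chance edges to beat the null maximum — so recovery checks are
run as small power simulations over replicate cohorts rather than a
single draw.

## Group statistics

Sex: Pearson χ² on 2×2 counts, df = 1, no continuity correction. Age and
ICV: one-way ANOVA reconstructed from per-group (mean, SD, n) summaries
via between/within sums of squares — algebraically identical to raw-data
ANOVA when the summaries are exact, but third-decimal differences are
expected when reconstructing published values from *rounded* summaries.
Tukey–Kramer post-hocs use the studentized-range distribution with
SE = √(MSW/2 · (1/nᵢ + 1/nⱼ)) and df = N − k. ANCOVA fits
`y ~ group + age + sex + icv` by OLS and tests the 2-df group term by a
partial F-test (equivalent to a Type-II ANOVA); adjusted group means are
predictions at sample-mean covariates, and the attached post-hocs apply
Tukey–Kramer to those adjusted means with the full-model residual mean
square. BH-FDR (step-up) is applied within each analysis level —
whole-brain, module, node, hub-rank — separately. Hub-rank comparisons
use per-subject rank vectors restricted to nodes identified as hubs in
every group.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `numpy.random.SeedSequence`, so
a run is reproducible byte-for-byte from its config. The test suite and
acceptance script use the study's group sizes (24/30/36) throughout;
calibration uses 200 replicate null cohorts with 99 permutations per NBS
test (p resolution 0.01 is sufficient to measure a 5% error rate), and
recovery power uses 5–9 replicate cohorts at 1000 permutations.

## Known limitations

- The ANCOVA assumes Gaussian homoscedastic errors; module-mean AUC
  metrics of log-normal-noise networks satisfy this only approximately
  (calibration is verified empirically, not by theory).
- One consensus partition is produced for the whole cohort; uncertainty
  in module assignment is not propagated into module-level inference.
- NBS power depends on the spatial extent of the true effect; small
  compact effects at lenient thresholds face heavy null maxima (above).
- The literal alternative reading of shortest-path length (raw weights
  as lengths rather than reciprocals) is not implemented; the reciprocal
  convention is standard for strength-weighted connectomes.
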