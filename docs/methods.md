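# Methods

## Scope and model

`beetlenet` reconstructs species co-occurrence networks from community
survey data in which every sample records, per species, an abundance
count and a biomass measurement. The intended setting is a multi-region
survey of water beetles in small dystrophic (humic) lakes — several
regions, tens of samples per region, tens of species per region — but
nothing in the code is specific to beetles: any long-format
sample × species × (count, biomass) table in the documented schema works.

The analysis has four statistical layers.

### 1. Community statistics

Per region we report richness S, abundance N, total biomass, dominance D
(per-species percentage of total N) and the Shannon–Wiener index
H′ = −Σ pᵢ ln pᵢ computed on pooled species abundances, in nats. The
"mean ± SD" columns reported next to group totals are conditional on
presence: they average the non-zero (sample, species) cells, i.e. the
mean number of individuals per species occurrence. This occurrence-level
convention is the only one under which a group observed once with one
individual has mean 1.0, and it is how we read the survey tables this
package emulates; a sample-level conditional mean is available by
aggregating the per-sample table directly.

Cross-region contrasts use the tie-corrected Kruskal–Wallis H test
(p from χ² with k−1 df) with a Dunn-type post-hoc on mean ranks:
z = |R̄ᵢ−R̄ⱼ| / √[(N(N+1)/12)(1/nᵢ+1/nⱼ)], two-sided normal p multiplied
by the number of pairs (Bonferroni) and capped at 1. All ranks are
midranks; fully tied data return H = 0, p = 1 rather than 0/0.

### 2. Network inference

Each region's samples × species biomass matrix is transformed by
x → log₂(x + c) followed by per-column autoscaling (mean 0, SD 1 with
denominator n−1). The pseudocount c defaults to half the smallest
positive value in the matrix; zero biomass encodes absence, and the
pseudocount keeps absences on the log scale. Columns with fewer than two
distinct values are dropped from inference (and listed in the run
manifest) — they carry no correlation information.

Pairwise association uses two complementary estimates:

- **Pearson correlation** r with a two-sided p from
  t = r√((n−2)/(1−r²)) on n−2 df. These are the display weights and the
  significance filter.
- **Partial correlations from the graphical lasso.** The glasso
  maximises log det Θ − tr(SΘ) − λ‖Θ‖₁,off over the sample correlation
  matrix S, and partial correlations follow as
  ρᵢⱼ = −θᵢⱼ/√(θᵢᵢθⱼⱼ). The penalty λ is selected by StARS: 50 row
  subsamples of size ⌊0.8 n⌋, edge instability 2θ̂(1−θ̂) averaged over
  pairs, instability monotonised along the path, and the smallest λ whose
  instability stays ≤ 0.05 is kept (largest λ, with a warning, if none
  qualifies). The grid is 20 log-spaced points from max|off-diagonal
  of S| down to 5% of it; the endpoints are our choice, the conventional
  ratio grid for glasso paths. The solver is
  `sklearn.covariance.graphical_lasso`; the StARS wrapper, partial-
  correlation conversion and edge assembly are this package's.

An edge (i, j) enters the network iff the partial correlation is
non-zero (|ρ| > 10⁻⁸) **and** the Pearson p ≤ α (default 0.05, no
multiple-testing correction). The filter addresses the Pearson
correlation — the quantity reported on edges — not the partial
correlation; both the α and the filtered quantity are configurable.
Edges carry pearson_r, partial_corr, p and sign(pearson_r); species that
end up isolated remain as nodes.

### 3. Graph metrics

All topology metrics are computed on the simple unweighted graph; edge
weights only influence layout. Conventions follow the NetworkAnalyzer
family:

- NDC = degree; NCC = (reachable nodes)/(Σ distances), i.e. reciprocal
  mean distance within the component (0 for isolated nodes);
  NBC normalised by (n−1)(n−2)/2 with n the **component** size;
  local clustering 2eᵥ/(kᵥ(kᵥ−1)), 0 when kᵥ < 2, included in the
  network mean (averaging over deg ≥ 2 nodes only is a flag away via the
  per-node table).
- Shortest-path counts and EBC use **ordered-pair** counting, so the
  edge of an isolated species pair has EBC exactly 2 — the natural floor
  observed for mutually exclusive pairs.
- density = 2E/(N(N−1)); avg. neighbours = 2E/N; characteristic path
  length = mean distance over ordered reachable pairs; heterogeneity =
  CV of the degree sequence (population variance); centralization =
  [N/(N−2)]·[max deg/(N−1) − density] (undefined below N = 3).

`beetlenet.oracle` re-derives NCC/NBC/EBC/path statistics by exhaustive
BFS shortest-path enumeration on graphs of ≤ 12 nodes. It shares no
algorithmic code with the networkx-based implementation and exists
purely as an independent cross-check; the test suite requires agreement
to 10⁻⁹ on batches of random graphs.

### 4. Ordination

A sample-level feature table joins community indicators (N, S, biomass,
per-group N and S), abundance-weighted means of the network metrics of
the species present in each sample (unweighted means by flag), and the
environmental covariates (ordinal ranks entered as integers, continuous
covariates as-is; missing cells imputed by column median with a logged
count). PCA standardises columns and eigendecomposes the correlation
matrix; explained ratios are eigenvalues over the number of features,
and each component is flipped so its largest-magnitude loading is
positive, making outputs deterministic. A companion report lists all
pairwise Pearson correlations with p-values sorted by |r|.

## The synthetic generator

`simulate.PlantedCommunitySpec` emulates the survey structure with known
ground truth:

- **Precision matrix.** Species are split round-robin into K clusters;
  within-cluster precision off-diagonals are −ρ_w (negative precision →
  positive partial correlation → co-occurrence), optional cross-cluster
  edges at half strength; the diagonal is inflated exactly enough to put
  the smallest eigenvalue at 0.05. The planted edge set is the support
  of Θ. Note that for clusters of ≥ 4 species at ρ_w = 0.3 the inflation
  is active, so realised partial correlations are ≈ ρ_w/diag rather than
  ρ_w, and the eigenvalue floor induces strong marginal correlations
  within clusters.
- **Biomass.** Per sample, a latent z ~ MVN(0, Θ⁻¹); biomass =
  exp(μ_c(region) + σz) in mg, with μ the log of a 10 mg occurrence
  median times the cluster's regional prevalence multiplier (each
  cluster is twice as prevalent in its home region by default). Zero
  inflation masks each cell independently with probability π₀, emulating
  sampling absences.
- **Counts.** count = ⌈biomass / individual mass⌉, with per-species
  individual mass drawn once from a lognormal (median 10 mg, log-SD 1.5,
  spanning roughly 0.5–200 mg — the body-mass range from small
  hydroporine diving beetles to large dytiscids). This keeps biomass and
  abundance mutually consistent and biomass = 0 ⇔ count = 0.
- **Labels.** Ecological and functional groups are assigned per cluster,
  so "clusters of ecologically similar species" is true by construction
  and detectable downstream. Sample metadata (habitat/stage/… ranks,
  hydrochemistry) is drawn from plausible ranges but is *not* coupled to
  the biomass field — environmental gradients are not planted.

Defaults are the benchmark recovery setting: S = 20, K = 4, ρ_w = 0.3,
one region of 500 samples, σ = 1, π₀ = 0.2. `study_like_spec()` gives a
survey-shaped variant (3 regions × 70 samples, 60 species in 6
clusters). What passing recovery tests show is that the inference stack
finds planted conditional-dependence structure under lognormal noise and
independent zero inflation; they say nothing about hurdle-style
correlated absences, compositional effects, or environmental confounding
in real surveys.

## Numerical choices and edge cases

- Duplicate (sample, species) rows are summed (repeated sub-samples);
  absence is explicit 0; identifiers are opaque strings; matrix columns
  are sorted lexicographically so downstream linear algebra is
  deterministic.
- |r| = 1 maps to p = 0 exactly; correlation matrices are symmetrised
  and clipped to [−1, 1] before use.
- Glasso non-convergence on a subsample skips that fit with a warning;
  non-convergence of the final fit falls back up the path toward larger
  penalties.
- All randomness (simulation, StARS subsampling, layout) flows from a
  single integer seed; StARS subsample index sets are retained in the
  result object, and reruns with the same config and seed are
  bit-identical in every table.
- The spring-embedded layout uses |r| as spring strength, centres the
  coordinates and scales them to the unit box; figures are advisory and
  carry no numeric guarantees.

## Benchmark problem sizes

The validation experiments are sized for a single CPU: the edge-recovery
benchmark runs 10 seeds at n ∈ {100, 250, 500} on the default planted
community (~8 minutes, dominated by ~1000 glasso fits per StARS run);
the Kruskal–Wallis calibration uses 2000 null replicates of 3 × 10
normal observations; the metric-oracle comparison uses 100 random graphs
of ≤ 8 nodes; the permutation-null network check in the test suite runs
at a reduced scale (8 species, 60 samples, 10 StARS subsamples per
replicate) to keep 50 replicates affordable.

## Known limitations

- StARS at instability threshold 0.05 is deliberately conservative; on
  the default planted community its selected penalty sits at the knee of
  the instability curve, and recovered edge sets favour precision over
  recall (edge-recovery F1 at n = 500 averages ≈ 0.8 and is the
  benchmark's most seed-sensitive number).
- The significance filter is applied per edge without multiple-testing
  correction, matching the reporting convention the pipeline emulates;
  users wanting FDR control should filter the edge table themselves.
- Sample-level aggregation of node metrics mixes species-level and
  sample-level quantities; the abundance-weighted mean is one defensible
  choice among several, and the unweighted variant is exposed.
- The generator's zero inflation is independent Bernoulli masking;
  real surveys show structured (habitat-driven) absences that will
  attenuate correlations differently.
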