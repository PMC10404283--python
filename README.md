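# beetlenet

Correlation-based species co-occurrence network analysis for community
survey data.

Freshwater invertebrate surveys — the motivating case is water beetles
in small dystrophic (humic) lakes sampled across several lake regions —
produce long-format tables of samples × species with abundance counts
and biomass. `beetlenet` turns such tables into signed species
interaction networks and the accompanying community statistics:

- **Community statistics** — richness S, abundance N, dominance D,
  Shannon–Wiener H′ = −Σ pᵢ ln pᵢ (nats), ecological/functional group
  aggregates, and tie-corrected Kruskal–Wallis tests with Dunn-type
  Bonferroni post-hoc comparisons of mean ranks between regions.
- **Network inference** — per region: log₂(x + c) + autoscale
  normalisation, Pearson correlations with t-test p-values, sparse
  partial correlations ρᵢⱼ = −θᵢⱼ/√(θᵢᵢθⱼⱼ) from the graphical lasso
  with the penalty selected by StARS stability; an edge requires a
  non-zero partial correlation and Pearson p ≤ 0.05.
- **Graph metrics** — node degree/closeness/betweenness centrality
  (NDC/NCC/NBC), edge betweenness (EBC, ordered-pair counting so an
  isolated pair's edge scores exactly 2), local clustering, and
  whole-network attributes (density, Freeman centralization, degree
  heterogeneity, characteristic path length, shortest-path counts) —
  validated against an independent brute-force shortest-path enumerator.
- **Ordination** — correlation-matrix PCA of community indicators,
  sample-aggregated network attributes and environmental covariates,
  plus the full pairwise correlation report.
- **Synthetic communities** — a planted-structure generator (block
  precision matrix, lognormal biomass, zero inflation, region-specific
  prevalence) whose ground-truth edge set scores the whole stack's
  edge-recovery precision/recall/F1.

See `docs/methods.md` for the statistical details and conventions.

## Worked example

Simulate a planted community (20 species in 4 clusters, 250 samples,
20% zero inflation), infer its network and score recovery:

```python
import beetlenet as bn

spec = bn.PlantedCommunitySpec(n_samples=250, seed=11)
survey, species_meta, sample_meta, truth = bn.make_planted_community(spec)
matrix = bn.build_biomass_matrix(survey, value_kind="biomass")
net, stars = bn.infer_network(matrix, seed=11, species_meta=species_meta)
print(net.number_of_edges(), round(stars.lambda_selected, 3))
print(bn.recovery_report(net, truth))
print(bn.network_attributes(net).as_series().round(3))
```

prints

```
12 0.186
{'precision': 0.833, 'recall': 0.25, 'f1': 0.385, 'n_inferred': 12, 'n_true': 40}
n_nodes                       20.000
n_edges                       12.000
clustering_coefficient         0.150
centralization                 0.105
shortest_paths                56.000
characteristic_path_length     1.786
avg_neighbors                  1.200
density                        0.063
heterogeneity                  0.858
```

At 250 samples StARS keeps the penalty conservative (λ = 0.186): the 12
recovered edges are mostly real (precision 0.83) but only a quarter of
the 40 planted within-cluster dependencies are found; recall climbs
steeply with sample size (the acceptance benchmark runs the same
recovery at n = 100/250/500 over ten seeds). The network attributes read
as in any co-occurrence study: 12 edges over 20 nodes give density
2E/(N(N−1)) = 0.063, a mean of 1.2 neighbours per species, and 56
ordered reachable pairs with mean shortest-path length 1.79.

The same pipeline runs from the shell:

```sh
beetlenet simulate --outdir sim --seed 2 --species 20 --clusters 4 --samples 250
beetlenet infer --survey sim/survey.tsv --out net.graphml --seed 2
beetlenet run --config config.yaml   # full multi-region report bundle
```

A config file names either input files (`survey_path`,
`species_meta_path`, `sample_meta_path`) or a `simulate:` block, and the
report bundle contains per-region GraphML/edge-list exports, metric and
community tables, Kruskal–Wallis results, PCA outputs and a
`manifest.json` with the seed and the selected penalty per region.

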