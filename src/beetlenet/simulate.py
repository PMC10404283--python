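"""Synthetic multi-region survey communities with planted network structure.

The generator emulates the structure of a multi-lake beetle survey: a
species pool organised into clusters of ecologically similar species, a
sparse block precision matrix encoding within-cluster co-occurrence,
lognormal biomass with region-specific cluster prevalence, independent
zero inflation (sampling absences), and abundance counts derived from
biomass through a per-species individual body mass. Every dataset comes
with its ground truth (precision matrix, partial correlations, edge set),
so edge-recovery performance of the inference stack can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ECOLOGICAL_GROUPS,
    FUNCTIONAL_GROUPS,
    SurveyTable,
    validate_sample_meta,
    validate_species_meta,
)

MIN_EIGENVALUE = 0.05


@dataclass
class PlantedCommunitySpec:
    """Parameters of a planted community.

    Defaults give the benchmark recovery setting: 20 species in 4 equal
    clusters with within-cluster partial-correlation strength 0.3, a
    single region of 500 samples, lognormal biomass (sigma = 1) around a
    10 mg occurrence median, and 20% zero inflation.
    """

    n_species: int = 20
    n_clusters: int = 4
    rho_within: float = 0.3
    cross_cluster_p: float = 0.0
    n_samples: int = 500
    n_regions: int = 1
    region_multipliers: np.ndarray | None = None  # regions × clusters prevalence
    base_log_biomass: float = float(np.log(10.0))  # ln mg per occurrence
    sigma: float = 1.0
    zero_inflation: float = 0.2
    #: per-species individual mass ~ lognormal(ln median_mass, body_size_sigma)
    median_individual_mass: float = 10.0
    body_size_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho_within < 1:
            raise ValidationError("rho_within must be in (0, 1)")
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError("zero_inflation must be in [0, 1)")
        if self.n_clusters > self.n_species:
            raise ValidationError("more clusters than species")

    @property
    def cluster_assignment(self) -> np.ndarray:
        """Species → cluster labels, round-robin so cluster sizes differ by ≤1."""
        return np.arange(self.n_species) % self.n_clusters

    def multipliers(self) -> np.ndarray:
        """Regions × clusters prevalence multipliers.

        Default: each cluster is twice as prevalent in its 'home' region
        (cluster index mod number of regions), emulating regional turnover
        of species pools.
        """
        if self.region_multipliers is not None:
            m = np.asarray(self.region_multipliers, dtype=float)
            if m.shape != (self.n_regions, self.n_clusters):
                raise ValidationError("region_multipliers must be regions × clusters")
            return m
        m = np.ones((self.n_regions, self.n_clusters))
        for c in range(self.n_clusters):
            m[c % self.n_regions, c] = 2.0
        return m


def study_like_spec(seed: int = 0) -> PlantedCommunitySpec:
    """A spec shaped like the survey design: 3 regions × 70 samples, 60 species."""
    return PlantedCommunitySpec(
        n_species=60,
        n_clusters=6,
        n_samples=70,
        n_regions=3,
        seed=seed,
    )


@dataclass
class PlantedTruth:
    """Ground truth of a planted community."""

    precision: pd.DataFrame
    partial_corr: pd.DataFrame
    edges: set  # frozenset pairs of species ids
    clusters: dict  # species_id → cluster index

    @property
    def species(self) -> list[str]:
        return list(self.precision.columns)


def _species_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"sp{str(i).zfill(width)}" for i in range(n)]


def make_planted_precision(spec: PlantedCommunitySpec) -> PlantedTruth:
    """Block-structured sparse precision matrix with enforced positive definiteness.

    Within-cluster off-diagonals are -rho_within (negative precision
    entries give positive partial correlations, i.e. co-occurrence);
    optional cross-cluster edges are added with probability
    ``cross_cluster_p`` at half strength. The diagonal is inflated until
    the smallest eigenvalue reaches 0.05.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.n_species
    clusters = spec.cluster_assignment
    theta = np.eye(s)
    for i in range(s):
        for j in range(i + 1, s):
            if clusters[i] == clusters[j]:
                theta[i, j] = theta[j, i] = -spec.rho_within
            elif spec.cross_cluster_p > 0 and rng.random() < spec.cross_cluster_p:
                theta[i, j] = theta[j, i] = -spec.rho_within / 2.0
    eig_min = float(np.linalg.eigvalsh(theta).min())
    if eig_min < MIN_EIGENVALUE:
        # inflate the diagonal exactly enough to reach the eigenvalue floor
        theta = theta + (MIN_EIGENVALUE - eig_min) * np.eye(s)

    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)

    ids = _species_ids(s)
    edges = {
        frozenset((ids[i], ids[j]))
        for i in range(s)
        for j in range(i + 1, s)
        if theta[i, j] != 0.0
    }
    return PlantedTruth(
        precision=pd.DataFrame(theta, index=ids, columns=ids),
        partial_corr=pd.DataFrame(rho, index=ids, columns=ids),
        edges=edges,
        clusters={ids[i]: int(clusters[i]) for i in range(s)},
    )


def _species_meta(spec: PlantedCommunitySpec, ids: list[str]) -> pd.DataFrame:
    clusters = spec.cluster_assignment
    rows = [
        {
            "species_id": ids[i],
            "ecological_group": ECOLOGICAL_GROUPS[clusters[i] % len(ECOLOGICAL_GROUPS)],
            "functional_group": FUNCTIONAL_GROUPS[clusters[i] % len(FUNCTIONAL_GROUPS)],
            "family": f"fam{clusters[i]}",
        }
        for i in range(spec.n_species)
    ]
    return validate_species_meta(pd.DataFrame(rows))


def _sample_meta(spec: PlantedCommunitySpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for r in range(spec.n_regions):
        region = f"region{r}"
        n_lakes = max(1, spec.n_samples // 9)
        for k in range(spec.n_samples):
            lake = rng.integers(n_lakes)
            shares = rng.dirichlet(np.ones(4)) * rng.uniform(0.8, 1.0)
            rows.append(
                {
                    "sample_id": f"{region}_s{k:04d}",
                    "region": region,
                    "lake_id": f"{region}_lake{lake}",
                    "habitat": int(rng.integers(1, 5)),
                    "stage": int(rng.integers(1, 4)),
                    "depth_cm": float(rng.uniform(10, 50)),
                    "detritus": int(rng.integers(1, 5)),
                    "floating_matter": int(rng.integers(1, 3)),
                    "shore": int(rng.integers(1, 3)),
                    "place": int(rng.integers(1, 4)),
                    "substratum": int(rng.integers(1, 4)),
                    "trophic_rank": int(rng.integers(1, 5)),
                    "area_ha": float(rng.uniform(0.4, 18.0)),
                    "cover_mat_pct": float(rng.uniform(2, 75)),
                    "Sm": float(shares[0]),
                    "Di": float(shares[1]),
                    "De": float(shares[2]),
                    "A": float(shares[3]),
                    "temperature": float(rng.normal(17.3, 6.1)),
                    "pH": float(rng.normal(5.43, 0.68)),
                    "EC": float(rng.normal(5.29, 0.82)),
                    "O2": float(rng.normal(85.0, 10.0)),
                    "HDI": float(rng.normal(142.2, 21.0)),
                }
            )
    return validate_sample_meta(pd.DataFrame(rows))


def simulate_community(
    truth: PlantedTruth, spec: PlantedCommunitySpec
) -> tuple[SurveyTable, pd.DataFrame, pd.DataFrame]:
    """Draw a survey dataset from the planted structure.

    Per sample: latent z ~ MVN(0, Theta^-1); biomass_i = exp(mu_c(region)
    + sigma z_i), independently set to 0 with probability zero_inflation;
    count_i = ceil(biomass_i / individual mass of species i), so biomass
    and abundance stay mutually consistent. Returns (survey, species_meta,
    sample_meta) in the standard schema. Fully determined by spec.seed.
    """
    ids = truth.species
    if len(ids) != spec.n_species:
        raise ValidationError("truth and spec disagree on species count")
    rng = np.random.default_rng(spec.seed)
    sigma_mat = np.linalg.inv(truth.precision.values)
    clusters = spec.cluster_assignment
    multipliers = spec.multipliers()
    individual_mass = rng.lognormal(
        mean=np.log(spec.median_individual_mass), sigma=spec.body_size_sigma, size=spec.n_species
    )
    records = []
    for r in range(spec.n_regions):
        region = f"region{r}"
        mu = spec.base_log_biomass + np.log(multipliers[r, clusters])
        z = rng.multivariate_normal(np.zeros(spec.n_species), sigma_mat, size=spec.n_samples)
        biomass = np.exp(mu + spec.sigma * z)
        if spec.zero_inflation > 0:
            mask = rng.random(biomass.shape) < spec.zero_inflation
            biomass[mask] = 0.0
        counts = np.ceil(biomass / individual_mass).astype(np.int64)
        for k in range(spec.n_samples):
            sample = f"{region}_s{k:04d}"
            for i, sp in enumerate(ids):
                if biomass[k, i] > 0:
                    records.append(
                        {
                            "sample_id": sample,
                            "species_id": sp,
                            "count": counts[k, i],
                            "biomass": biomass[k, i],
                        }
                    )
    survey = SurveyTable(pd.DataFrame(records))
    species_meta = _species_meta(spec, ids)
    sample_meta = _sample_meta(spec, rng)
    return survey, species_meta, sample_meta


def make_planted_community(
    spec: PlantedCommunitySpec,
) -> tuple[SurveyTable, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Convenience: precision + simulated survey in one call."""
    truth = make_planted_precision(spec)
    survey, species_meta, sample_meta = simulate_community(truth, spec)
    return survey, species_meta, sample_meta, truth


def recovery_benchmark(
    n_values=(100, 250, 500),
    n_seeds: int = 10,
    base_seed: int = 0,
    stars_subsamples: int = 50,
    **spec_overrides,
) -> pd.DataFrame:
    """Edge-recovery F1 of the full inference stack across sample sizes.

    For each n in ``n_values`` and each of ``n_seeds`` seeds (base_seed,
    base_seed+1, ...), generates the default planted community at that
    size, runs normalise → Pearson → glasso+StARS → significance filter,
    and scores the recovered edge set against the planted one. Returns a
    tidy frame with one row per (n, seed).
    """
    from .inference import infer_network
    from .io import build_biomass_matrix

    rows = []
    for n in n_values:
        for k in range(n_seeds):
            seed = int(base_seed) + k
            spec = PlantedCommunitySpec(n_samples=n, seed=seed, **spec_overrides)
            survey, _, _, truth = make_planted_community(spec)
            matrix = build_biomass_matrix(survey, value_kind="biomass")
            net, stars = infer_network(
                matrix, seed=seed, stars_subsamples=stars_subsamples
            )
            rep = recovery_report(net, truth)
            rows.append(
                {
                    "n": n,
                    "seed": seed,
                    "f1": rep["f1"],
                    "precision": rep["precision"],
                    "recall": rep["recall"],
                    "lambda_selected": stars.lambda_selected,
                }
            )
    return pd.DataFrame(rows)


def recovery_report(inferred: nx.Graph, truth: PlantedTruth) -> dict:
    """Edge-recovery precision, recall and F1 against the planted edge set."""
    if set(inferred.nodes) != set(truth.species):
        raise ValidationError("inferred network and truth cover different species")
    found = {frozenset(e) for e in inferred.edges}
    tp = len(found & truth.edges)
    precision = tp / len(found) if found else (1.0 if not truth.edges else 0.0)
    recall = tp / len(truth.edges) if truth.edges else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_inferred": len(found),
        "n_true": len(truth.edges),
    }
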