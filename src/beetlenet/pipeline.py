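"""Pipeline orchestration: config → per-region networks → reports → figures.

A run takes either input files (survey + species/sample metadata) or a
``simulate`` block describing a planted community, builds one network per
region, writes metric and statistics tables as tab-separated text plus
GraphML/edge-list exports, runs the cross-region Kruskal–Wallis tests and
the PCA, and records a manifest (seed, selected penalty per region,
dropped species, imputation counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import community, inference, io, metrics, ordination, simulate
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline configuration (one of ``survey_path`` / ``simulate`` set)."""

    outdir: str = "beetlenet_out"
    seed: int = 0
    survey_path: str | None = None
    species_meta_path: str | None = None
    sample_meta_path: str | None = None
    simulate: dict | None = None
    value_kind: str = "biomass"
    pseudocount: float | str = "auto"
    alpha: float = 0.05
    lambda_points: int = 20
    lambda_min_ratio: float = 0.05
    stars_subsamples: int = 50
    stars_threshold: float = 0.05
    pca_components: int = 2
    weighted_aggregation: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        has_files = self.survey_path is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValidationError("config needs exactly one of survey_path / simulate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        spec = simulate.PlantedCommunitySpec(**{**config.simulate, "seed": config.seed})
        survey, species_meta, sample_meta, truth = simulate.make_planted_community(spec)
        return survey, species_meta, sample_meta, truth
    survey = io.read_survey_table(config.survey_path)
    if config.species_meta_path is None or config.sample_meta_path is None:
        raise ValidationError("file inputs need species_meta_path and sample_meta_path")
    species_meta = io.read_species_meta(config.species_meta_path)
    sample_meta = io.read_sample_meta(config.sample_meta_path)
    return survey, species_meta, sample_meta, None


def spring_layout(net: nx.Graph, iterations: int = 100, seed: int = 0) -> dict:
    """Edge-weighted spring-embedded layout, |r| as spring strength.

    Stronger (higher |r|) edges pull their endpoints closer. Coordinates
    are centred and scaled to the unit box; a single node sits at the
    origin. Deterministic under a fixed seed.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot lay out an empty graph")
    if net.number_of_nodes() == 1:
        return {next(iter(net.nodes)): np.zeros(2)}
    pos = nx.spring_layout(net, weight="weight", iterations=iterations, seed=seed)
    coords = np.array(list(pos.values()))
    coords = coords - coords.mean(axis=0)
    extent = np.abs(coords).max()
    if extent > 0:
        coords = coords / extent
    return {v: coords[i] for i, v in enumerate(pos)}


def _network_figure(net: nx.Graph, path: Path, seed: int) -> None:
    pos = spring_layout(net, seed=seed)
    nm = metrics.node_metrics(net)
    sizes = 100 + 900 * nm.reindex(list(net.nodes))["ncc"].fillna(0.0).values
    colors = nm.reindex(list(net.nodes))["nbc"].fillna(0.0).values
    edge_colors = ["tab:orange" if d.get("sign", 1) >= 0 else "tab:blue" for _, _, d in net.edges(data=True)]
    widths = [1 + 3 * abs(d.get("pearson_r", 0.5)) for _, _, d in net.edges(data=True)]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        net, pos=pos, ax=ax, node_size=sizes, node_color=colors, cmap="plasma",
        edge_color=edge_colors, width=widths, font_size=6,
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _per_sample_parameters(
    abundance: io.BiomassMatrix, biomass: io.BiomassMatrix, species_meta: pd.DataFrame
) -> pd.DataFrame:
    counts = abundance.values
    out = pd.DataFrame(index=abundance.samples)
    out["N"] = counts.sum(axis=1)
    out["S"] = (counts > 0).sum(axis=1)
    out["H"] = [
        community.shannon_index(row[row > 0]) if (row > 0).any() else 0.0
        for row in counts.values
    ]
    out["biomass"] = biomass.values.reindex(
        index=abundance.samples, columns=abundance.species
    ).fillna(0.0).sum(axis=1)
    meta = species_meta.set_index(species_meta["species_id"].astype(str))
    for col in ("ecological_group", "functional_group"):
        labels = meta.reindex(abundance.species)[col]
        for group in sorted(labels.dropna().unique()):
            spp = [s for s in abundance.species if labels[s] == group]
            out[f"{group}_N"] = counts[spp].sum(axis=1)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle (also on disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    survey, species_meta, sample_meta, truth = _load_inputs(config)

    abundance = io.build_biomass_matrix(survey, value_kind="abundance")
    biomass = io.build_biomass_matrix(survey, value_kind=config.value_kind if config.value_kind != "abundance" else "biomass")
    regions = sorted(sample_meta["region"].unique())

    manifest = {"seed": config.seed, "regions": {}, "alpha": config.alpha}
    networks: dict[str, nx.Graph] = {}
    node_metric_frames = []
    summaries = []

    for region in regions:
        stage = f"network inference [{region}]"
        try:
            region_biomass = io.subset_by_region(biomass, sample_meta, region)
            region_abund = io.subset_by_region(abundance, sample_meta, region)
            normalized = inference.normalize_biomass(region_biomass, config.pseudocount)
            corr = inference.pearson_with_p(normalized)
            grid = inference.default_lambda_grid(
                np.corrcoef(normalized.values, rowvar=False),
                points=config.lambda_points,
                min_ratio=config.lambda_min_ratio,
            )
            rho, stars = inference.glasso_partial_correlations(
                normalized,
                lambda_grid=grid,
                stars_subsamples=config.stars_subsamples,
                stars_threshold=config.stars_threshold,
                seed=config.seed,
            )
            net = inference.build_network(rho, corr, alpha=config.alpha, species_meta=species_meta)
            metrics.annotate_network(net)
            networks[region] = net

            dropped = sorted(set(region_biomass.species) - set(normalized.columns))
            manifest["regions"][region] = {
                "n_samples": region_biomass.shape[0],
                "n_species": region_biomass.shape[1],
                "lambda_selected": stars.lambda_selected,
                "dropped_species": dropped,
                "n_edges": net.number_of_edges(),
            }

            io.write_network(net, outdir / f"network_{region}.graphml", format="graphml")
            io.write_network(net, outdir / f"edges_{region}.tsv", format="edge_list")
            nm = metrics.node_metrics(net)
            nm.to_csv(outdir / f"node_metrics_{region}.tsv", sep="\t")
            nm["region"] = region
            node_metric_frames.append(nm)
            metrics.edge_betweenness(net).to_csv(
                outdir / f"edge_betweenness_{region}.tsv", sep="\t", index=False
            )
            metrics.network_attributes(net).as_series().to_csv(
                outdir / f"network_attributes_{region}.tsv", sep="\t", header=False
            )
            summaries.append(
                community.region_summary(region_abund, region_biomass, species_meta, region)
            )
            if config.make_figures:
                _network_figure(net, outdir / f"network_{region}.png", seed=config.seed)
        except Exception as exc:  # noqa: BLE001 - stage-labelled abort
            raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    stage = "community statistics"
    try:
        pd.DataFrame(summaries).set_index("region").to_csv(
            outdir / "community_summary.tsv", sep="\t"
        )
        per_sample = _per_sample_parameters(abundance, biomass, species_meta)
        per_sample["region"] = sample_meta.reindex(per_sample.index)["region"]
        if len(regions) >= 2:  # region comparisons need something to compare
            params = [c for c in per_sample.columns if c != "region"]
            kw_table = community.regional_kw_report(per_sample, "region", params)
            kw_table.to_csv(outdir / "kruskal_wallis.tsv", sep="\t")
        else:
            kw_table = None
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    stage = "ordination"
    try:
        all_node_metrics = (
            pd.concat(node_metric_frames)
            .groupby(level=0)[["ndc", "ncc", "nbc", "local_clustering"]]
            .mean()
        )
        features = ordination.assemble_feature_table(
            abundance, biomass, species_meta, all_node_metrics, sample_meta,
            weighted=config.weighted_aggregation,
        )
        pca_res = ordination.pca(features, n_components=config.pca_components)
        pca_res.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
        pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.Series(
            pca_res.explained_variance_ratio,
            index=pca_res.loadings.columns,
            name="explained_variance_ratio",
        ).to_csv(outdir / "pca_explained.tsv", sep="\t")
        correlations = ordination.pairwise_variable_correlations(features)
        correlations.to_csv(outdir / "variable_correlations.tsv", sep="\t", index=False)
        if config.make_figures:
            _biplot(pca_res, outdir / "pca_biplot.png")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    result = {
        "networks": networks,
        "manifest": manifest,
        "summaries": summaries,
        "kw_table": kw_table,
        "pca": pca_res,
        "features": features,
        "correlations": correlations,
    }
    if truth is not None:
        recoveries = {}
        for region, net in networks.items():
            if set(net.nodes) == set(truth.species):
                recoveries[region] = simulate.recovery_report(net, truth)
        if recoveries:
            result["recovery"] = recoveries
            manifest["recovery"] = recoveries
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result


def _biplot(pca_res: ordination.PCAResult, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.scatter(pca_res.scores["PC1"], pca_res.scores["PC2"], s=8, alpha=0.4)
    scale = float(pca_res.scores.abs().max().max())
    for feat in pca_res.loadings.index:
        x, y = pca_res.loadings.loc[feat, ["PC1", "PC2"]] * scale
        ax.annotate(feat, (x, y), fontsize=6, color="tab:red")
        ax.plot([0, x], [0, y], color="tab:red", lw=0.5, alpha=0.6)
    evr = pca_res.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
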