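"""PCA ordination of community, network and environmental features.

Assembles a sample-level feature table (abundance and richness totals and
per-group breakdowns, total biomass, abundance-weighted means of the
network centralities of the species present, and the ordinal / continuous
environmental covariates), then runs a correlation-matrix PCA with a
deterministic sign convention, plus an all-pairs Pearson correlation
report of the features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import BiomassMatrix

log = logging.getLogger(__name__)

ENV_COLUMNS = (
    "habitat", "stage", "depth_cm", "detritus", "floating_matter", "shore",
    "place", "substratum", "trophic_rank", "area_ha", "cover_mat_pct",
    "Sm", "Di", "De", "A", "temperature", "pH", "EC", "O2", "HDI",
)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # feature × component
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # row × component


def aggregate_node_metrics(
    abundance: BiomassMatrix, node_metrics: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Per-sample means of the network metrics of the species present.

    ``weighted=True`` weights each species by its abundance in the sample;
    otherwise species present contribute equally.
    """
    metrics = node_metrics.reindex(abundance.species)
    out = {}
    for col in ("ndc", "ncc", "nbc", "local_clustering"):
        vals = metrics[col].values.astype(float)
        rows = []
        for _, counts in abundance.values.iterrows():
            w = counts.values.astype(float)
            present = (w > 0) & ~np.isnan(vals)
            if not present.any():
                rows.append(np.nan)
                continue
            weights = w[present] if weighted else np.ones(present.sum())
            rows.append(float(np.average(vals[present], weights=weights)))
        out[col] = rows
    return pd.DataFrame(out, index=abundance.samples)


def assemble_feature_table(
    abundance: BiomassMatrix,
    biomass: BiomassMatrix,
    species_meta: pd.DataFrame,
    node_metrics: pd.DataFrame,
    sample_meta: pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Sample-level feature table for ordination.

    Columns: N_total, S_total, total_biomass, per-group N and S, the
    aggregated network metrics, and any recognised environmental columns
    in ``sample_meta``. Missing covariates are imputed by column median
    (count logged); zero-variance columns are dropped with a warning.
    """
    counts = abundance.values
    feats = pd.DataFrame(index=abundance.samples)
    feats["N_total"] = counts.sum(axis=1)
    feats["S_total"] = (counts > 0).sum(axis=1)
    feats["total_biomass"] = biomass.values.reindex(
        index=abundance.samples, columns=abundance.species
    ).fillna(0.0).sum(axis=1)
    meta = species_meta.set_index(species_meta["species_id"].astype(str))
    for col in ("ecological_group", "functional_group"):
        labels = meta.reindex(abundance.species)[col]
        for group in sorted(labels.dropna().unique()):
            spp = [s for s in abundance.species if labels[s] == group]
            feats[f"{group}_N"] = counts[spp].sum(axis=1)
            feats[f"{group}_S"] = (counts[spp] > 0).sum(axis=1)
    agg = aggregate_node_metrics(abundance, node_metrics, weighted=weighted)
    feats = feats.join(agg.rename(columns=str.upper).rename(columns={"LOCAL_CLUSTERING": "clustering_coefficient"}))
    env = sample_meta.set_index(sample_meta["sample_id"].astype(str))
    env_cols = [c for c in ENV_COLUMNS if c in env.columns]
    feats = feats.join(env.reindex(feats.index)[env_cols].astype(float))
    if feats.empty:
        raise ValidationError("feature assembly produced an empty table")
    n_missing = int(feats.isna().sum().sum())
    if n_missing:
        log.info("imputing %d missing feature cells by column median", n_missing)
        feats = feats.fillna(feats.median())
    keep = feats.columns[feats.std(ddof=1) > 0]
    dropped = [c for c in feats.columns if c not in keep]
    if dropped:
        log.warning("dropping zero-variance feature(s): %s", dropped)
    return feats[keep]


def pca(features: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Correlation-matrix PCA with a deterministic sign convention.

    Columns are standardised (mean 0, sd 1, ddof=1); components are the
    eigenvectors of the correlation matrix, ordered by decreasing
    eigenvalue, each flipped so its largest-magnitude loading is positive.
    Explained variance ratios are eigenvalues over the number of features.
    """
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 rows and 2 columns")
    z = (features - features.mean()) / features.std(ddof=1)
    corr = np.corrcoef(z.values, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] *= -1.0
    if n_components is None:
        n_components = features.shape[1]
    n_components = min(n_components, features.shape[1])
    eigvals = eigvals[:n_components]
    eigvecs = eigvecs[:, :n_components]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    loadings = pd.DataFrame(eigvecs, index=features.columns, columns=comp_names)
    scores = pd.DataFrame(z.values @ eigvecs, index=features.index, columns=comp_names)
    ratio = eigvals / features.shape[1]
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=ratio,
        eigenvalues=eigvals,
        scores=scores,
    )


def pairwise_variable_correlations(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for every feature pair, sorted by |r|."""
    if features.shape[0] < 3:
        raise ValidationError("need at least 3 rows for correlation p-values")
    cols = list(features.columns)
    n = features.shape[0]
    r_mat = np.corrcoef(features.values, rowvar=False)
    rows = []
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            r = float(np.clip(r_mat[i, j], -1.0, 1.0))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rows.append({"var1": a, "var2": cols[j], "r": r, "p": p})
    out = pd.DataFrame(rows)
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
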