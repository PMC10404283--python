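"""Community summary statistics and non-parametric group comparisons.

Implements the descriptive side of the analysis: species richness S,
abundance N, dominance D (percentage of total abundance), the
Shannon–Wiener diversity index H' (natural log), aggregates per
ecological / functional group, and the Kruskal–Wallis H test with
Dunn-type post-hoc comparisons of mean ranks (Bonferroni-adjusted) for
contrasting regions.

Per-sample means reported alongside group totals are conditional on
presence: they average the non-zero (sample, species) cells of the
abundance matrix, i.e. the mean number of individuals per species
occurrence — the convention under which singleton groups have mean 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import BiomassMatrix


def shannon_index(counts) -> float:
    """Shannon–Wiener diversity H' = -sum p_i ln p_i, in nats.

    Zero-count species are ignored; a single-species community has H' = 0.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValidationError("Shannon index undefined for an all-zero community")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def dominance_table(matrix: BiomassMatrix) -> pd.Series:
    """Per-species dominance D: percentage of total abundance, sorted descending."""
    totals = matrix.values.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("dominance undefined: no individuals")
    pct = 100.0 * totals / grand
    return pct.sort_values(ascending=False, kind="mergesort")


def _occurrence_mean_sd(values: pd.DataFrame) -> tuple[float, float]:
    """Mean ± sample SD over the non-zero cells of a samples × species block."""
    cells = values.values[values.values > 0]
    if cells.size == 0:
        return float("nan"), float("nan")
    mean = float(cells.mean())
    sd = float(cells.std(ddof=1)) if cells.size > 1 else 0.0
    return mean, sd


def group_aggregate(
    matrix: BiomassMatrix, species_meta: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Per-group totals N, richness S, and occurrence mean ± SD.

    ``grouping`` is ``"ecological"`` or ``"functional"``. Every species in
    the matrix must be classified; group labels partition the species, so
    group N sums to total N.
    """
    col = {"ecological": "ecological_group", "functional": "functional_group"}.get(grouping)
    if col is None:
        raise ValidationError(f"unknown grouping {grouping!r}")
    meta = species_meta.set_index(species_meta["species_id"].astype(str))
    unclassified = [s for s in matrix.species if s not in meta.index]
    if unclassified:
        raise ValidationError(f"species without metadata: {unclassified}")
    rows = []
    labels = meta.loc[matrix.species, col]
    for group in sorted(labels.unique()):
        spp = [s for s in matrix.species if labels[s] == group]
        block = matrix.values[spp]
        n_total = float(block.values.sum())
        richness = int((block.sum(axis=0) > 0).sum())
        mean, sd = _occurrence_mean_sd(block)
        rows.append(
            {"group": group, "N": n_total, "S": richness, "mean": mean, "sd": sd}
        )
    return pd.DataFrame(rows).set_index("group")


def group_share(group_n: float, total_n: float) -> float:
    """Percentage share of a group's abundance in the community total."""
    if total_n <= 0:
        raise ValidationError("total abundance must be positive")
    return 100.0 * group_n / total_n


def region_summary(
    matrix: BiomassMatrix,
    biomass: BiomassMatrix,
    species_meta: pd.DataFrame,
    region: str = "",
) -> dict:
    """Community summary for one region: n, N, S, H', biomass, occurrence mean ± SD."""
    if matrix.value_kind != "abundance":
        raise ValidationError("region_summary needs an abundance matrix")
    totals = matrix.values.sum(axis=0)
    mean, sd = _occurrence_mean_sd(matrix.values)
    out = {
        "region": region,
        "n_samples": matrix.shape[0],
        "abundance_N": float(totals.sum()),
        "species_S": int((totals > 0).sum()),
        "shannon_H": shannon_index(totals.values),
        "total_biomass": float(biomass.values.to_numpy().sum()),
        "occurrence_mean": mean,
        "occurrence_sd": sd,
    }
    for grouping in ("ecological", "functional"):
        agg = group_aggregate(matrix, species_meta, grouping)
        for group, row in agg.iterrows():
            out[f"{group}_N"] = row["N"]
            out[f"{group}_S"] = row["S"]
    return out


# ---------------------------------------------------------------------------
# Kruskal–Wallis and post-hoc mean-rank comparisons


@dataclass
class KWResult:
    """Kruskal–Wallis test result with Dunn-type post-hoc comparisons."""

    H: float
    df: int
    p: float
    mean_ranks: dict
    group_sizes: dict
    posthoc: pd.DataFrame  # pairwise Bonferroni-adjusted p values


def _check_groups(values, groups) -> tuple[np.ndarray, np.ndarray, list]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have the same length")
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    for g in levels:
        if (groups == g).sum() == 0:
            raise ValidationError(f"group {g!r} has zero observations")
    return values, groups, levels


def kruskal_wallis(values, groups) -> KWResult:
    """Tie-corrected Kruskal–Wallis H test.

    H = [12 / (N (N+1)) * sum R_j^2 / n_j - 3 (N+1)] / C with the tie
    correction C = 1 - sum(t^3 - t) / (N^3 - N); p from a chi-square with
    k - 1 degrees of freedom. All-tied data give H = 0, p = 1.
    """
    values, groups, levels = _check_groups(values, groups)
    n_total = values.size
    ranks = stats.rankdata(values)  # midranks for ties
    rank_sums = {g: ranks[groups == g].sum() for g in levels}
    sizes = {g: int((groups == g).sum()) for g in levels}
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        rank_sums[g] ** 2 / sizes[g] for g in levels
    ) - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    df = len(levels) - 1
    if correction == 0.0:  # every observation identical
        h_corr, p = 0.0, 1.0
    else:
        h_corr = h / correction
        p = float(stats.chi2.sf(h_corr, df))
    mean_ranks = {g: rank_sums[g] / sizes[g] for g in levels}
    posthoc = posthoc_mean_ranks(values, groups)
    return KWResult(
        H=float(h_corr), df=df, p=p, mean_ranks=mean_ranks, group_sizes=sizes, posthoc=posthoc
    )


def posthoc_mean_ranks(values, groups) -> pd.DataFrame:
    """Dunn-type multiple comparison of mean ranks for all pairs of groups.

    z_ij = |Rbar_i - Rbar_j| / sqrt[(N (N+1) / 12) (1/n_i + 1/n_j)];
    two-sided normal p, Bonferroni-multiplied by the number of pairs and
    capped at 1. Adjusted p is never below the raw p.
    """
    values, groups, levels = _check_groups(values, groups)
    n_total = values.size
    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in levels}
    sizes = {g: (groups == g).sum() for g in levels}
    k = len(levels)
    n_pairs = k * (k - 1) // 2
    out = pd.DataFrame(np.nan, index=levels, columns=levels, dtype=float)
    for i, gi in enumerate(levels):
        for gj in levels[i + 1 :]:
            se = np.sqrt((n_total * (n_total + 1) / 12.0) * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            if se == 0:
                p_adj = 1.0
            else:
                z = abs(mean_ranks[gi] - mean_ranks[gj]) / se
                p_adj = min(1.0, 2.0 * stats.norm.sf(z) * n_pairs)
            out.loc[gi, gj] = p_adj
            out.loc[gj, gi] = p_adj
    return out


def regional_kw_report(
    per_sample: pd.DataFrame, region_col: str, parameters: list[str]
) -> pd.DataFrame:
    """Kruskal–Wallis tests of per-sample parameters across regions.

    ``per_sample`` holds one row per sample with a region column and the
    numeric parameters to compare (N, S, H', biomass, group N/S...).
    Returns a tidy table with H, df, p and the significant post-hoc pairs.
    """
    rows = []
    for param in parameters:
        res = kruskal_wallis(per_sample[param].values, per_sample[region_col].values)
        sig_pairs = []
        levels = list(res.posthoc.index)
        for i, gi in enumerate(levels):
            for gj in levels[i + 1 :]:
                p_adj = res.posthoc.loc[gi, gj]
                if p_adj <= 0.05:
                    sig_pairs.append(f"{gi}-{gj} ({p_adj:.2g})")
        rows.append(
            {
                "parameter": param,
                "H": res.H,
                "df": res.df,
                "p": res.p,
                "posthoc_significant": "; ".join(sig_pairs),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
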