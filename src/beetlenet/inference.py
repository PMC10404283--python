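"""Sparse partial-correlation network inference from biomass matrices.

The route from a samples × species biomass matrix to a species network:

1. normalise — log2(x + pseudocount) then per-column autoscaling, the
   standard variance-stabilising pretreatment for right-skewed, zero-rich
   biomass data;
2. Pearson correlations with two-sided t-test p-values (these become the
   display weights and the significance filter on edges);
3. graphical lasso on the sample correlation matrix, with the penalty
   selected by StARS (stability across row subsamples), giving a sparse
   precision matrix and hence partial correlations
   rho_ij = -theta_ij / sqrt(theta_ii theta_jj);
4. keep an edge (i, j) when the partial correlation is non-zero AND the
   Pearson correlation is significant at p <= alpha (no multiple-testing
   correction); the edge records both coefficients, the p-value and the
   sign of the Pearson correlation. Species absent or constant within a
   region are excluded from inference but retained in the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso

from .errors import InferenceError, ValidationError
from .io import BiomassMatrix

log = logging.getLogger(__name__)

PARTIAL_CORR_EPS = 1e-8


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass
class StarsResult:
    """Penalty-path bookkeeping from StARS selection."""

    lambda_selected: float
    lambda_grid: np.ndarray
    instability: np.ndarray  # monotonised instability per lambda (desc order)
    subsample_indices: list = field(default_factory=list)


def normalize_biomass(
    matrix: BiomassMatrix, pseudocount: float | str = "auto"
) -> pd.DataFrame:
    """log2(x + pseudocount) then autoscale each column to mean 0, sd 1 (ddof=1).

    ``pseudocount="auto"`` uses half the smallest positive value in the
    matrix. Columns with fewer than two distinct values carry no
    correlation information and are dropped with a warning.
    """
    values = matrix.values
    if values.size == 0:
        raise InferenceError("empty matrix")
    keep = [c for c in values.columns if values[c].nunique() >= 2]
    dropped = [c for c in values.columns if c not in keep]
    if dropped:
        log.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped)
    if not keep:
        raise InferenceError("all columns have zero variance")
    values = values[keep]
    if pseudocount == "auto":
        positive = values.values[values.values > 0]
        if positive.size == 0:
            raise InferenceError("matrix has no positive entries")
        pseudocount = float(positive.min()) / 2.0
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    logged = np.log2(values + pseudocount)
    return (logged - logged.mean()) / logged.std(ddof=1)


def pearson_with_p(normalized: pd.DataFrame) -> CorrelationResult:
    """All-pairs Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2)).

    Requires n >= 3 samples. |r| = 1 maps to p = 0; the p diagonal is 0 by
    convention (self-correlation is not a test).
    """
    n = normalized.shape[0]
    if n < 3:
        raise InferenceError(f"need at least 3 samples for correlation tests, got {n}")
    x = normalized.values
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    cols = normalized.columns
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


def _fit_glasso(S: np.ndarray, lam: float) -> np.ndarray | None:
    """One graphical-lasso fit; returns the precision matrix or None on failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, precision = graphical_lasso(S, alpha=lam, max_iter=200)
        return precision
    except (FloatingPointError, np.linalg.LinAlgError, ValueError):
        return None


def _partials_from_precision(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def _support(theta: np.ndarray) -> np.ndarray:
    rho = _partials_from_precision(theta)
    mask = np.abs(rho) > PARTIAL_CORR_EPS
    np.fill_diagonal(mask, False)
    return mask


def default_lambda_grid(S: np.ndarray, points: int = 20, min_ratio: float = 0.05) -> np.ndarray:
    """Log-spaced penalty grid from max |off-diagonal of S| down to a fixed ratio."""
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, points)


def glasso_partial_correlations(
    normalized: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    stars_subsamples: int = 50,
    stars_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, StarsResult]:
    """Sparse partial correlations via graphical lasso with StARS selection.

    The graphical lasso maximises log det(Theta) - tr(S Theta) -
    lambda ||Theta||_1,off over the sample correlation matrix S. StARS
    refits on ``stars_subsamples`` row subsamples of size floor(0.8 n) per
    penalty and selects the smallest lambda whose (monotonised) edge
    instability stays at or below ``stars_threshold``; if every penalty is
    unstable the largest one is returned with a warning. The full-data fit
    at the selected penalty yields rho_ij = -theta_ij/sqrt(theta_ii theta_jj).
    """
    x = normalized.values
    n, p = x.shape
    if n < 3:
        raise InferenceError("too few samples for inference")
    S = np.corrcoef(x, rowvar=False)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(S)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if (lambda_grid <= 0).any() or (np.diff(lambda_grid) >= 0).any():
        raise ValidationError("lambda grid must be positive and strictly decreasing")

    rng = np.random.default_rng(seed)
    m = int(np.floor(0.8 * n))
    subsamples = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(stars_subsamples)]
    n_lam = lambda_grid.size
    edge_freq = np.zeros((n_lam, p, p))
    fits_per_lam = np.zeros(n_lam, dtype=int)
    for idx in subsamples:
        S_b = np.corrcoef(x[idx], rowvar=False)
        for k, lam in enumerate(lambda_grid):
            theta = _fit_glasso(S_b, lam)
            if theta is None:
                log.warning("glasso failed on a subsample at lambda=%.4g; skipped", lam)
                continue
            edge_freq[k] += _support(theta)
            fits_per_lam[k] += 1

    instability = np.zeros(n_lam)
    iu = np.triu_indices(p, 1)
    for k in range(n_lam):
        if fits_per_lam[k] == 0:
            instability[k] = np.inf
            continue
        freq = edge_freq[k][iu] / fits_per_lam[k]
        instability[k] = float(np.mean(2.0 * freq * (1.0 - freq)))
    # monotonise: instability treated as non-decreasing with decreasing lambda
    monotone = np.maximum.accumulate(instability)

    stable = np.where(monotone <= stars_threshold)[0]
    if stable.size:
        k_sel = int(stable.max())  # smallest stable lambda (grid is decreasing)
    else:
        k_sel = 0
        log.warning("no penalty met the StARS stability threshold; using the largest")
    lam_sel = float(lambda_grid[k_sel])

    theta = _fit_glasso(S, lam_sel)
    if theta is None:  # fall back up the path to a penalty that converges
        for k in range(k_sel - 1, -1, -1):
            theta = _fit_glasso(S, float(lambda_grid[k]))
            if theta is not None:
                lam_sel = float(lambda_grid[k])
                break
    if theta is None:
        raise InferenceError("graphical lasso failed to converge on the full data")
    rho = _partials_from_precision(theta)
    cols = normalized.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        StarsResult(
            lambda_selected=lam_sel,
            lambda_grid=lambda_grid,
            instability=monotone,
            subsample_indices=subsamples,
        ),
    )


def build_network(
    partial_corr: pd.DataFrame,
    corr: CorrelationResult,
    alpha: float = 0.05,
    species_meta: pd.DataFrame | None = None,
) -> nx.Graph:
    """Assemble the species network from partial correlations + significance.

    Edge (i, j) exists iff |rho_ij| > 1e-8 and the Pearson p-value is at
    most ``alpha``. Edges carry pearson_r (display weight), partial_corr,
    p and sign; isolated species stay in the graph as nodes. Optional
    species metadata attaches group labels to nodes.
    """
    species = list(partial_corr.columns)
    if list(corr.r.columns) != species:
        raise ValidationError("species sets of partial and Pearson matrices differ")
    net = nx.Graph(n_samples=corr.n, alpha=alpha)
    for s in species:
        attrs = {}
        if species_meta is not None and s in species_meta.index:
            attrs = {
                "ecological_group": species_meta.at[s, "ecological_group"],
                "functional_group": species_meta.at[s, "functional_group"],
            }
        net.add_node(s, **attrs)
    for i, u in enumerate(species):
        for v in species[i + 1 :]:
            rho = float(partial_corr.at[u, v])
            p_val = float(corr.p.at[u, v])
            if abs(rho) > PARTIAL_CORR_EPS and p_val <= alpha:
                r_val = float(corr.r.at[u, v])
                net.add_edge(
                    u,
                    v,
                    partial_corr=rho,
                    pearson_r=r_val,
                    p=p_val,
                    sign=int(np.sign(r_val)),
                    weight=abs(r_val),
                )
    return net


def infer_network(
    matrix: BiomassMatrix,
    pseudocount: float | str = "auto",
    alpha: float = 0.05,
    lambda_grid: np.ndarray | None = None,
    stars_subsamples: int = 50,
    stars_threshold: float = 0.05,
    seed: int = 0,
    species_meta: pd.DataFrame | None = None,
) -> tuple[nx.Graph, StarsResult]:
    """Full normalise → correlate → glasso → filter route for one region."""
    normalized = normalize_biomass(matrix, pseudocount=pseudocount)
    corr = pearson_with_p(normalized)
    rho, stars = glasso_partial_correlations(
        normalized,
        lambda_grid=lambda_grid,
        stars_subsamples=stars_subsamples,
        stars_threshold=stars_threshold,
        seed=seed,
    )
    net = build_network(rho, corr, alpha=alpha, species_meta=species_meta)
    return net, stars
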