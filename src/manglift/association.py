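"""Mantel tests, correlation screens, distance-decay regressions and RACD.

RACD (relative abundance-weighted community degree) summarises a taxon
co-occurrence network: with edges where |Spearman ρ| ≥ a threshold at
p < 0.05, ``RACD = Σ_i w_i·k_i / n_nodes`` with w_i the mean relative
abundance and k_i the degree of taxon i.  The exact published formula is
not reproduced in the source literature; this operationalization is this
package's own and its thresholds are exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CommunityTable, DistanceMatrix, EnvFrame, to_relative

logger = logging.getLogger("manglift")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, method: str = "pearson",
    n_permutations: int = 999, seed: int = 0,
) -> MantelResult:
    """Mantel correlation of two distance matrices.

    One-tailed (greater) permutation p-value, permuting rows+columns of
    the second matrix jointly, add-one convention.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different ids")
    d2 = d2.align(d1.ids)
    n = len(d1.ids)
    iu, ju = np.triu_indices(n, k=1)
    x = d1.values[iu, ju]
    y = d2.values[iu, ju]
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance matrix in Mantel test")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    obs = float(np.mean(xs * ys))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    rows, cols = perms[:, iu], perms[:, ju]  # (P, M) index pairs
    vals = d2.values[rows, cols]
    if method == "spearman":
        vals = stats.rankdata(vals, axis=1)
    vs = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    null = vs @ xs / xs.size
    p = (1 + np.sum(null >= obs)) / (n_permutations + 1)
    return MantelResult(r=obs, p=float(p), n_permutations=n_permutations, method=method)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_screen(
    ratios: pd.DataFrame, env: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations of ratio columns against environment columns.

    Returns a long table with r, two-tailed p, significance stars, and a
    Benjamini–Hochberg adjusted column.
    """
    rows = []
    for rcol in ratios.columns:
        for ecol in env.columns:
            paired = pd.concat([ratios[rcol], env[ecol]], axis=1, join="inner").dropna()
            if len(paired) < 3:
                raise ValueError(f"fewer than 3 paired observations for {rcol} vs {ecol}")
            x, y = paired.iloc[:, 0].values, paired.iloc[:, 1].values
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning("zero-variance pair %s vs %s; NaN emitted", rcol, ecol)
                r, p = np.nan, np.nan
            elif method == "pearson":
                r, p = stats.pearsonr(x, y)
            elif method == "spearman":
                r, p = stats.spearmanr(x, y)
            else:
                raise ValueError(f"unknown method: {method!r}")
            rows.append({"ratio": rcol, "variable": ecol, "r": r, "p": p, "n": len(paired)})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_bh"] = np.nan
    if mask.any():
        out.loc[mask, "p_bh"] = stats.false_discovery_control(out.loc[mask, "p"], method="bh")
    out["stars"] = out["p"].map(lambda p: _stars(p) if np.isfinite(p) else "")
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def distance_decay(metric_pairs: np.ndarray, geo_pairs: np.ndarray) -> RegressionResult:
    """OLS of a pairwise community metric on pairwise geographic distance.

    Pairwise observations are not independent; the classical p-value is
    reported with that caveat (see methods note).
    """
    x = np.asarray(geo_pairs, dtype=float)
    y = np.asarray(metric_pairs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all distances equal")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue), n=int(x.size),
    )


def pairwise_from_matrix(dist: DistanceMatrix) -> np.ndarray:
    return dist.condensed()


@dataclass
class RacdResult:
    group: str
    racd: float
    n_nodes: int
    n_edges: int
    corr_threshold: float


def racd(
    table: CommunityTable, group=None, corr_threshold: float = 0.6,
    p_threshold: float = 0.05, min_prevalence: int = 3, group_name: str = "all",
) -> RacdResult:
    """Relative abundance-weighted community degree of a sample group."""
    sub = table if group is None else table.subset_samples(list(group))
    if sub.n_samples < 5:
        raise ValueError("RACD needs at least 5 samples")
    rel = to_relative(sub)
    prev = (sub.counts > 0).sum(axis=0)
    keep = np.flatnonzero(prev >= min_prevalence)
    if keep.size < 2:
        logger.warning("fewer than 2 eligible taxa in group %r; RACD = 0", group_name)
        return RacdResult(group=group_name, racd=0.0, n_nodes=int(keep.size), n_edges=0,
                          corr_threshold=corr_threshold)
    x = rel.counts[:, keep]
    rho, pval = stats.spearmanr(x)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    adj = (np.abs(rho) >= corr_threshold) & (pval < p_threshold)
    np.fill_diagonal(adj, False)
    degree = adj.sum(axis=1)
    weights = x.mean(axis=0)
    n_nodes = keep.size
    value = float((weights * degree).sum() / n_nodes)
    return RacdResult(
        group=group_name, racd=value, n_nodes=int(n_nodes),
        n_edges=int(adj.sum() // 2), corr_threshold=corr_threshold,
    )
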