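"""Alpha diversity, Bray–Curtis dissimilarity, NMDS, ANOSIM and β-dispersion."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

from .core_data import CommunityTable, DistanceMatrix

logger = logging.getLogger("manglift")


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = −Σ p_i log p_i of one abundance vector.

    Natural log by default; pass ``base`` to change units.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity(table: CommunityTable, base: float | None = None) -> dict[str, float]:
    return {sid: shannon(row, base=base) for sid, row in zip(table.sample_ids, table.counts)}


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    sums = table.counts.sum(axis=1)
    if (sums == 0).sum() >= 1:
        raise ValueError("all-zero sample(s) make Bray-Curtis undefined")
    d = squareform(pdist(table.counts, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float  # Kruskal stress-1
    n_restarts_used: int
    converged: bool
    sample_ids: list[str]


def nmds(
    dist: DistanceMatrix, k: int = 2, n_restarts: int = 20,
    max_iter: int = 300, tol: float = 1e-7, seed: int = 0,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling, best of ``n_restarts`` by stress-1.

    Uses SMACOF majorization with isotonic regression on the
    dissimilarities; the reported stress is Kruskal's stress-1.
    """
    n = len(dist.ids)
    if k >= n:
        raise ValueError("k must be below the number of samples")
    kwargs = dict(
        n_components=k, n_init=n_restarts, max_iter=max_iter, eps=tol,
        random_state=seed, normalized_stress=True,
    )
    try:
        mds = MDS(metric_mds=False, metric="precomputed", init="random", **kwargs)
    except TypeError:  # older sklearn API
        mds = MDS(metric=False, dissimilarity="precomputed", **kwargs)
    coords = mds.fit_transform(dist.values)
    converged = bool(mds.n_iter_ < max_iter)
    if not converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    return OrdinationResult(
        coordinates=coords, stress=float(mds.stress_),
        n_restarts_used=n_restarts, converged=converged,
        sample_ids=list(dist.ids),
    )


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


def anosim(dist: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities: R = (r̄_between − r̄_within) / (M/2).

    One-tailed permutation p-value with the add-one convention.
    """
    labels = np.asarray(list(groups))
    if labels.size != len(dist.ids):
        raise ValueError("group labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = uniq[counts < 2]
        raise ValueError(f"singleton group(s): {list(bad)}")
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dist.values[iu, ju])
    codes = np.unique(labels, return_inverse=True)[1]
    obs = _anosim_r(ranks, codes[iu] == codes[ju])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    within_all = perms[:, iu] == perms[:, ju]  # (P, M)
    m = ranks.size
    sum_all = ranks.sum()
    sum_within = within_all @ ranks
    n_within = within_all.sum(axis=1)
    mean_within = sum_within / n_within
    mean_between = (sum_all - sum_within) / (m - n_within)
    null = (mean_between - mean_within) / (m / 2)
    p = (1 + np.sum(null >= obs)) / (n_permutations + 1)
    return AnosimResult(R=float(obs), p_value=float(p), n_permutations=n_permutations)


def beta_dispersion(dist: DistanceMatrix, groups) -> dict[str, float]:
    """Per-group mean distance to the group centroid in PCoA space.

    Negative eigenvalue axes contribute negatively (imaginary-part
    correction), as in the standard β-dispersion procedure.
    """
    labels = np.asarray(list(groups))
    d = dist.values
    n = d.shape[0]
    # principal-coordinate embedding via double centring
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.abs(evals) > 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(np.abs(evals))
    pos = evals > 0
    out: dict[str, float] = {}
    for grp in np.unique(labels):
        idx = np.flatnonzero(labels == grp)
        if idx.size < 2:
            logger.warning("group %r has a single member; excluded from dispersion", grp)
            continue
        centroid = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - centroid) ** 2
        # real axes add, imaginary axes subtract squared distance
        z2 = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
        out[str(grp)] = float(np.sqrt(np.clip(z2, 0, None)).mean())
    return out
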