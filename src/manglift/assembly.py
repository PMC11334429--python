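"""Null-model partitioning of community assembly processes.

Pairwise βMNTD (abundance-weighted mean nearest-taxon phylogenetic
distance) is compared to a tip-label-shuffle null to give βNTI z-scores;
Bray–Curtis Raup–Crick (RCbray) uses richness- and abundance-preserving
null communities.  Pairs are then classified with the standard
thresholds: βNTI > +2 heterogeneous selection, βNTI < −2 homogeneous
selection, otherwise RCbray > +0.95 dispersal limitation, RCbray < −0.95
homogenizing dispersal, else drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import CommunityTable, DistanceMatrix

logger = logging.getLogger("manglift")

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def patristic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Pairwise patristic (branch-length) distances for the given tip labels."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    sub = tree.extract_tree_with_taxa_labels(taxa)
    pdm = sub.phylogenetic_distance_matrix()
    index = {t.label: t for t in sub.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(index[taxa[i]], index[taxa[j]])
    return d


def _bmntd_from_patristic(weights: np.ndarray, d: np.ndarray) -> np.ndarray:
    """All-pairs abundance-weighted βMNTD given relative-abundance weights.

    ``weights`` is samples × taxa (rows sum to 1, zeros for absent taxa).
    For each recipient community b, ``m_b[i]`` is taxon i's nearest-taxon
    distance into b; βMNTD(a,b) = ½(Σ_i w_ai m_b[i] + Σ_j w_bj m_a[j]).
    """
    n_samples, n_taxa = weights.shape
    m = np.empty((n_samples, n_taxa))
    for s in range(n_samples):
        idx = np.flatnonzero(weights[s] > 0)
        m[s] = d[:, idx].min(axis=1)
    t = weights @ m.T  # t[a, b] = Σ_i w_ai · m_b[i]
    out = 0.5 * (t + t.T)
    np.fill_diagonal(out, 0.0)
    return out


def _weights(table: CommunityTable) -> np.ndarray:
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("all-zero sample in community table")
    return table.counts / sums[:, None]


def beta_mntd(table: CommunityTable, tree: dendropy.Tree, weighted: bool = True) -> DistanceMatrix:
    """Between-community mean nearest-taxon distance (abundance-weighted by default)."""
    d = patristic_matrix(tree, list(table.asv_ids))
    w = _weights(table) if weighted else _presence_weights(table)
    return DistanceMatrix(list(table.sample_ids), _bmntd_from_patristic(w, d))


def _presence_weights(table: CommunityTable) -> np.ndarray:
    pres = table.presence().astype(float)
    return pres / pres.sum(axis=1)[:, None]


def beta_nti(
    table: CommunityTable, tree: dendropy.Tree, n_null: int = 999,
    seed: int = 0, weighted: bool = True,
) -> pd.DataFrame:
    """βNTI z-scores: (observed βMNTD − null mean) / null sd.

    Null model shuffles tip labels across the whole tree (taxa shuffle),
    i.e. permutes rows/columns of the patristic matrix.  Pairs with zero
    null variance get NaN with a warning.
    """
    d = patristic_matrix(tree, list(table.asv_ids))
    w = _weights(table) if weighted else _presence_weights(table)
    obs = _bmntd_from_patristic(w, d)
    rng = np.random.default_rng(seed)
    n_taxa = d.shape[0]
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        bm = _bmntd_from_patristic(w, d[np.ix_(perm, perm)])
        null_sum += bm
        null_sq += bm**2
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd <= 1e-12] = np.nan
    np.fill_diagonal(z, 0.0)
    n_nan = int(np.isnan(z[np.triu_indices_from(z, 1)]).sum())
    if n_nan:
        logger.warning("βNTI undefined (zero null variance) for %d pairs", n_nan)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def raup_crick_bray(table: CommunityTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Raup–Crick on Bray–Curtis, scaled to [−1, 1].

    Null communities preserve each sample's richness and read total:
    taxa are drawn without replacement with probability proportional to
    occupancy, then reads are allocated one per member plus a multinomial
    draw proportional to regional relative abundance.
    ``RC = 2·(P(null < obs) + ½·P(null = obs)) − 1``.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    counts = table.counts
    n_samples, n_taxa = counts.shape
    pres = counts > 0
    occupancy = pres.sum(axis=0).astype(float)
    occ_p = occupancy / occupancy.sum()
    abund = counts.sum(axis=0)
    richness = pres.sum(axis=1)
    totals = counts.sum(axis=1).astype(int)
    obs = squareform(pdist(counts, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs)
    equal = np.zeros_like(obs)
    for _ in range(n_null):
        null_counts = np.zeros((n_samples, n_taxa))
        for s in range(n_samples):
            members = rng.choice(n_taxa, size=int(richness[s]), replace=False, p=occ_p)
            w = abund[members].astype(float)
            extra = rng.multinomial(totals[s] - richness[s], w / w.sum())
            null_counts[s, members] = 1 + extra
        null_d = squareform(pdist(null_counts, metric="braycurtis"))
        less += null_d < obs
        equal += np.isclose(null_d, obs)
    rc = 2 * ((less + 0.5 * equal) / n_null) - 1
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class AssemblyPartition:
    pairs: pd.DataFrame  # sample_a, sample_b, betaNTI, RC_bray, process
    fractions: pd.Series  # process -> fraction (NaN pairs excluded)


def classify_pair(bnti: float, rc: float, bnti_threshold: float = 2.0, rc_threshold: float = 0.95) -> str:
    if np.isnan(bnti):
        return "undefined"
    if bnti > bnti_threshold:
        return "heterogeneous_selection"
    if bnti < -bnti_threshold:
        return "homogeneous_selection"
    if rc > rc_threshold:
        return "dispersal_limitation"
    if rc < -rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    bnti: pd.DataFrame, rc: pd.DataFrame,
    bnti_threshold: float = 2.0, rc_threshold: float = 0.95,
) -> AssemblyPartition:
    """Classify every sample pair and report process fractions."""
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise ValueError("βNTI and RC matrices are not aligned")
    ids = list(bnti.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b, r = float(bnti.iat[i, j]), float(rc.iat[i, j])
            rows.append(
                {
                    "sample_a": ids[i], "sample_b": ids[j],
                    "betaNTI": b, "RC_bray": r,
                    "process": classify_pair(b, r, bnti_threshold, rc_threshold),
                }
            )
    pairs = pd.DataFrame(rows)
    valid = pairs[pairs["process"] != "undefined"]
    n_nan = len(pairs) - len(valid)
    if n_nan:
        logger.warning("excluded %d pairs with undefined βNTI from fractions", n_nan)
    fractions = valid["process"].value_counts(normalize=True)
    fractions = fractions.reindex(PROCESSES, fill_value=0.0)
    return AssemblyPartition(pairs=pairs, fractions=fractions)
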