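"""Redundancy analysis and variation partitioning among predictor blocks.

The community response is Hellinger-transformed (square root of relative
abundance) before the least-squares RDA fit; explained variance is
adjusted with the Ezekiel formula 1 − (1−R²)(n−1)/(n−p−1).  Venn
fractions over 2–4 blocks come from all-subset adjusted R² by Möbius
(inclusion–exclusion) inversion, so every subset's adjusted R² is
reconstructed exactly by summing the atoms it touches.  Fractions can be
negative — a known property of adjusted R² — and are reported as
computed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CommunityTable, to_relative

logger = logging.getLogger("manglift")


def hellinger(table: CommunityTable) -> np.ndarray:
    """Hellinger transform: square root of relative abundances."""
    return np.sqrt(to_relative(table).counts)


def _pivoted_qr(x: np.ndarray):
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    return r, piv


def _qr_rank(r: np.ndarray, tol: float) -> int:
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return 0
    return int((diag > tol * diag[0]).sum())


def rda_r2(response: np.ndarray, predictors: np.ndarray, adjusted: bool = True) -> float:
    """RDA explained-variance share of a (multivariate) response.

    Both sides are column-centred; R² = ‖Ŷ‖²/‖Y‖² from the least-squares
    fit, adjusted by Ezekiel's formula using the predictor rank.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    y = y - y.mean(axis=0)
    x = x - x.mean(axis=0)
    r, piv = _pivoted_qr(x)
    rank = _qr_rank(r, 1e-10)
    if rank < x.shape[1]:
        logger.warning("dropped %d collinear predictor(s)", x.shape[1] - rank)
    x = x[:, np.sort(piv[:rank])]
    p = x.shape[1]
    if n <= p + 1:
        raise ValueError(f"too few samples ({n}) for {p} predictors")
    sst = float((y**2).sum())
    if sst == 0:
        raise ValueError("constant response")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    ssf = float(((x @ beta) ** 2).sum())
    r2 = ssf / sst
    if not adjusted:
        return r2
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VpaResult:
    """Venn decomposition of adjusted R² among named predictor blocks."""

    block_names: list[str]
    #: atom fractions keyed by frozenset of block names (shared among exactly those)
    atoms: dict = field(default_factory=dict)
    subset_r2: dict = field(default_factory=dict)  # frozenset -> adjusted R² of union
    residual: float = 0.0

    @property
    def total_explained(self) -> float:
        return sum(self.atoms.values())

    def unique(self, block: str) -> float:
        return self.atoms[frozenset([block])]

    def reconstruct(self, blocks) -> float:
        """Adjusted R² of a block subset, rebuilt from the atoms (exact identity)."""
        s = frozenset(blocks)
        return sum(v for k, v in self.atoms.items() if k & s)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fraction": "&".join(sorted(k)), "n_blocks": len(k), "adj_r2": v}
            for k, v in sorted(self.atoms.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        rows.append({"fraction": "residual", "n_blocks": 0, "adj_r2": self.residual})
        return pd.DataFrame(rows)


def variation_partition(response: np.ndarray, blocks: dict[str, np.ndarray]) -> VpaResult:
    """Partition response variance among 2–4 predictor blocks.

    ``blocks`` maps block name → predictor matrix (aligned rows).
    """
    names = list(blocks)
    if not 2 <= len(names) <= 4:
        raise ValueError("variation partitioning supports 2-4 blocks")
    y = np.asarray(response, dtype=float)
    mats = {k: (np.asarray(v, float)[:, None] if np.asarray(v).ndim == 1 else np.asarray(v, float)) for k, v in blocks.items()}

    subset_r2: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            x = np.hstack([mats[c] for c in combo])
            subset_r2[frozenset(combo)] = rda_r2(y, x)

    full = frozenset(names)
    r_full = subset_r2[full]

    def h(w: frozenset) -> float:
        if not w:
            return 0.0
        if w == full:
            return r_full
        return r_full - subset_r2[full - w]

    atoms: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            t = frozenset(combo)
            val = 0.0
            for k2 in range(0, len(combo) + 1):
                for sub in itertools.combinations(combo, k2):
                    val += (-1) ** (len(t) - k2) * h(frozenset(sub))
            atoms[t] = val

    return VpaResult(
        block_names=names, atoms=atoms, subset_r2=subset_r2, residual=1 - r_full
    )
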