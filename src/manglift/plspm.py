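"""Partial least squares path modeling (PLS-PM) with reflective blocks.

Latent variables are measured by reflective (mode A) indicator blocks
and connected by an acyclic inner path model.  Estimation follows the
Lohmöller algorithm: inner approximation by the chosen scheme (path,
centroid or factorial), outer weights as indicator–proxy correlations,
latent scores renormalized to unit variance each round, iterated to
convergence of the outer weights.  Path coefficients are then OLS fits
of each endogenous latent on its predecessors; indirect effects are the
matrix power series of the path-coefficient matrix; the goodness of fit
is sqrt(mean communality × mean R² over endogenous latents).  Bootstrap
resampling of rows (with sign correction against the original loadings)
gives standard errors and normal-approximation p-values for the paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PathModel:
    """Inner/outer specification of a PLS path model.

    ``paths`` lists directed edges (source, target); the implied
    adjacency must be acyclic with latents orderable so that the matrix
    is lower-triangular.  Every indicator belongs to exactly one block.
    """

    latent_names: list[str]
    paths: list[tuple[str, str]]
    blocks: dict[str, list[str]]
    scheme: str = "path"
    max_iter: int = 300
    tol: float = 1e-6
    bootstrap_n: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        order = {name: i for i, name in enumerate(self.latent_names)}
        for src, dst in self.paths:
            if src not in order or dst not in order:
                raise ValueError(f"path {src}->{dst} names an unknown latent")
            if order[src] >= order[dst]:
                raise ValueError(
                    f"path {src}->{dst} violates the declared ordering (inner model must be acyclic)"
                )
        if self.scheme not in ("path", "centroid", "factorial"):
            raise ValueError(f"unknown scheme: {self.scheme!r}")
        seen: set[str] = set()
        for name in self.latent_names:
            block = self.blocks.get(name, [])
            if not block:
                raise ValueError(f"latent {name!r} has an empty indicator block")
            dup = seen & set(block)
            if dup:
                raise ValueError(f"indicator(s) in more than one block: {sorted(dup)}")
            seen |= set(block)

    def inner_matrix(self) -> np.ndarray:
        n = len(self.latent_names)
        order = {name: i for i, name in enumerate(self.latent_names)}
        m = np.zeros((n, n))
        for src, dst in self.paths:
            m[order[dst], order[src]] = 1.0  # column -> row
        return m

    def endogenous(self) -> list[str]:
        targets = {dst for _, dst in self.paths}
        return [name for name in self.latent_names if name in targets]


@dataclass
class PlsPmResult:
    model: PathModel
    outer_weights: pd.Series  # indicator -> weight
    loadings: pd.Series  # indicator -> correlation with own latent
    scores: pd.DataFrame  # rows × latents, unit variance
    path_coefficients: pd.DataFrame  # rows=target, columns=source (0 where no path)
    r_squared: pd.Series  # per endogenous latent
    communalities: pd.Series  # loading² per indicator
    effects: pd.DataFrame = field(default=None)
    boot_se: pd.DataFrame = field(default=None)
    boot_p: pd.DataFrame = field(default=None)
    n_iter: int = 0

    @property
    def gof(self) -> float:
        return float(np.sqrt(self.communalities.mean() * self.r_squared.mean()))


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant indicator column")
    return (x - mu) / sd


def _iterate_weights(x_blocks, inner, scheme, max_iter, tol):
    """Lohmöller outer-weight iteration; returns (weights per block, n_iter)."""
    n_lat = len(x_blocks)
    weights = [np.ones(b.shape[1]) for b in x_blocks]
    n = x_blocks[0].shape[0]

    def scores_from(wts):
        lv = np.column_stack([b @ w for b, w in zip(x_blocks, wts)])
        sd = lv.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("degenerate latent score (zero variance)")
        return lv / sd

    lv = scores_from(weights)
    connected = (inner + inner.T) > 0
    for it in range(1, max_iter + 1):
        corr = lv.T @ lv / n
        if scheme == "centroid":
            e = np.sign(corr) * connected
        elif scheme == "factorial":
            e = corr * connected
        else:  # path scheme
            e = np.zeros((n_lat, n_lat))
            for i in range(n_lat):
                preds = np.flatnonzero(inner[i] > 0)
                if preds.size:
                    b = np.linalg.solve(corr[np.ix_(preds, preds)], corr[preds, i])
                    e[i, preds] = b
                succ = np.flatnonzero(inner[:, i] > 0)
                e[i, succ] = corr[i, succ]
        z = lv @ e.T
        zsd = z.std(axis=0, ddof=0)
        if np.any(zsd == 0):
            raise ValueError("inner proxy with zero variance (disconnected latent?)")
        z /= zsd
        new_weights = []
        for b, zi in zip(x_blocks, z.T):
            w = b.T @ zi / n  # mode A: indicator-proxy correlations
            new_weights.append(w)
        # normalize so each latent score has unit variance
        normed = [w / (b @ w).std(ddof=0) for b, w in zip(x_blocks, new_weights)]
        # convergence on the summed squared change of absolute weights
        # (sign-indeterminacy-safe, the usual PLS-PM criterion)
        delta = sum(
            float(np.sum((np.abs(wn) - np.abs(wo)) ** 2)) for wn, wo in zip(normed, weights)
        )
        weights = normed
        lv = scores_from(weights)
        if delta < tol:
            return weights, it
    raise RuntimeError(
        f"PLS-PM outer weights did not converge in {max_iter} iterations (last change {delta:.3g})"
    )


def _fit_core(data: pd.DataFrame, model: PathModel):
    x_blocks = []
    for name in model.latent_names:
        cols = model.blocks[name]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks indicator column(s): {missing}")
        block = data[cols].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise ValueError("missing values in indicators; impute upstream")
        x_blocks.append(_standardize(block))
    inner = model.inner_matrix()
    weights, n_iter = _iterate_weights(x_blocks, inner, model.scheme, model.max_iter, model.tol)
    n = x_blocks[0].shape[0]
    lv = np.column_stack([b @ w for b, w in zip(x_blocks, weights)])
    lv /= lv.std(axis=0, ddof=0)

    # orient each latent with its block (majority-positive loadings)
    for k, b in enumerate(x_blocks):
        load = b.T @ lv[:, k] / n
        if load.sum() < 0:
            lv[:, k] *= -1
            weights[k] = -weights[k]

    n_lat = len(model.latent_names)
    paths = np.zeros((n_lat, n_lat))
    r2 = {}
    for i in range(n_lat):
        preds = np.flatnonzero(inner[i] > 0)
        if preds.size == 0:
            continue
        x = lv[:, preds]
        try:
            beta = np.linalg.solve(x.T @ x, x.T @ lv[:, i])
        except np.linalg.LinAlgError:
            raise RuntimeError(
                f"singular inner regression for latent {model.latent_names[i]!r}"
            ) from None
        paths[i, preds] = beta
        fitted = x @ beta
        r2[model.latent_names[i]] = float(np.var(fitted) / np.var(lv[:, i]))
    loadings = {}
    for name, b, k in zip(model.latent_names, x_blocks, range(n_lat)):
        for col, x in zip(model.blocks[name], b.T):
            loadings[col] = float(np.corrcoef(x, lv[:, k])[0, 1])
    return weights, lv, paths, r2, loadings, n_iter


def effects_decomposition(paths: np.ndarray, latent_names: list[str]) -> pd.DataFrame:
    """Direct/indirect/total effects; indirect = Σ_{k≥2} (B^k)."""
    n = paths.shape[0]
    total = np.zeros_like(paths)
    power = np.eye(n)
    for _ in range(n):
        power = power @ paths
        total += power
    indirect = total - paths
    rows = []
    for j, src in enumerate(latent_names):
        for i, dst in enumerate(latent_names):
            if i == j:
                continue
            if paths[i, j] == 0 and indirect[i, j] == 0:
                continue
            rows.append(
                {
                    "from": src, "to": dst,
                    "direct": paths[i, j], "indirect": indirect[i, j],
                    "total": total[i, j],
                }
            )
    return pd.DataFrame(rows)


def fit_plspm(data: pd.DataFrame, model: PathModel, bootstrap: bool = True) -> PlsPmResult:
    """Fit a PLS path model; optionally bootstrap path-coefficient errors."""
    if len(data) <= max(len(b) for b in model.blocks.values()) + 2:
        raise ValueError("too few rows for the largest indicator block")
    weights, lv, paths, r2, loadings, n_iter = _fit_core(data, model)
    names = model.latent_names
    indicator_index = [c for name in names for c in model.blocks[name]]
    w_series = pd.Series(
        np.concatenate(weights), index=indicator_index, name="outer_weight"
    )
    load_series = pd.Series({c: loadings[c] for c in indicator_index}, name="loading")
    comm = load_series**2
    comm.name = "communality"
    paths_df = pd.DataFrame(paths, index=names, columns=names)
    r2_series = pd.Series(r2, name="r_squared").reindex(model.endogenous()).fillna(0.0)
    result = PlsPmResult(
        model=model,
        outer_weights=w_series,
        loadings=load_series,
        scores=pd.DataFrame(lv, index=data.index, columns=names),
        path_coefficients=paths_df,
        r_squared=r2_series,
        communalities=comm,
        n_iter=n_iter,
    )
    result.effects = effects_decomposition(paths, names)

    if bootstrap and model.bootstrap_n > 0:
        rng = np.random.default_rng(model.seed)
        n = len(data)
        boots = []
        for _ in range(model.bootstrap_n):
            idx = rng.integers(0, n, size=n)
            sample = data.iloc[idx]
            try:
                _, _, bpaths, _, bload, _ = _fit_core(sample, model)
            except (ValueError, RuntimeError):
                continue
            # sign correction: align each latent with the original loadings
            flip = np.ones(len(names))
            for k, name in enumerate(names):
                orig = np.array([loadings[c] for c in model.blocks[name]])
                new = np.array([bload[c] for c in model.blocks[name]])
                if float(orig @ new) < 0:
                    flip[k] = -1
            bpaths = bpaths * np.outer(flip, flip)
            boots.append(bpaths)
        if boots:
            arr = np.stack(boots)
            se = arr.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                zstat = np.abs(paths) / se
            pvals = 2 * stats.norm.sf(zstat)
            mask = model.inner_matrix() > 0
            se[~mask] = 0.0
            pvals[~mask] = np.nan
            result.boot_se = pd.DataFrame(se, index=names, columns=names)
            result.boot_p = pd.DataFrame(pvals, index=names, columns=names)
    return result


def gof(result: PlsPmResult) -> float:
    """Goodness of fit: sqrt(mean communality × mean R² over endogenous latents)."""
    return result.gof
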