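"""Data model and I/O for community tables, metadata, environment tables and distances.

The central object is :class:`CommunityTable`, a samples × ASVs count matrix.
On disk the common amplicon convention is used (rows = ASVs, columns =
samples, first header cell ``#ASV_ID``); in memory everything is oriented
samples × ASVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("manglift")

COMPARTMENTS = ("NS", "RS", "RE", "LE")
#: internal transmission chain, soil to leaves
CHAIN = (("NS", "RS"), ("RS", "RE"), ("RE", "LE"))
EARTH_RADIUS_KM = 6371.0

ENV_BLOCKS = ("soil_properties", "nutrients", "climate", "biotic", "geography")


class DataError(ValueError):
    """Raised for invalid or inconsistent input data."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CommunityTable:
    """Samples × ASVs abundance matrix.

    Parameters
    ----------
    sample_ids, asv_ids
        Unique identifiers for rows and columns.
    counts
        Non-negative numeric matrix, shape ``(n_samples, n_asvs)``.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.asv_ids = [str(a).strip() for a in self.asv_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.asv_ids, "ASV")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.asv_ids)} ASVs"
            )
        if np.any(self.counts < 0):
            raise DataError("negative counts are not allowed")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def presence(self) -> np.ndarray:
        """Boolean samples × ASVs occurrence matrix (count > 0)."""
        return self.counts > 0

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def presence_set(self, sample_id: str) -> set[str]:
        """Set of ASV ids with positive count in one sample."""
        row = self.counts[self.sample_index(sample_id)]
        return {a for a, c in zip(self.asv_ids, row) if c > 0}

    def subset_samples(self, sample_ids) -> "CommunityTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CommunityTable(list(sample_ids), list(self.asv_ids), self.counts[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)


def read_community_table(path, orientation: str = "asvs_as_rows") -> CommunityTable:
    """Read a tab-delimited count table.

    ``orientation="asvs_as_rows"`` (default, matching the on-disk
    convention) expects rows = ASVs, columns = samples; ``"samples_as_rows"``
    the transpose.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].values):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise DataError(
                    f"non-numeric cell at row {df.index[i]!r}, column {col!r}: {raw!r}"
                ) from None
    row_ids = [str(x).strip() for x in df.index]
    col_ids = [str(x).strip() for x in df.columns]
    if orientation == "asvs_as_rows":
        table = CommunityTable(col_ids, row_ids, values.T)
    elif orientation == "samples_as_rows":
        table = CommunityTable(row_ids, col_ids, values)
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    return table


def write_community_table(table: CommunityTable, path) -> None:
    """Write in the on-disk convention (rows = ASVs, header cell ``#ASV_ID``)."""
    df = pd.DataFrame(table.counts.T, index=table.asv_ids, columns=table.sample_ids)
    df.index.name = "#ASV_ID"
    df.to_csv(path, sep="\t")


def filter_table(
    table: CommunityTable, min_total_count: int = 0, min_prevalence: int = 0
) -> CommunityTable:
    """Drop ASVs below a total-count or prevalence threshold; drop emptied samples."""
    if min_total_count < 0 or min_prevalence < 0:
        raise ValueError("thresholds must be >= 0")
    totals = table.counts.sum(axis=0)
    prev = (table.counts > 0).sum(axis=0)
    keep = (totals >= min_total_count) & (prev >= min_prevalence)
    if not keep.any():
        raise DataError("filtering removed every ASV")
    counts = table.counts[:, keep]
    asv_ids = [a for a, k in zip(table.asv_ids, keep) if k]
    nonempty = counts.sum(axis=1) > 0
    if not nonempty.all():
        dropped = [s for s, k in zip(table.sample_ids, nonempty) if not k]
        logger.warning("dropping %d empty samples after filtering: %s", len(dropped), dropped)
    sample_ids = [s for s, k in zip(table.sample_ids, nonempty) if k]
    return CommunityTable(sample_ids, asv_ids, counts[nonempty])


def to_relative(table: CommunityTable) -> CommunityTable:
    """Convert each sample row to relative abundances (rows sum to 1)."""
    sums = table.counts.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise DataError(f"zero-sum sample(s): {[table.sample_ids[i] for i in zero]}")
    return CommunityTable(
        list(table.sample_ids), list(table.asv_ids), table.counts / sums[:, None]
    )


@dataclass
class SampleFrame:
    """Per-sample metadata: site, compartment, coordinates, plot replicate."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "site", "compartment", "latitude", "longitude", "plot")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataError(f"sample metadata missing columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        _check_unique(df["sample_id"], "sample")
        bad = set(df["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise DataError(f"unknown compartment level(s): {sorted(bad)}")
        lat, lon = df["latitude"].astype(float), df["longitude"].astype(float)
        if lat.isna().any() or lon.isna().any():
            raise DataError("missing coordinates")
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise DataError("coordinates out of range")
        self.frame = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def validate_against(self, table: CommunityTable) -> None:
        extra = set(self.sample_ids) - set(table.sample_ids)
        if extra:
            raise DataError(f"metadata samples absent from community table: {sorted(extra)}")

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        for col, val in conditions.items():
            mask &= self.frame[col] == val
        return list(self.frame.loc[mask, "sample_id"])

    @classmethod
    def read(cls, path) -> "SampleFrame":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class EnvFrame:
    """Environmental covariates with a variable → block assignment.

    Blocks follow the field grouping: soil properties, nutrients, climate,
    biotic, geography.
    """

    frame: pd.DataFrame  # indexed by sample_id (or site)
    blocks: dict[str, str]  # variable name -> block

    def __post_init__(self) -> None:
        for var, block in self.blocks.items():
            if block not in ENV_BLOCKS:
                raise DataError(f"unknown block {block!r} for variable {var!r}")
            if var not in self.frame.columns:
                raise DataError(f"block assignment names unknown variable {var!r}")

    def variables(self, block: str | None = None) -> list[str]:
        if block is None:
            return list(self.blocks)
        return [v for v, b in self.blocks.items() if b == block]

    def matrix(self, block: str | None = None, samples=None) -> pd.DataFrame:
        cols = self.variables(block)
        df = self.frame[cols]
        if samples is not None:
            df = df.loc[list(samples)]
        return df.astype(float)

    def impute_missing(self, site_of: pd.Series | None = None, max_missing_frac: float = 0.3) -> "EnvFrame":
        """Mean-impute missing values (within site when a site map is given)."""
        df = self.frame.copy()
        for var in self.blocks:
            col = df[var].astype(float)
            frac = col.isna().mean()
            if frac == 0:
                continue
            if frac > max_missing_frac:
                raise DataError(f"variable {var!r} has {frac:.0%} missing values (>30%)")
            if site_of is not None:
                col = col.groupby(site_of.reindex(col.index)).transform(
                    lambda s: s.fillna(s.mean())
                )
            col = col.fillna(col.mean())
            logger.warning("imputed %d missing values in %r", int(df[var].isna().sum()), var)
            df[var] = col
        return EnvFrame(df, dict(self.blocks))

    @classmethod
    def read(cls, table_path, blocks_path) -> "EnvFrame":
        """Read variables from TSV and block assignment from a key=value file."""
        df = pd.read_csv(table_path, sep="\t", index_col=0)
        blocks: dict[str, str] = {}
        with open(blocks_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("["):
                    continue
                var, _, block = line.partition("=")
                blocks[var.strip().strip('"')] = block.strip().strip('"')
        return cls(df, blocks)

    def write(self, table_path, blocks_path) -> None:
        self.frame.to_csv(table_path, sep="\t")
        with open(blocks_path, "w") as fh:
            fh.write("[blocks]\n")
            for var, block in self.blocks.items():
                fh.write(f"{var} = {block}\n")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance/dissimilarity with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(x) for x in self.ids]
        _check_unique(self.ids, "distance-matrix")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise DataError("distances must be non-negative")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def align(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.values)

    def write(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def geographic_distance(samples: SampleFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances between samples, in km."""
    lat = np.radians(samples.frame["latitude"].astype(float).values)
    lon = np.radians(samples.frame["longitude"].astype(float).values)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return DistanceMatrix(samples.sample_ids, d)
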