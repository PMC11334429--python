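"""Species exchange/extinction/immigration ratios along transmission pathways.

For an ordered pair of communities (source A → recipient B) the turnover
quantities are

* ``Simm`` — taxa gained by the recipient (present in B, absent in A),
* ``Sext`` — taxa lost from the source (present in A, absent in B),
* ``Stot`` — taxa in the union of both communities,

and the ratios

* species exchange ratio   ``SERr = (Simm + Sext) / Stot``,
* species immigration ratio ``SImR = Simm / Stot``,
* species extinction ratio  ``SExR = Sext / Stot``.

This is the self-consistent ecological convention (gained = immigration,
lost = extinction).  ``convention="literal"`` swaps the SImR/SExR labels
for audit against sources that map them the other way around.

The module also classifies shared taxa into the internal/external
pathway groups (I: NS∩RS, II: NS∩RS∩RE, III: all four compartments,
IV: NS∩LE) and produces UpSet-style exclusive intersection counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CHAIN, COMPARTMENTS, CommunityTable, SampleFrame

logger = logging.getLogger("manglift")


@dataclass
class TurnoverRecord:
    source_sample: str
    recipient_sample: str
    transition: str
    Simm: int
    Sext: int
    Stot: int
    SERr: float
    SExR: float
    SImR: float


def turnover(
    source: set, recipient: set, *,
    source_sample: str = "A", recipient_sample: str = "B",
    transition: str = "", convention: str = "ecological",
) -> TurnoverRecord:
    """Turnover quantities and ratios for one ordered pair of presence sets."""
    stot = len(source | recipient)
    if stot == 0:
        raise ValueError("both presence sets are empty")
    simm = len(recipient - source)
    sext = len(source - recipient)
    simr, sexr = simm / stot, sext / stot
    if convention == "literal":
        simr, sexr = sexr, simr
    elif convention != "ecological":
        raise ValueError(f"unknown ratio convention: {convention!r}")
    return TurnoverRecord(
        source_sample=source_sample,
        recipient_sample=recipient_sample,
        transition=transition or f"{source_sample}->{recipient_sample}",
        Simm=simm,
        Sext=sext,
        Stot=stot,
        # summing the two rounded ratios keeps SImR + SExR == SERr exact in floats
        SERr=simr + sexr,
        SExR=sexr,
        SImR=simr,
    )


def turnover_chain(
    table: CommunityTable,
    samples: SampleFrame,
    *,
    pairing: str = "plot",
    convention: str = "ecological",
) -> pd.DataFrame:
    """One turnover record per plot (or pooled site) per chain transition.

    ``pairing="plot"`` matches compartments within each (site, plot);
    ``pairing="site"`` pools each compartment's taxa over plots (union)
    before comparing, one record per site per transition.
    """
    samples.validate_against(table)
    records: list[TurnoverRecord] = []
    meta = samples.frame
    if pairing == "plot":
        units = meta.groupby(["site", "plot"], sort=True)
    elif pairing == "site":
        units = meta.groupby(["site"], sort=True)
    else:
        raise ValueError(f"unknown pairing: {pairing!r}")

    for key, sub in units:
        sets: dict[str, set] = {}
        for comp in COMPARTMENTS:
            ids = list(sub.loc[sub["compartment"] == comp, "sample_id"])
            if not ids:
                continue
            acc: set = set()
            for sid in ids:
                acc |= table.presence_set(sid)
            sets[comp] = acc
        for a, b in CHAIN:
            if a not in sets or b not in sets:
                logger.warning("unit %s lacks compartment pair %s->%s; skipped", key, a, b)
                continue
            if not (sets[a] | sets[b]):
                logger.warning("unit %s has empty %s∪%s; skipped", key, a, b)
                continue
            unit = key if isinstance(key, str) else "_".join(map(str, key))
            records.append(
                turnover(
                    sets[a], sets[b],
                    source_sample=f"{unit}_{a}", recipient_sample=f"{unit}_{b}",
                    transition=f"{a}_{b}", convention=convention,
                )
            )
    if not records:
        raise ValueError("no matched compartment pairs found")
    return pd.DataFrame([vars(rec) for rec in records])


@dataclass
class PathwayGroups:
    """Shared-taxon groups along the internal and external pathways."""

    group_I: set  # NS ∩ RS
    group_II: set  # NS ∩ RS ∩ RE
    group_III: set  # NS ∩ RS ∩ RE ∩ LE
    group_IV: set  # NS ∩ LE
    group_IV_external_only: set  # (NS ∩ LE) \ (RS ∪ RE)
    scope: str


def _compartment_sets(table: CommunityTable, sub: pd.DataFrame) -> dict[str, set]:
    sets: dict[str, set] = {}
    for comp in COMPARTMENTS:
        ids = list(sub.loc[sub["compartment"] == comp, "sample_id"])
        if ids:
            acc: set = set()
            for sid in ids:
                acc |= table.presence_set(sid)
            sets[comp] = acc
    return sets


def pathway_groups(
    table: CommunityTable, samples: SampleFrame, *, scope: str = "global",
    site: str | None = None, plot: str | None = None,
) -> PathwayGroups:
    """Groups I–IV of shared taxa at plot, site, or global scope."""
    meta = samples.frame
    if scope == "global":
        sub = meta
    elif scope == "site":
        sub = meta[meta["site"] == site]
    elif scope == "plot":
        sub = meta[(meta["site"] == site) & (meta["plot"] == plot)]
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    sets = _compartment_sets(table, sub)
    missing = [c for c in COMPARTMENTS if c not in sets]
    if missing:
        raise ValueError(f"missing compartment(s) in scope: {missing}")
    ns, rs, re_, le = (sets[c] for c in COMPARTMENTS)
    return PathwayGroups(
        group_I=ns & rs,
        group_II=ns & rs & re_,
        group_III=ns & rs & re_ & le,
        group_IV=ns & le,
        group_IV_external_only=(ns & le) - (rs | re_),
        scope=scope,
    )


def intersection_counts(table: CommunityTable, samples: SampleFrame, *, site: str | None = None) -> pd.DataFrame:
    """Exclusive intersection-region sizes over compartments (UpSet-style).

    Each taxon is assigned to exactly one membership pattern; region sizes
    therefore sum to the number of distinct taxa in the union.
    """
    meta = samples.frame
    if site is not None:
        meta = meta[meta["site"] == site]
    sets = _compartment_sets(table, meta)
    comps = [c for c in COMPARTMENTS if c in sets]
    if len(comps) < 2:
        raise ValueError("need at least two compartments")
    rows = []
    for k in range(1, len(comps) + 1):
        for combo in itertools.combinations(comps, k):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in comps if c not in combo)) if k < len(comps) else set()
            rows.append(
                {
                    "compartments": "&".join(combo),
                    "degree": k,
                    "exclusive_size": len(inside - outside),
                    "intersection_size": len(inside),
                }
            )
    return pd.DataFrame(rows)


def mean_intersection_counts(table: CommunityTable, samples: SampleFrame) -> pd.DataFrame:
    """Per-site intersection counts aggregated as mean ± sd across sites."""
    per_site = []
    for site in sorted(samples.frame["site"].unique()):
        df = intersection_counts(table, samples, site=site)
        df["site"] = site
        per_site.append(df)
    allc = pd.concat(per_site, ignore_index=True)
    agg = (
        allc.groupby(["compartments", "degree"])["exclusive_size"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_exclusive_size", "std": "sd_exclusive_size"})
    )
    return agg.sort_values(["degree", "compartments"]).reset_index(drop=True)
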