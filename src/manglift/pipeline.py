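"""End-to-end pipeline: simulate → diversity → pools → immigration →
assembly → association → VPA → PLS-PM, driven by one config.

Every stage derives its RNG seed from the global seed and the stage name
(stable CRC32 hash), so inserting or removing a stage does not shift the
randomness of the others.  A manifest records the package version,
config hash, seed and per-stage wall times; all stochastic outputs are
bit-identical across reruns of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import beta_nti, partition_processes, raup_crick_bray
from .association import correlation_screen, distance_decay, mantel, racd
from .core_data import (
    COMPARTMENTS,
    CommunityTable,
    DistanceMatrix,
    EnvFrame,
    SampleFrame,
    geographic_distance,
    read_community_table,
    write_community_table,
)
from .diversity import alpha_diversity, anosim, beta_dispersion, bray_curtis, nmds
from .immigration import mean_intersection_counts, pathway_groups, turnover_chain
from .plspm import PathModel, fit_plspm
from .species_pool import pool_by_group
from .synthetic import SimConfig, simulate
from .vpa import hellinger, variation_partition

logger = logging.getLogger("manglift")

ENV_INDICATORS = {
    "soil_properties": ["ORP", "pH", "temperature", "salinity", "clay"],
    "nutrients": ["TC", "TOC", "TN", "NO3_N", "NH4_N"],
    "climate": ["MAT", "MAP", "MAR"],
    "biotic": ["plant_height", "basal_diameter", "biomass"],
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulate": {},
        "diversity": {"n_permutations": 999},
        "assembly": {"n_null": 199, "max_asvs": 150},
        "association": {"n_permutations": 999},
        "plspm": {"bootstrap_n": 100},
    }


def _simulate_stage(config: dict, outdir: Path):
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs.setdefault("seed", stage_seed(config.get("seed", 0), "simulate"))
    if "retention" in sim_kwargs:
        sim_kwargs["retention"] = dict(sim_kwargs["retention"])
    if "gain" in sim_kwargs:
        sim_kwargs["gain"] = dict(sim_kwargs["gain"])
    if "pool_sizes" in sim_kwargs:
        sim_kwargs["pool_sizes"] = dict(sim_kwargs["pool_sizes"])
    for tuple_key in ("site_names", "latitudes", "longitudes"):
        if tuple_key in sim_kwargs:
            sim_kwargs[tuple_key] = tuple(sim_kwargs[tuple_key])
    sim_config = SimConfig(**sim_kwargs)
    table, samples, env, tree, truth = simulate(sim_config)
    write_community_table(table, outdir / "community.tsv")
    samples.write(outdir / "samples.tsv")
    env.write(outdir / "env.tsv", outdir / "env_blocks.toml")
    tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    truth.pathway_labels.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
    truth.expected.to_csv(outdir / "truth_expected.tsv", sep="\t")
    return table, samples, env, tree, truth


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage and write outputs plus a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "wall_time_s": round(time.perf_counter() - self_.t0, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    with timed("simulate"):
        table, samples, env, tree, truth = _simulate_stage(config, outdir)

    with timed("diversity"):
        div_cfg = config.get("diversity", {})
        alpha = alpha_diversity(table)
        pd.Series(alpha, name="shannon").rename_axis("sample_id").to_csv(
            outdir / "alpha.tsv", sep="\t"
        )
        bc = bray_curtis(table)
        bc.write(outdir / "bray_curtis.tsv")
        ord_res = nmds(bc, seed=stage_seed(seed, "nmds"))
        coords = pd.DataFrame(
            ord_res.coordinates, index=ord_res.sample_ids,
            columns=[f"NMDS{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        coords["stress"] = ord_res.stress
        coords.rename_axis("sample_id").to_csv(outdir / "nmds.tsv", sep="\t")
        groups = [samples.frame.loc[s, "compartment"] for s in table.sample_ids]
        an = anosim(
            bc, groups, n_permutations=int(div_cfg.get("n_permutations", 999)),
            seed=stage_seed(seed, "anosim"),
        )
        _json_dump(
            {"R": an.R, "p_value": an.p_value, "n_permutations": an.n_permutations},
            outdir / "anosim.json",
        )
        _json_dump(beta_dispersion(bc, groups), outdir / "dispersion.json")

    with timed("species_pool"):
        pools = pool_by_group(table, samples, by="site_compartment")
        pools.to_csv(outdir / "pools.tsv", sep="\t")
        pool_by_group(table, samples, by="compartment").to_csv(
            outdir / "pools_by_compartment.tsv", sep="\t"
        )

    with timed("immigration"):
        records = turnover_chain(table, samples, pairing="plot")
        records.to_csv(outdir / "turnover.tsv", sep="\t", index=False)
        grp = pathway_groups(table, samples, scope="global")
        pd.DataFrame(
            [
                {"group": "I", "n_asvs": len(grp.group_I)},
                {"group": "II", "n_asvs": len(grp.group_II)},
                {"group": "III", "n_asvs": len(grp.group_III)},
                {"group": "IV", "n_asvs": len(grp.group_IV)},
                {"group": "IV_external_only", "n_asvs": len(grp.group_IV_external_only)},
            ]
        ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
        mean_intersection_counts(table, samples).to_csv(
            outdir / "upset.tsv", sep="\t", index=False
        )

    with timed("assembly"):
        asm_cfg = config.get("assembly", {})
        max_asvs = int(asm_cfg.get("max_asvs", 150))
        n_null = int(asm_cfg.get("n_null", 199))
        top = np.argsort(table.counts.sum(axis=0))[::-1][:max_asvs]
        top = np.sort(top)
        sub = CommunityTable(
            list(table.sample_ids), [table.asv_ids[i] for i in top], table.counts[:, top]
        )
        nonzero = [s for s, row in zip(sub.sample_ids, sub.counts) if row.sum() > 0]
        sub = sub.subset_samples(nonzero)
        bnti = beta_nti(sub, tree, n_null=n_null, seed=stage_seed(seed, "bnti"))
        bnti.to_csv(outdir / "bnti.tsv", sep="\t")
        rc = raup_crick_bray(sub, n_null=n_null, seed=stage_seed(seed, "rcbray"))
        rc.to_csv(outdir / "rcbray.tsv", sep="\t")
        part = partition_processes(bnti, rc)
        part.pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
        _json_dump(part.fractions.to_dict(), outdir / "assembly_fractions.json")

    with timed("association"):
        asc_cfg = config.get("association", {})
        n_perm = int(asc_cfg.get("n_permutations", 999))
        geo = geographic_distance(samples)
        ns_ids = samples.samples_where(compartment="NS")
        bc_ns = bray_curtis(table.subset_samples(ns_ids))
        geo_ns = geo.align(ns_ids)
        env_ns = env.matrix(samples=ns_ids)
        env_std = (env_ns - env_ns.mean()) / env_ns.std().replace(0, 1)
        from scipy.spatial.distance import pdist, squareform

        env_d = DistanceMatrix(ns_ids, squareform(pdist(env_std.values)))
        mres = {
            "bray_vs_geography": vars(
                mantel(bc_ns, geo_ns, n_permutations=n_perm, seed=stage_seed(seed, "mantel_geo"))
            ),
            "bray_vs_environment": vars(
                mantel(bc_ns, env_d, n_permutations=n_perm, seed=stage_seed(seed, "mantel_env"))
            ),
        }
        _json_dump(mres, outdir / "mantel.json")

        records = turnover_chain(table, samples, pairing="plot")
        merged = _ratio_env_frame(records, samples, env, alpha_source="source")
        screen = correlation_screen(
            merged[["SERr", "SExR", "SImR"]],
            merged[[c for cols in ENV_INDICATORS.values() for c in cols]],
        )
        screen.to_csv(outdir / "screen.tsv", sep="\t", index=False)

        decay = distance_decay(bc_ns.condensed(), geo_ns.condensed())
        _json_dump(vars(decay), outdir / "decay.json")

        racd_rows = []
        for comp in COMPARTMENTS:
            ids = samples.samples_where(compartment=comp)
            res = racd(table, ids, group_name=comp)
            racd_rows.append(vars(res))
        pd.DataFrame(racd_rows).to_csv(outdir / "racd.tsv", sep="\t", index=False)

    with timed("vpa"):
        resp = hellinger(table)
        blocks = {
            name: env.matrix(samples=table.sample_ids)[cols].values
            for name, cols in ENV_INDICATORS.items()
        }
        vres = variation_partition(resp, blocks)
        vres.to_frame().to_csv(outdir / "vpa.tsv", sep="\t", index=False)
        _json_dump(
            {
                "total_explained": vres.total_explained,
                "residual": vres.residual,
                "unique": {b: vres.unique(b) for b in vres.block_names},
            },
            outdir / "vpa.json",
        )

    with timed("plspm"):
        pls_cfg = config.get("plspm", {})
        records = turnover_chain(table, samples, pairing="plot")
        pools = pool_by_group(table, samples, by="site_compartment")
        results = {}
        effects_frames = []
        for trans in ("NS_RS", "RS_RE", "RE_LE"):
            data = _plspm_frame(records, trans, samples, env, table, pools)
            model = default_path_model(
                bootstrap_n=int(pls_cfg.get("bootstrap_n", 100)),
                seed=stage_seed(seed, f"plspm_{trans}"),
            )
            res = fit_plspm(data, model)
            results[trans] = {
                "gof": res.gof,
                "r_squared": res.r_squared.to_dict(),
                "paths_to_SImR": res.path_coefficients.loc["SImR"].to_dict(),
            }
            eff = res.effects.copy()
            eff["transition"] = trans
            effects_frames.append(eff)
            res.path_coefficients.to_csv(outdir / f"plspm_paths_{trans}.tsv", sep="\t")
        pd.concat(effects_frames, ignore_index=True).to_csv(
            outdir / "plspm_effects.tsv", sep="\t", index=False
        )
        _json_dump(results, outdir / "plspm.json")

    _json_dump(manifest, outdir / "manifest.json")
    return manifest


def _ratio_env_frame(records: pd.DataFrame, samples: SampleFrame, env: EnvFrame, alpha_source: str = "source") -> pd.DataFrame:
    """Join turnover records with the source sample's environment row."""
    key = "source_sample" if alpha_source == "source" else "recipient_sample"
    env_rows = env.frame.loc[records[key].values].reset_index(drop=True)
    return pd.concat([records.reset_index(drop=True), env_rows], axis=1)


def _plspm_frame(
    records: pd.DataFrame, transition: str, samples: SampleFrame,
    env: EnvFrame, table, pools: pd.DataFrame,
) -> pd.DataFrame:
    """Per-plot indicator table for one transition's path model."""
    from .diversity import bray_curtis as _bc, shannon as _sh

    sub = records[records["transition"] == transition].reset_index(drop=True)
    rows = []
    source_comp = transition.split("_")[0]
    for _, rec in sub.iterrows():
        src, dst = rec["source_sample"], rec["recipient_sample"]
        row = dict(env.frame.loc[src])
        row["alpha"] = _sh(table.counts[table.sample_index(src)])
        pair = table.subset_samples([src, dst])
        row["beta"] = float(_bc(pair).values[0, 1])
        site = samples.frame.loc[src, "site"]
        row["pool"] = float(pools.loc[f"{site}_{source_comp}", "chao"])
        row["SImR"] = rec["SImR"]
        rows.append(row)
    return pd.DataFrame(rows)


def default_path_model(bootstrap_n: int = 100, seed: int = 0) -> PathModel:
    """Reference inner model: four environment blocks → diversity latents → SImR.

    Each exogenous block also keeps a direct path to SImR.
    """
    env_latents = list(ENV_INDICATORS)
    latents = env_latents + ["alpha_diversity", "beta_diversity", "species_pool", "SImR"]
    paths = []
    for src in env_latents:
        for dst in ("alpha_diversity", "beta_diversity", "species_pool", "SImR"):
            paths.append((src, dst))
    for src in ("alpha_diversity", "beta_diversity", "species_pool"):
        paths.append((src, "SImR"))
    blocks = dict(ENV_INDICATORS)
    blocks.update(
        {
            "alpha_diversity": ["alpha"],
            "beta_diversity": ["beta"],
            "species_pool": ["pool"],
            "SImR": ["SImR"],
        }
    )
    return PathModel(
        latent_names=latents, paths=paths, blocks=blocks,
        bootstrap_n=bootstrap_n, seed=seed,
    )
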