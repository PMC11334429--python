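"""Synthetic multi-site, multi-compartment communities with known ground truth.

The generator emulates a soil→plant transmission design: at each site a
regional species pool feeds four nested compartment pools
(nonrhizosphere soil NS ⊇ rhizosphere soil RS ⊇ root endosphere RE ⊇
leaves LE).  A compartment pool is the set of taxa able to occupy that
habitat: persistence along the chain is habitat-filtered.  Within each
replicate plot an NS community is drawn from the site pool, and each
downstream compartment community is derived from its predecessor by
per-transition retention (persistence of predecessor members that belong
to the recipient's pool) and gain (immigration of other recipient-pool
members from the site pool).  Leaves additionally
receive soil-restricted taxa — NS-plot members absent from that plot's
RS and RE communities — through a direct external deposition channel,
modelling aerosol/splash transfer of non-root-colonising soil taxa.

Because every mechanism is Bernoulli and independent across taxa, the
expected immigration/extinction/exchange ratios of every transition have
a closed form (:func:`expected_ratios`), and every leaf occurrence
carries a pathway label (internal / resident / external), so downstream
statistics can be validated against known truth.

Counts are multinomial at the configured sequencing depth, but every
community member receives at least one read: the generator models
membership, not detection loss, so occupancy truth is exactly
recoverable from the count table.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_data import CHAIN, COMPARTMENTS, CommunityTable, EnvFrame, SampleFrame

TRANSITIONS = ("NS_RS", "RS_RE", "RE_LE")

#: default site layout: six mangrove stands along the southern-China coast
DEFAULT_SITES = ("LD", "DZ", "SK", "ZZ", "HD", "FG")
DEFAULT_LATITUDES = (18.44, 19.95, 21.57, 21.62, 22.83, 24.39)
DEFAULT_LONGITUDES = (108.95, 110.58, 109.61, 108.24, 114.88, 117.92)

#: environment variables generated per block: (name, block, slope per degree latitude, intercept)
ENV_SPEC = (
    ("ORP", "soil_properties", -8.0, 150.0),
    ("pH", "soil_properties", 0.08, 5.5),
    ("temperature", "soil_properties", -0.6, 42.0),
    ("salinity", "soil_properties", 0.4, 5.0),
    ("clay", "soil_properties", 1.0, 10.0),
    ("TC", "nutrients", 0.5, 5.0),
    ("TOC", "nutrients", 0.4, 3.0),
    ("TN", "nutrients", 0.05, 0.5),
    ("TP", "nutrients", 0.02, 0.3),
    ("NO3_N", "nutrients", 0.3, 2.0),
    ("NH4_N", "nutrients", 0.2, 1.5),
    ("MAT", "climate", -0.45, 33.0),
    ("MAP", "climate", -60.0, 3000.0),
    ("MAR", "climate", 0.5, 60.0),
    ("plant_height", "biotic", -0.15, 8.0),
    ("basal_diameter", "biotic", -0.3, 14.0),
    ("biomass", "biotic", -2.0, 90.0),
)


@dataclass
class SimConfig:
    """Generator parameters; defaults define the reference study conditions."""

    n_sites: int = 6
    site_names: tuple = DEFAULT_SITES
    latitudes: tuple = DEFAULT_LATITUDES
    longitudes: tuple = DEFAULT_LONGITUDES
    n_plots_per_site: int = 5
    universe_size: int = 2000
    pool_sizes: dict = field(
        default_factory=lambda: {"NS": 400, "RS": 240, "RE": 140, "LE": 80}
    )
    #: probability an NS-site-pool taxon occurs in a given NS plot community
    occupancy: float = 0.8
    retention: dict = field(
        default_factory=lambda: {"NS_RS": 0.30, "RS_RE": 0.60, "RE_LE": 0.90}
    )
    gain: dict = field(
        default_factory=lambda: {"NS_RS": 0.30, "RS_RE": 0.30, "RE_LE": 0.35}
    )
    external_rate: float = 0.05
    abundance_shape: float = 1.5  # lognormal sigma of global taxon weights
    abundance_noise: float = 0.5  # per-sample lognormal noise around the global weight
    #: site pools sample taxa ∝ exp(pool_concentration · log-weight): common
    #: taxa recur across sites, giving realistic cross-site community overlap
    pool_concentration: float = 0.6
    #: sd of fixed per-taxon × compartment abundance offsets (habitat preference)
    compartment_preference: float = 1.2
    selection_strength: float = 0.0
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_sites
        if not (len(self.site_names) >= n and len(self.latitudes) >= n and len(self.longitudes) >= n):
            raise ValueError("need a name/latitude/longitude per site")
        self.site_names = tuple(self.site_names)[:n]
        self.latitudes = tuple(self.latitudes)[:n]
        self.longitudes = tuple(self.longitudes)[:n]
        sizes = [self.pool_sizes[c] for c in COMPARTMENTS]
        if any(s <= 0 for s in sizes) or any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("pool sizes must be positive and weakly decreasing NS≥RS≥RE≥LE")
        if self.pool_sizes["NS"] > self.universe_size:
            raise ValueError("NS pool size exceeds the ASV universe")
        for d in (self.retention, self.gain):
            for t in TRANSITIONS:
                if not 0.0 <= d[t] <= 1.0:
                    raise ValueError(f"probability out of [0,1] for transition {t}")
        if not 0.0 <= self.occupancy <= 1.0 or not 0.0 <= self.external_rate <= 1.0:
            raise ValueError("occupancy and external_rate must be in [0,1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated data set."""

    config: SimConfig
    #: expected per-transition (SImR, SExR, SERr), identical across sites
    expected: pd.DataFrame
    #: one row per leaf occurrence: site, plot, asv, label ∈ {internal, resident, external}
    pathway_labels: pd.DataFrame
    tree: dendropy.Tree
    env: EnvFrame

    def labels_for(self, site: str, plot: str) -> dict[str, str]:
        df = self.pathway_labels
        sub = df[(df["site"] == site) & (df["plot"] == plot)]
        return dict(zip(sub["asv"], sub["label"]))


# ---------------------------------------------------------------------------
# closed-form expectations
# ---------------------------------------------------------------------------

def _state_distribution(config: SimConfig):
    """Exact joint occupancy distribution over (NS, RS, RE, LE) membership.

    Taxa fall into four classes by deepest nested pool membership
    (LE-pool ⊆ RE ⊆ RS ⊆ NS); within a class the 16 possible membership
    patterns of one plot's four communities have exact probabilities given
    by the chain mechanism.  Returns ``(class_sizes, probs)`` with
    ``probs[c][state]`` for state a 4-bit tuple.
    """
    r = [config.retention[t] for t in TRANSITIONS]
    g = [config.gain[t] for t in TRANSITIONS]
    occ, ext = config.occupancy, config.external_rate
    sizes = [config.pool_sizes[c] for c in COMPARTMENTS]
    class_sizes = {  # deepest pool the class belongs to
        "LE": sizes[3],
        "RE": sizes[2] - sizes[3],
        "RS": sizes[1] - sizes[2],
        "NS": sizes[0] - sizes[1],
    }
    in_pool = {
        "LE": (1, 1, 1, 1),
        "RE": (1, 1, 1, 0),
        "RS": (1, 1, 0, 0),
        "NS": (1, 0, 0, 0),
    }
    probs: dict[str, dict[tuple, float]] = {}
    for cls, pools in in_pool.items():
        dist: dict[tuple, float] = {}
        for ns in (0, 1):
            p_ns = occ if ns else 1 - occ
            for rs in (0, 1):
                p1 = r[0] * pools[1] if ns else g[0] * pools[1]
                p_rs = p1 if rs else 1 - p1
                for re_ in (0, 1):
                    p2 = r[1] * pools[2] if rs else g[1] * pools[2]
                    p_re = p2 if re_ else 1 - p2
                    for le in (0, 1):
                        p3 = r[2] * pools[3] if re_ else g[2] * pools[3]
                        # external channel: NS members absent from RS and RE
                        if ns and not rs and not re_:
                            p3 = p3 + (1 - p3) * ext
                        p_le = p3 if le else 1 - p3
                        dist[(ns, rs, re_, le)] = p_ns * p_rs * p_re * p_le
        probs[cls] = dist
    return class_sizes, probs


def _expected_ratio_of_sums(p_num: np.ndarray, p_union: np.ndarray, sizes: np.ndarray) -> float:
    """Exact E[X/Y | Y ≥ 1] for X, Y sums of per-taxon independent Bernoullis.

    Per taxon class c there are ``sizes[c]`` taxa with numerator-event
    probability ``p_num[c]`` and union-membership probability
    ``p_union[c]`` (numerator event implies membership).  Using
    ``1/Y = ∫₀¹ t^{Y−1} dt`` and independence across taxa,

        E[X/Y; Y≥1] = ∫₀¹ G(t) Σ_c n_c p_num_c / (1 − p_u_c + p_u_c t) dt

    with ``G(t) = Π_c (1 − p_u_c + p_u_c t)^{n_c}``, then divide by
    P(Y ≥ 1) = 1 − G(0).
    """
    from scipy.integrate import quad

    p_num = np.asarray(p_num, float)
    p_union = np.asarray(p_union, float)
    sizes = np.asarray(sizes, float)
    if p_num.sum() == 0:
        return 0.0

    def integrand(t: float) -> float:
        factors = 1 - p_union + p_union * t
        g = np.prod(factors**sizes)
        return g * float(np.sum(sizes * p_num / factors))

    val, _ = quad(integrand, 0.0, 1.0, limit=200)
    p_nonempty = 1 - float(np.prod((1 - p_union) ** sizes))
    return val / p_nonempty if p_nonempty > 0 else 0.0


def expected_ratios(config: SimConfig) -> pd.DataFrame:
    """Closed-form expected (SImR, SExR, SERr) per transition.

    Valid for the neutral generator (``selection_strength == 0``); the
    selection tilt makes occupancy taxon-specific and breaks the class
    exchangeability the closed form relies on.

    Each ratio is the expectation of a ratio of sums of independent
    per-taxon Bernoulli indicators, conditioned on a non-empty union
    (pairs with an empty union are skipped downstream); it is evaluated
    exactly via the integral identity in ``_expected_ratio_of_sums``.
    """
    if config.selection_strength != 0:
        raise ValueError("closed-form expectations require selection_strength == 0")
    class_sizes, probs = _state_distribution(config)
    rows = []
    for k, trans in enumerate(TRANSITIONS):
        a_bit, b_bit = k, k + 1
        classes = list(probs)
        sizes = np.array([class_sizes[c] for c in classes], float)
        p01 = np.array([
            sum(p for s, p in probs[c].items() if not s[a_bit] and s[b_bit]) for c in classes
        ])
        p10 = np.array([
            sum(p for s, p in probs[c].items() if s[a_bit] and not s[b_bit]) for c in classes
        ])
        p11 = np.array([
            sum(p for s, p in probs[c].items() if s[a_bit] and s[b_bit]) for c in classes
        ])
        pu = p01 + p10 + p11
        mu_i, mu_e, mu_t = (sizes * p01).sum(), (sizes * p10).sum(), (sizes * pu).sum()
        simr = _expected_ratio_of_sums(p01, pu, sizes)
        sexr = _expected_ratio_of_sums(p10, pu, sizes)
        rows.append(
            {
                "transition": trans,
                "SImR": simr,
                "SExR": sexr,
                "SERr": simr + sexr,
                "E_Simm": mu_i,
                "E_Sext": mu_e,
                "E_Stot": mu_t,
            }
        )
    return pd.DataFrame(rows).set_index("transition")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _simulate_tree(asv_ids, seed: int) -> dendropy.Tree:
    """Random coalescent tree over all taxa (Kingman, unit population size)."""
    tns = dendropy.TaxonNamespace(list(asv_ids))
    return dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
    )


def _brownian_traits(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """Brownian-motion trait evolution along branches; standardized tip values."""
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            el = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(max(el, 1e-12)))
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    arr = np.array(list(tips.values()))
    mu, sd = arr.mean(), arr.std()
    sd = sd if sd > 0 else 1.0
    return {k: (v - mu) / sd for k, v in tips.items()}


def _tilt(p: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Tilt Bernoulli probabilities by selection weights, preserving the mean scale."""
    w = weight / weight.mean() if weight.mean() > 0 else weight
    return np.clip(p * w, 0.0, 1.0)


def _generate_env(config: SimConfig, sample_meta: pd.DataFrame, rng: np.random.Generator) -> EnvFrame:
    lat = sample_meta["latitude"].values.astype(float)
    lat_range = max(np.ptp(lat), 1.0)
    data = {}
    blocks = {}
    for name, block, slope, intercept in ENV_SPEC:
        noise_sd = 0.1 * abs(slope) * lat_range
        data[name] = intercept + slope * lat + rng.normal(0.0, noise_sd, size=lat.size)
        blocks[name] = block
    data["latitude"] = lat
    data["longitude"] = sample_meta["longitude"].values.astype(float)
    blocks["latitude"] = "geography"
    blocks["longitude"] = "geography"
    frame = pd.DataFrame(data, index=sample_meta["sample_id"].values)
    return EnvFrame(frame, blocks)


def simulate(config: SimConfig):
    """Generate a full synthetic data set.

    Returns ``(table, samples, env, tree, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    n_u = config.universe_size
    asv_ids = [f"ASV{i + 1:05d}" for i in range(n_u)]
    tree = _simulate_tree(asv_ids, seed=int(rng.integers(2**31 - 1)))
    traits = _brownian_traits(tree, rng)
    trait_vec = np.array([traits[a] for a in asv_ids])

    # site environmental optimum on the trait scale: standardized latitude
    lats = np.asarray(config.latitudes, dtype=float)
    optimum = (lats - lats.mean()) / (lats.std() if lats.std() > 0 else 1.0)

    sizes = config.pool_sizes
    r = {t: config.retention[t] for t in TRANSITIONS}
    g = {t: config.gain[t] for t in TRANSITIONS}

    sample_rows = []
    member_sets: dict[str, np.ndarray] = {}  # sample_id -> bool over universe
    label_rows = []

    # global species-abundance distribution and habitat preferences, shared
    # by every site so that communities overlap realistically across space
    base_logw = rng.normal(0.0, config.abundance_shape, size=n_u)
    comp_pref = {
        c: rng.normal(0.0, config.compartment_preference, size=n_u) for c in COMPARTMENTS
    }

    def _weighted_subset(candidates: np.ndarray, size: int) -> np.ndarray:
        logw = config.pool_concentration * base_logw[candidates]
        p = np.exp(logw - logw.max())
        p /= p.sum()
        return np.sort(rng.choice(candidates, size=size, replace=False, p=p))

    for s in range(config.n_sites):
        site = config.site_names[s]
        pool_ns = _weighted_subset(np.arange(n_u), sizes["NS"])
        pool_rs = _weighted_subset(pool_ns, sizes["RS"])
        pool_re = _weighted_subset(pool_rs, sizes["RE"])
        pool_le = _weighted_subset(pool_re, sizes["LE"])
        pools = {"NS": pool_ns, "RS": pool_rs, "RE": pool_re, "LE": pool_le}

        if config.selection_strength > 0:
            sel = np.exp(-config.selection_strength * (trait_vec - optimum[s]) ** 2)
        else:
            sel = None

        for p in range(config.n_plots_per_site):
            plot = f"P{p + 1}"
            occ = np.full(sizes["NS"], config.occupancy)
            if sel is not None:
                occ = _tilt(occ, sel[pool_ns])
            in_ns = np.zeros(n_u, dtype=bool)
            in_ns[pool_ns] = rng.random(sizes["NS"]) < occ

            comm = {"NS": in_ns}
            gained_le = np.zeros(n_u, dtype=bool)
            for (a, b), trans in zip(CHAIN, TRANSITIONS):
                prev = comm[a]
                in_pool_b = np.zeros(n_u, dtype=bool)
                in_pool_b[pools[b]] = True
                retained = prev & in_pool_b & (rng.random(n_u) < r[trans])
                gain_p = np.zeros(n_u)
                gain_p[pools[b]] = g[trans]
                if sel is not None:
                    gain_p[pools[b]] = _tilt(gain_p[pools[b]], sel[pools[b]])
                gained = (~prev) & (rng.random(n_u) < gain_p)
                comm[b] = retained | gained
                if b == "LE":
                    gained_le = gained

            # external pathway: soil-restricted NS members deposited onto leaves
            candidates = comm["NS"] & ~comm["RS"] & ~comm["RE"] & ~comm["LE"]
            external = candidates & (rng.random(n_u) < config.external_rate)
            retained_le = comm["LE"] & ~gained_le
            comm["LE"] = comm["LE"] | external

            for idx in np.flatnonzero(comm["LE"]):
                if retained_le[idx]:
                    label = "internal"
                elif gained_le[idx]:
                    label = "resident"
                else:
                    label = "external"
                label_rows.append((site, plot, asv_ids[idx], label))

            for comp in COMPARTMENTS:
                sid = f"{site}_{plot}_{comp}"
                member_sets[sid] = comm[comp]
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "site": site,
                        "compartment": comp,
                        "latitude": config.latitudes[s],
                        "longitude": config.longitudes[s],
                        "plot": plot,
                    }
                )

    meta = pd.DataFrame(sample_rows)
    # counts: global taxon weight × compartment preference × per-sample noise
    counts = np.zeros((len(meta), n_u))
    for i, (sid, comp) in enumerate(zip(meta["sample_id"], meta["compartment"])):
        members = np.flatnonzero(member_sets[sid])
        if members.size == 0:
            continue
        if config.depth < members.size:
            raise ValueError(
                f"depth {config.depth} below community richness {members.size} for {sid}"
            )
        logw = (
            base_logw[members]
            + comp_pref[comp][members]
            + rng.normal(0.0, config.abundance_noise, size=members.size)
        )
        w = np.exp(logw - logw.max())
        extra = rng.multinomial(config.depth - members.size, w / w.sum())
        counts[i, members] = 1 + extra

    used = counts.sum(axis=0) > 0
    table = CommunityTable(
        list(meta["sample_id"]), [a for a, u in zip(asv_ids, used) if u], counts[:, used]
    )
    samples = SampleFrame(meta)
    env = _generate_env(config, meta, rng)
    labels = pd.DataFrame(label_rows, columns=["site", "plot", "asv", "label"])
    if config.selection_strength == 0:
        expected = expected_ratios(config)
    else:
        expected = pd.DataFrame(
            index=pd.Index(TRANSITIONS, name="transition"),
            columns=["SImR", "SExR", "SERr", "E_Simm", "E_Sext", "E_Stot"],
            dtype=float,
        )
    truth = SimTruth(config=config, expected=expected, pathway_labels=labels, tree=tree, env=env)
    return table, samples, env, tree, truth
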