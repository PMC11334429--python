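# Methods

`manglift` analyses how microbial taxa move along the soil→plant
continuum of a multi-site study design: nonrhizosphere soil (NS),
rhizosphere soil (RS), root endosphere (RE) and leaves (LE), sampled in
replicate plots at several sites along a latitudinal gradient.  This
note documents the statistical procedures, the synthetic study design
used for validation, the numerical choices, and the limitations.

## Turnover ratios along the transmission chain

For an ordered pair of communities, source A → recipient B (presence =
count > 0):

* `Simm = |B \ A|` — taxa gained by the recipient (immigration),
* `Sext = |A \ B|` — taxa lost from the source (extinction),
* `Stot = |A ∪ B|`,
* `SImR = Simm/Stot`, `SExR = Sext/Stot`, `SERr = SImR + SExR`.

SERr is stored as the sum of the two rounded float ratios so the
identity `SImR + SExR == SERr` is bitwise exact; it differs from
`(Simm+Sext)/Stot` by at most one ulp.  Some sources label the two
component ratios the other way around; `convention="literal"` swaps the
SImR/SExR labels for audit purposes while leaving the quantities
unchanged.  Ratios are computed per plot (compartments matched within a
site × plot unit) by default; a pooled per-site mode (union over plots)
is provided because the pairing unit is a genuine design choice.

Shared-taxon pathway groups: Group I = NS∩RS, II = NS∩RS∩RE,
III = NS∩RS∩RE∩LE (the internal, through-the-plant route), and
IV = NS∩LE (the external, direct-deposition route).  Groups I–III are
plain intersections and therefore monotone by construction.  Because
Group IV also contains taxa that travelled internally, an
external-only variant `(NS∩LE) \ (RS∪RE)` is always emitted; it is the
detector evaluated against the generator's truth labels.

## The synthetic study design

The generator is the package's ground truth and mirrors the reference
design: 6 sites along a latitudinal transect (18.4–24.4°N), 5 plots per
site, 4 compartments per plot, with a global universe of 2,000 taxa
(scaled down from amplicon scale for speed; every analysis is
size-agnostic).

**Pools and membership.**  Each site draws an NS pool (400 taxa) from
the universe, then nested compartment pools RS ⊇ RE ⊇ LE
(240/140/80): a compartment pool is the set of taxa able to occupy that
habitat.  Pool sampling is weighted by taxon commonness
(`pool_concentration`, default 0.6, applied to the global log-weight),
so widespread taxa recur across sites — this is what gives realistic
cross-site community overlap and distance decay.  Plot-level dynamics
are Bernoulli and independent across taxa:

* NS plot community: each NS-pool taxon occurs with probability
  `occupancy` (0.8);
* chain transition A→B: an A-member persists into B with probability
  `retention[A_B]` *if it belongs to B's pool* (habitat filtering),
  and each other B-pool taxon immigrates with probability `gain[A_B]`;
* external channel: each NS-plot member absent from that plot's RS and
  RE communities is deposited onto LE with probability `external_rate`.
  The external channel deliberately models soil-restricted taxa: root
  colonisers that reach leaves are the internal chain's job.  This
  makes the truth labels and the external-only detector semantically
  aligned.

Every LE occurrence is labelled by its route with precedence
retained-from-RE (`internal`) > gained-from-LE-pool (`resident`) >
deposited (`external`).

Defaults `retention = (0.30, 0.60, 0.90)`, `gain = (0.30, 0.30, 0.35)`,
`external_rate = 0.05` were chosen from the closed-form expectation
table (below) so that mean SImR rises and mean SExR falls from soil to
leaves — the qualitative pattern the pipeline is meant to detect — with
soil-to-soil turnover dominated by extinction.  Habitat filtering also
produces the companion gradients: species pools and alpha diversity
decrease from NS to LE.

**Abundances.**  Each taxon has a global lognormal weight
(`abundance_shape`, σ = 1.5) plus a fixed per-compartment offset
(`compartment_preference`, σ = 1.2; habitat preference is what makes
compartment communities compositionally distinct, ANOSIM R ≈ 0.3–0.6)
and per-sample lognormal noise (σ = 0.5).  Counts are multinomial at
`depth` (10,000 reads), but every member receives at least one read
(`counts = 1 + multinomial(depth − richness)`): the generator models
membership, not detection loss, so occupancy truth is exactly
recoverable from the count table.  Consequences: tests validate the
statistics, not robustness to sequencing dropout; real data would add
detection noise that biases Simm/Sext upward.

**Phylogeny and selection.**  A Kingman-coalescent tree spans the
universe; tip traits evolve by Brownian motion.  With
`selection_strength > 0`, occupancy and gain probabilities are tilted
by `exp(−s·(trait − site optimum)²)` (site optimum = standardized
latitude), producing the phylogenetically structured communities the
assembly module is tested against.  The default is neutral (s = 0).

**Environment.**  Each variable is a linear function of latitude plus
Gaussian noise with sd equal to 10% of the slope × latitude range,
assigned to the blocks soil properties, nutrients, climate, biotic
(plus geography).

**Closed-form expectations.**  Because the membership chain is Markov
per taxon and taxa fall into four exchangeable classes (deepest nested
pool), the joint distribution of one plot's (NS, RS, RE, LE) membership
pattern is computed exactly over 16 states per class.  Each ratio is
then `E[X/Y | Y ≥ 1]` for X, Y sums of independent Bernoullis, evaluated
exactly with the identity `1/Y = ∫₀¹ t^{Y−1} dt`, which reduces to a
one-dimensional integral of a product of per-class linear factors
(`scipy.integrate.quad`).  The closed form requires the neutral
generator and raises otherwise.

## Diversity, ordination and group tests

Shannon diversity is reported in nats (switchable base).  No
rarefaction is applied; diversity operates on relative abundances, and
analyses that need counts use them directly.  Bray–Curtis uses
`scipy.spatial.distance.pdist`.  NMDS is nonmetric SMACOF
(scikit-learn) with k = 2, 20 random restarts, tolerance 1e-7, 300
iterations, reporting Kruskal stress-1.  ANOSIM is implemented
in-package — `R = (r̄_between − r̄_within)/(M/2)` on ranked
distances — with a seeded vectorised permutation test (999 permutations,
add-one convention, one-tailed); scikit-bio's ANOSIM serves as a
cross-check oracle in the tests, not as the implementation, because it
offers no RNG seed and seed-stable outputs are a pipeline contract.
"β-deviation" is implemented as distance-to-centroid dispersion in
PCoA space (betadisper-style, imaginary axes subtracting); the term is
used loosely in parts of the literature and a null-model-standardised
β-diversity would be a different statistic — this choice is documented
rather than hidden.

## Species-pool estimation

Incidence-based richness estimators over a group of N replicate
samples: Chao2 (small-sample form, with the bias-corrected branch when
there are no doubletons), first- and second-order jackknife, and
bootstrap, with the standard variance formulas (Chao 1987; Smith & van
Belle 1984).  Point estimates and standard errors reproduce vegan's
`specpool` to printed precision on a frozen fixture, with one deliberate
exception: the raw second-order jackknife can fall below observed
richness when doubletons outnumber singletons, and a pool estimate
below `S_obs` is meaningless, so jack2 is floored at `S_obs`.  The
headline "species pool" number is Chao2; all four estimators are always
emitted.  Presence means count > 0.

## Community assembly

βMNTD is the abundance-weighted mean nearest-taxon patristic distance
between samples (matches picante's `comdistnt` with
`abundance.weighted=TRUE`).  βNTI standardises the observed βMNTD
against a tip-label-shuffle null (999 draws by default, implemented as
row/column permutation of the patristic matrix); pairs with zero null
variance yield NaN and are excluded from fractions with a logged count.
βNTI is invariant to global branch-length rescaling (asserted in the
tests).  RCbray draws null communities preserving each sample's
richness and read total (taxa ∝ occupancy without replacement, reads
one-per-member plus a multinomial ∝ regional relative abundance), and
scales `P(null < obs) + ½P(null = obs)` to [−1, 1].  Pairs are
classified with the standard thresholds (|βNTI| > 2 selection; otherwise
|RC| > 0.95 dispersal; else drift).

## Driver attribution

*Mantel tests* correlate lower triangles with joint row/column
permutation of the second matrix (one-tailed, greater; seeded,
vectorised).  *Correlation screens* report Pearson r, raw two-tailed p
with significance stars, and always a Benjamini–Hochberg column; raw p
is primary since the screen mirrors a figure-style panel.
*Distance-decay* regressions are OLS on sample-pair observations; pairs
sharing a sample are not independent, so the classical p-value is
anti-conservative — reported with that caveat, not "corrected".
*RACD* builds a Spearman co-occurrence network over taxa with
prevalence ≥ 3 in the group (|ρ| ≥ 0.6, p < 0.05 ⇒ edge) and returns
`Σ w_i k_i / n_nodes` with w the mean relative abundance and k the
degree.  The exact published formula behind the name is not reproduced
in the source literature; this operationalization is the package's own
and both thresholds are exposed.

*Variation partitioning* Hellinger-transforms the community, fits each
block subset by least squares (collinear columns dropped via pivoted QR,
tolerance 1e-10), adjusts R² with the Ezekiel formula, and recovers the
Venn atoms by Möbius inversion over subset R² — so every subset's
adjusted R² is reconstructed exactly by summing the atoms it touches.
Fractions can be negative (an adjusted-R² property) and are reported as
computed.  Matches vegan's `varpart` on a frozen fixture.

*PLS path modeling* is authored in-package (reflective mode A only,
Lohmöller iteration; path weighting scheme by default, centroid and
factorial available).  Convergence uses the summed squared change of
absolute outer weights (tolerance 1e-6, 300 iterations) — the
sign-indeterminacy-safe criterion.  Latent scores are unit-variance;
each latent is oriented so its loadings are majority-positive.  Path
coefficients are OLS of each endogenous latent on its predecessors;
indirect effects are the power series Σ_{k≥2} Bᵏ of the coefficient
matrix (exact for an acyclic inner model); GoF = √(mean communality ×
mean R² over endogenous latents).  Bootstrap (500 rows-resamples by
default) applies sign correction against the original loadings and
reports normal-approximation p-values.  Note the usual PLS caveat:
composites attenuate structural paths below their data-generating
values at finite reliability — with six indicators loading 0.8,
composite reliability ≈ 0.91 and a true 0.5 path estimates near 0.46.

The default inner model (per transition, one row per plot) is: four
exogenous environment blocks → {alpha diversity, beta diversity,
species pool} → SImR, with direct environment → SImR paths retained.
Alpha diversity is the source sample's Shannon index; beta diversity is
the source–recipient Bray–Curtis; species pool is the source
compartment's per-site Chao2.  The wiring is a plain-text model object
and fully user-editable.

## Pipeline and reproducibility

`manglift run config.toml -o outdir` executes simulate → diversity →
pools → immigration → assembly → association → VPA → PLS-PM.  Every
stage derives its seed as `global_seed XOR crc32(stage_name) mod 2³¹`,
so adding a stage never shifts another stage's randomness; reruns are
byte-identical except the manifest's wall times.  The assembly stage
restricts to the most abundant taxa (`max_asvs`, default 150) and uses
199 nulls by default — βNTI cost grows with pairs × nulls × richness,
and the z-scores stabilise well before 999 nulls at these sizes; both
knobs are config keys.

Validation problem sizes: the replicate studies in the test suite use a
3-site × 3-plot design with a 400-taxon universe (pools 120/90/60/40,
depth 2,000) unless a check specifically concerns the 6-site defaults;
the parameter-recovery grid uses 2 sites × 10 plots × 17 replicates
(~1,020 plot transitions per cell); assembly contrasts use 4 sites × 2
plots with a 200-taxon universe and 60 nulls.  These sizes were chosen
so the whole suite exercises every code path at comfortable
Monte-Carlo precision.

## Known limitations

* The generator has no sequencing noise, chimeras, or compositional
  detection loss; passing tests say nothing about robustness to those.
* Membership dynamics are independent across taxa (no interactions);
  RACD is therefore validated only against its own definition, not
  against an interaction ground truth.
* Distance-decay p-values inherit pairwise non-independence (above).
* Quantities that depend on a particular real sequencing data set
  (total ASV counts, taxon compositions, exact shared-ASV counts)
  cannot be reproduced from a synthetic desk-scale study; validation
  is property- and oracle-based instead.
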