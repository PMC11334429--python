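# manglift

Species-immigration analysis of multi-compartment microbial
communities.

Plant-associated microbiomes assemble from soil: taxa pass from
nonrhizosphere soil (NS) through the rhizosphere (RS) into the root
endosphere (RE) and on to the leaves (LE), or land on leaves directly
from the environment.  `manglift` quantifies that movement for
amplicon (ASV) data from replicated multi-site designs — e.g. nitrogen
fixer (*nifH*) communities of mangrove stands along a latitudinal
gradient — and attributes it to environmental drivers.

For an ordered source→recipient pair of communities A → B it computes
the richness-based turnover ratios

    Simm = |B \ A|      Sext = |A \ B|      Stot = |A ∪ B|
    SImR = Simm/Stot    SExR = Sext/Stot    SERr = SImR + SExR

(species immigration, extinction, and exchange ratios) along the
transmission chain NS→RS→RE→LE, classifies shared ASVs into the
internal-pathway groups I–III (NS∩RS, NS∩RS∩RE, NS∩RS∩RE∩LE) and the
external group IV (NS∩LE, with an external-only variant
(NS∩LE)\(RS∪RE)), and surrounds the core with the standard community
ecology toolkit:

* alpha diversity, Bray–Curtis, NMDS, ANOSIM, β-dispersion;
* incidence-based species pools (Chao2, jackknife 1/2, bootstrap,
  matching vegan's `specpool`);
* null-model assembly partitioning (βMNTD/βNTI, Raup–Crick on
  Bray–Curtis, Stegen-style process classification);
* Mantel tests, Pearson screens, distance-decay regressions, and an
  abundance-weighted co-occurrence degree (RACD);
* variation partitioning over predictor blocks (partial RDA, adjusted
  R², matching vegan's `varpart`);
* from-scratch PLS path modeling (reflective blocks, path scheme,
  direct/indirect/total effects, goodness of fit, bootstrap errors).

A fully ground-truthed synthetic study generator (6 sites × 4
compartments × 5 plots, nested habitat pools, known per-pathway
retention/gain probabilities, latitude-linked environment, coalescent
phylogeny with optional trait selection) ships as first-class code, so
every statistic can be validated against closed-form expectations and
truth labels.  See `docs/methods.md` for the model details.

## Worked example

```python
from manglift import SimConfig, simulate, turnover_chain, expected_ratios

cfg = SimConfig(seed=1)                      # the reference study design
table, samples, env, tree, truth = simulate(cfg)

rec = turnover_chain(table, samples)         # one record per plot per transition
print(rec.groupby("transition")[["SImR", "SExR", "SERr"]].mean().round(3))
print(expected_ratios(cfg)[["SImR", "SExR", "SERr"]].round(3))
```

```
             SImR   SExR   SERr
transition
NS_RS       0.045  0.780  0.825
RS_RE       0.292  0.457  0.749
RE_LE       0.325  0.335  0.660

NS_RS       0.043  0.785  0.828
RS_RE       0.290  0.461  0.751
RE_LE       0.342  0.319  0.661
```

The realized per-plot means (top) reproduce the generator's closed-form
expectations (bottom): the immigration ratio rises from soil to leaves
while the extinction ratio falls — the signature of increasingly
selective but increasingly immigration-fed habitats along the
soil→plant chain.  Per-site Chao2 species pools show the companion
gradient (NS ≈ 400, RS ≈ 241, RE ≈ 139 for the same seed), and the
external-only Group IV variant recovers the truth-labelled
directly-deposited leaf taxa with recall and precision 1.0 when chain
gains are switched off.

The same analyses run from the shell:

```
manglift simulate -o data/ --seed 1
manglift immigration ratios --table data/community.tsv --metadata data/samples.tsv -o ratios.tsv
manglift pool --table data/community.tsv --metadata data/samples.tsv --by compartment -o pools.tsv
manglift run config.toml -o results/        # full pipeline from one TOML config
```

`manglift run` executes simulate → diversity → pools → immigration →
assembly → association → VPA → PLS-PM, writes TSV/JSON outputs plus a
manifest (package version, config hash, seed, stage wall times), and is
bit-reproducible: the same config and seed give byte-identical outputs.

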