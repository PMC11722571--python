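# cooccur

Co-occurrence analysis of **lianas** (woody climbers) and **vascular
epiphytes** on host trees in subtropical montane forest censuses.

Both guilds depend on trees for structural support, yet they are almost
always studied separately. Given a census of trees (≥ 10 cm dbh) in
plots nested within forest patches, with per-tree liana records (stem
diameter ≥ 1 cm, climbing mechanism, tree zone) and epiphyte records
(Braun-Blanquet cover class 1–5, zones occupied), this package asks at
which ecological scales the two guilds co-occur and what drives it:

1. **Occurrence scales** — liana × epiphyte presence per tree size
   class (2×2 tables, Yates-corrected χ², union-denominator shared-host
   percentages), per-plot trunk/crown occurrence counts, and per-patch
   host summaries.
2. **Count contrasts** — negative-binomial (NB2, log link) GLM group
   contrasts: liana vs epiphyte host counts per patch, trunk vs crown
   occurrences, and epiphyte co-occurrence with specialized-climbing vs
   leaning liana species. In a two-group NB2 design the contrast
   coefficient is exactly `log(mean_alt / mean_ref)`, which makes the
   published estimates reproducible from the printed host totals alone.
3. **Host models** — four Bayesian mixed-effects models of what a tree
   carries as a function of forest type (successional vs mature) and
   dbh, with a tree-species random intercept: hurdle-Poisson for liana
   and epiphyte species richness, hurdle-lognormal for liana basal
   area, cumulative-logit for epiphyte cover class.
4. **Interaction networks** — weighted bipartite matrices: liana × tree
   (summed basal area), epiphyte × tree (zone occupancies), epiphyte ×
   liana (shared host trees).
5. **Spatial association** — for a mapped block of contiguous plots,
   ring-differenced Ripley K (`K(r) − K(r − 2 m)`, translation edge
   correction) of guild-marked trees, with Monte Carlo envelopes from
   covariate-adjusted random labeling: marks are reshuffled with
   probabilities from a logistic fit of presence on dbh and species,
   preserving the observed number of hosts.

A synthetic stand generator (`cooccur.synthetic`) emulates the survey
design — 12 patches (8 successional, 4 mature) × ten 20 × 20 m plots,
~2100 trees, ~34% liana hosts, ~52% epiphyte hosts, and one 0.36-ha
mapped block of ~120 trees — so every stage is testable without the
deposited field data.

## Worked example

```python
from cooccur import StandParams, generate_stand
from cooccur.scales import class_cooccurrence_table

ds = generate_stand(StandParams(), seed=1)
tt = ds.tree_table()
print(len(tt), tt.liana_host.mean(), tt.epi_host.mean())
print(class_cooccurrence_table(ds).round(3))
```

prints (seed 1): 2057 trees, 33.6% liana hosts, 52.7% epiphyte hosts,
and the size-class table

```
class_label  n_trees  n_liana_hosts  n_epi_hosts  n_shared  shared_pct  chi2     p
     <13.15      407             69          136        30      17.143 3.257 0.071
13.15-19.75      761            204          320        93      21.578 1.240 0.265
19.75-33.76      675            270          439       178      33.522 0.098 0.754
    >=33.76      214            149          189       129      61.722 0.939 0.333
```

— the shared-host percentage climbs steeply with tree size (17% of the
smallest trees vs 62% of trees above 33.76 cm dbh) even though the
within-class presence association stays non-significant, the same
pattern the field survey reports.

The numbered scripts under `analysis/` run the full story on a
simulated census (`01_simulate_stand.py` writes `results/data/`, then
`02`–`06` cover scales, contrasts, host models, networks and the
spatial test). The same stages are available as a CLI:

```sh
cooccur simulate --out data --seed 1
cooccur validate data
cooccur scales data --classes 13.15,19.75,33.76
cooccur glm data --analysis mechanism
cooccur run --config run.yaml
```

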