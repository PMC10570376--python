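# phylonat

Community-phylogenetics tooling for a long-standing question in invasion
biology: are naturalized alien plants closer or more distant relatives of
the native flora than chance would predict — and how does the answer
change with latitude, climate and human modification of the landscape?

Two classical hypotheses pull in opposite directions.  Under
*preadaptation*, aliens closely related to natives naturalize more easily
because they share the traits that survive the local environmental
filter; under *Darwin's naturalization hypothesis*, close relatives are
disfavoured through competition and shared enemies.  `phylonat`
implements the regional-flora analysis that arbitrates between them:

* **Cross-group MPD.** For a region with alien tip set $A$ and native
  tip set $B$ on a dated phylogeny,

  $$\mathrm{MPD}(A,B) = \frac{1}{|A||B|} \sum_{a \in A}\sum_{b \in B} d(a,b),$$

  with $d$ the patristic distance.  Computed by edge contribution
  ($O(n)$ per evaluation), exactly equal to the brute-force
  patristic-matrix mean.  MNTD (mean nearest-native distance) is
  provided as a utility.
* **Source-pool null models.**  Holding the natives and the alien
  *count* fixed, alien identities are redrawn from one of six candidate
  pools (global non-native flora; economic-use ∪ naturalized flora;
  global naturalized; continent naturalized; climatically suitable;
  climatically suitable ∩ continent naturalized).  Summaries:
  $\Delta\mathrm{MPD} = \mathrm{MPD}_{obs} - \overline{\mathrm{MPD}}_{null}$,
  $\mathrm{SES} = \Delta\mathrm{MPD}/\mathrm{sd}(\mathrm{MPD}_{null})$,
  and weight $= 1/\mathrm{var}(\mathrm{MPD}_{null})$.  Positive
  ΔMPD supports Darwin's naturalization hypothesis, negative supports
  preadaptation.
* **Phylogeny curation.**  Missing species are grafted at the crown of
  their genus (else family) with ultrametricity preserved; a
  genus/family-level "less-resolved" tree is available for sensitivity.
* **Climate layer.**  PCA over the 19 bioclim variables (normalizing
  transforms, centered/scaled) yielding PC_Temp and PC_Prec region
  scores; per-species Mahalanobis climate envelopes over six bioclim
  variables with a seeded 80/20 split, held-out AUC > 0.7 retention and
  max-sensitivity+specificity thresholding feed the climate pools.
* **Regression layer.**  (Weighted) linear models of MPD/ΔMPD on
  latitude and the latitude × human-modification interaction;
  variance-weighted linear mixed models on PC_Temp × HM + PC_Prec × HM
  with a continent random intercept; and a species-level binomial GLMM
  with complementary log-log link,
  `naturalized ~ MPD × |latitude| + (1 + MPD × |latitude| | species) + (1 | region)`,
  fitted through R `lme4` (with an automatic intercepts-only refit and a
  documented plain-GLM fallback).
* **Synthetic worlds.**  A generator with known ground truth — Yule tree
  with monophyletic taxonomy, Brownian thermal optima, latitude-driven
  climate grids, poleward-tightening environmental filtering and a
  cloglog naturalization process with a negative MPD × latitude
  interaction — so the entire pipeline runs and is validated without any
  external data.

## Worked example

```python
import phylonat as pn

world = pn.generate_world(pn.WorldParams(
    n_species=150, n_genera=30, n_families=10, n_regions=40,
    cells_per_region=6, richness_per_region=40, seed=1,
))
rows = []
for region in world.regions:
    rows += pn.run_region_pools(
        world.tree, region, [pn.PoolType.GLOBAL_NAT], world.registry,
        continent_regions=world.continent_regions, n_reps=500, seed=2,
    )
df = pn.results_to_frame(rows)
lat = {r.region_id: abs(r.latitude) for r in world.regions}
fit = pn.fit_weighted_linear(
    df["delta_mpd"], {"lat": [lat[i] for i in df["region_id"]]},
    weights=df["weight"],
)
print(fit.coef.loc["lat"])
```

prints (see `examples/05_regression_layer.py`)

```
ΔMPD ~ |latitude|: slope -0.0222 (t = -4.76, p = 2.8e-05)
```

— the planted pattern: alien floras are relatively *closer* to the
native flora toward the poles (preadaptation strengthens with
latitude), here recovered from the null-model summaries by the weighted
regression.  The species-level cloglog model on the same world gives a
negative MPD × |latitude| interaction (z = −4.0): the effect of being a
close relative flips from neutral-or-negative near the equator to
positive at high latitude.

The `examples/` directory walks through each capability (distances and
grafting, world generation, the six null models, the climate layer, the
regression layer, the end-to-end pipeline), and the `phylonat` CLI
exposes the pipeline (`simulate`, `null`, `pca`, `suitability`, `fit`,
`run-all`) for shell use.

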