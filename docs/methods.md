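# Methods

## The quantity of interest

For each region we measure the cross-group mean pairwise phylogenetic
distance between its naturalized alien species $A$ and its native
species $B$ on a rooted, branch-length (time-calibrated) phylogeny:

$$\mathrm{MPD}(A,B)=\frac{1}{|A||B|}\sum_{a\in A}\sum_{b\in B} d(a,b),$$

where $d$ is the patristic distance.  MPD is dominated by deep branches
and is therefore robust to poor resolution near the tips, which is why
it — rather than the nearest-taxon statistic MNTD, supplied only as a
utility — carries the analysis.  MPD is computed by edge contribution:
an edge of length $L$ separating $c_a$ aliens and $c_b$ natives from the
rest contributes $L\,[c_a(|B|-c_b)+c_b(|A|-c_a)]$ cross pairs, giving an
$O(n)$ algorithm that is exactly the patristic-matrix mean (verified
against an independent dendropy-based oracle to $10^{-9}$).

Because MPD is linear in the alien set, a single $O(n)$ pass computing
$S(x)=\sum_{b\in B} d(x,b)$ for every tip makes each null replicate an
$O(|A|)$ subset mean.  This is what keeps thousands of randomizations
per region cheap.

## Tree curation

Species absent from the phylogeny are grafted as pendant tips at the
most recent common ancestor of their congeners, or of their family when
the genus is absent entirely.  The pendant length equals the attachment
node's height (distance down to the tip level), so an ultrametric tree
stays ultrametric; this choice is ours — only the attachment point, not
the branch length, is dictated by the procedure being emulated.  A genus
represented by a single tip has no crown; we split that tip's pendant
edge at half its length (configurable) and attach the newcomer there.
Polytomies are first-class and no resolution step is applied.  A
sensitivity tree with uniform within-genus (or within-family) resolution
is produced by `collapse_to_rank`, which re-hangs every species at its
rank's crown node.

## Null models and summaries

Per region and source pool, alien identities are redrawn uniformly
without replacement — a species list cannot contain duplicates — keeping
the native assemblage and the alien count fixed.  Summaries:
ΔMPD = observed − null mean; SES = ΔMPD / null SD (sample SD, $n-1$; a
zero-SD null leaves SES and the weight undefined, reported as NaN);
weight = inverse null variance, used in the weighted regressions.  The
engine is calibrated: when observed aliens are themselves a uniform pool
draw, SES has mean ≈ 0, variance ≈ 1, and ~5% of |SES| values exceed
1.96.

Six candidate pools are supported, nested as
continent ⊆ global-naturalized ⊆ econ-use ∪ naturalized ⊆ global
non-native, and climate ∩ continent ⊆ climate ⊆ global-naturalized.
Pools exclude the focal region's natives but deliberately retain its
actual aliens so the observed configuration is one of the draws the null
can produce.  A pool smaller than the region's observed alien count is
an error at the module level; the pipeline logs such region × pool pairs
and skips them (climatically strict pools in climatically extreme
regions are genuinely small).

Reproducibility contract: one master seed; each (region, pool) pair
draws from a substream obtained by hashing (seed, region id, pool name)
with SHA-256 into a `numpy` `SeedSequence`, so results are independent
of processing order.

## Climate layer

All 19 bioclim variables are transformed (default: per-variable fitted
Yeo–Johnson power transforms; log1p/sqrt/identity variants are
available and recorded for reuse), centered, scaled and fed to a PCA at
grid-cell level (a region-mean-level fit is available for sensitivity).
Axis signs are fixed so warm regions score high on axis 1 (positive
loading of mean annual temperature) and humid regions high on axis 2
(positive loading of annual precipitation); region scores are unweighted
cell means.

Climatic suitability per species is scored with a Mahalanobis climate
envelope over six bioclim variables (mean diurnal range, temperature
seasonality, max temperature of the warmest month, precipitation
seasonality, precipitation of the wettest and driest quarters):
suitability = exp(−½·D²) to the training-presence mean and covariance
(ridge-regularized when singular, epsilon recorded).  Species need more
than 15 presence cells; 80% of presences train, the held-out 20% are
scored against the non-presence background for the test AUC (rank-sum
formulation, ties counted ½); models with AUC > 0.7 are retained and
thresholded at maximum training sensitivity + specificity (ties toward
the larger threshold).  A region is suitable when at least one of its
cells reaches the threshold.  The envelope is this package's scorer by
design — the interface also accepts an externally computed
species × region suitability table, so scores from a full
maximum-entropy SDM can be plugged in unchanged.

## Regression layer

Region-level: MPD and each pool's ΔMPD are regressed on absolute
centroid latitude (signed latitude by configuration), with the inverse
null variance as weights for ΔMPD; the human-modification interaction
model is `response ~ latitude * HM`; the climate model is
`response ~ PC_Temp*HM + PC_Prec*HM + (1 | continent)` with the same
weights.  statsmodels `MixedLM` carries the mixed model; residual
weights enter exactly by premultiplying response and design by √w and
passing √w as the random-intercept design column.  Weights are
normalized to unit mean (inference is scale-invariant).  A single
continent, or non-convergence, degenerates to the weighted linear fit
with a flag.  Standardized effect sizes come from refitting on
unit-variance predictors.  All mixed-model tests are Wald tests.

Species-level: one row per (species, region) pair with the species not
native there, carrying that species' own cross-group MPD to the region's
natives.  The model is a binomial GLMM with complementary log-log link
(suited to the rare-outcome structure):
`naturalized ~ z(MPD) × z(|lat|) + (1 + z(MPD) × z(|lat|) | species) + (1 | region)`,
fitted with R `lme4::glmer` (Laplace, bobyqa) through an Rscript bridge;
predictors are standardized internally and coefficient names map back to
the raw predictors.  A non-converging or singular full structure is
automatically refit with random intercepts only; if R is unavailable the
model degrades to a plain cloglog GLM, which is flagged in the fit notes
and also serves as the independent cross-check in the test suite (with
zero random-effect variance the two agree within 2 SE).

Partial-prediction curves hold co-predictors at sample quantiles (HM at
10/50/90%) or at fixed values (latitude for the species-level model) and
use the fixed-effects prediction.  Completeness sensitivity refits the
latitude model on regions with completeness > 50% and, separately, with
completeness as weights.

## The synthetic world

The generator is a pure function of (parameters, seed) and emulates the
data structure the analysis assumes; its defaults are the package's
study conditions.

* **Tree** — crown-start pure-birth (Yule) process, birth rate 1 per
  unit time, conditioned on 400 tips (default).  Genera (60) and
  families (20) are the clades crossing two horizontal cuts, hence
  monophyletic; cut depths are chosen so exactly the target number of
  lineages crosses.  A fixed-duration mode exposes the raw process for
  moment checks (E[N(t)] = 2e^{bt} from the crown).
* **Niche traits** — Brownian motion along branches, rate σ² = 1 per
  unit time, root at 0: close relatives share thermal optima (niche
  conservatism).
* **Regions and climate** — 60 regions, latitudes uniform on ±60°,
  areas log-normal (median ≈ 13 000 km², so the 5 000 km² filter
  bites), HM ~ Beta(1.5, 3), four "continents" assigned in index
  blocks.  Ten cells per region carry the 19 bioclim variables:
  temperature variables decline with |latitude| (bio1 = 28 − 0.45·|lat|
  plus noise), seasonality rises, and the precipitation block follows a
  latitude-independent humidity factor with log-normal amounts (their
  skew exercises the power transforms).  Noise SD 1.5 puts the
  region-temperature/|latitude| correlation near −0.97.
* **Native assembly** — species s joins region r with weight
  exp(−(opt_s − μ_r)²/2σ_r²), where μ_r maps the region's mean
  temperature onto the trait scale and
  σ_r = 2.0 · exp(−0.025·|lat_r|): moderate climatic structuring of
  ranges in the tropics, tight filtering near the poles (native
  assemblages cluster phylogenetically poleward).  A fixed 80 natives
  per region are drawn without replacement under these weights.
* **Naturalization** — for every non-native (species, region) pair, a
  cloglog draw with linear predictor
  β₀ + β_mpd·z(MPD) + β_lat·z(|lat|) + β_int·z(MPD)·z(|lat|)
  − (opt_s − μ_r)²/(2·2.0²) + u_species + v_region, defaults
  β₀ = −2.2, β_mpd = 0.15, β_lat = 0, β_int = −0.35, random-effect SDs
  0.3.  The latitude-independent alien climate filter (tolerance 2.0,
  wider than the native filter) makes naturalized species climatically
  plausible where they establish — without it the climate-restricted
  source pools cannot cover the alien counts of extreme regions.  A
  region left with zero aliens (possible in the climatically most
  extreme regions) is redrawn, i.e. conditioned on being invaded.

How the planted latitudinal signal arises: native-side filtering alone
cancels out of ΔMPD, because observed and null alien draws face the same
native assemblage.  The gradient is carried by (i) the negative
MPD × latitude interaction — at high latitude, distant relatives
naturalize less — and (ii) the flat alien climate filter interacting
with poleward native clustering: climate-matched aliens sit closer than
random pool draws to natives precisely where natives are tightly
clustered around the regional climate.  Consistent with this,
experiments sweeping the generator show the fitted ΔMPD–latitude slope
responds monotonically to β_int (≈ +0.001, −0.006, −0.016 at β_int = 0,
−0.35, −0.7) but *not* to the native-filter latitude coefficient; the
planted-signal test therefore sweeps β_int.

What the generator does not emulate: geography and dispersal (continents
are labels, not places), introduction effort and residence time,
taxonomic error, the right-skewed richness distributions of real floras,
and realistic bioclim covariance beyond the two planted factors.
Passing recovery tests therefore demonstrates that the pipeline detects
these mechanisms when present and stays calibrated when absent — not
that the mechanisms explain any particular real flora.

## Replication settings and numerical choices

* Replicated experiments (signal recovery, type-I calibration) use
  worlds of 250 species / 50 regions / 8 cells per region / richness 60
  — large enough that ΔMPD sampling is near-normal (at 150 species the
  finite-pool, sub-Gaussian shape of subset means makes the weighted
  t-test measurably conservative, ~3% at α = 0.05; at 250/50 it is
  5.7% in a 300-replicate audit), small enough for hundreds of
  replicates.  Signal recovery uses 100 worlds at default effect sizes
  with 200 null replicates and the intercepts-only GLMM structure;
  type-I calibration uses 400 null-effect worlds (flat filtering,
  β_mpd = β_lat = β_int = 0, alien filter and random effects off) with
  100 null replicates.
* Null draws use `argpartition` over uniform keys — an exact uniform
  without-replacement sample per replicate.
* SES undefined (NaN) rather than ±∞ at zero null SD; sample SD uses
  the n−1 denominator.
* Envelope covariance ridge: smallest epsilon from
  {0, 1e−8, 1e−6, 1e−4, 1e−2}·(mean diagonal) that yields a finite
  inverse.
* max-SSS candidates are the unique observed scores; the prediction
  rule is score ≥ threshold ⇒ present; ties break toward the largest
  threshold.
* The 80/20 split rounds the test share to the nearest integer, at
  least 1.
* Rank-deficient linear designs raise an error naming the aliased
  terms (pivoted QR).
* Pipeline determinism: identical config + seed reproduce result CSVs
  byte-for-byte; the manifest (which carries timings) is excluded from
  that guarantee.

## Known limitations

* The climate envelope is a deliberately simple presence-only scorer;
  it has no feature classes or regularization path.  External SDM
  scores can be substituted through the suitability-table interface.
* Small-world SES/ΔMPD distributions are mildly sub-Gaussian; weighted
  t-tests are then conservative.  This is a finite-pool effect that
  shrinks with flora size.
* Crossed random slopes in the species-level GLMM depend on R lme4
  being present; the pure-Python fallback drops random effects
  entirely (flagged).
* Spatial autocorrelation is not modelled anywhere; continents enter
  only as random intercepts.
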