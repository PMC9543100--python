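# Methods

`fishestab` asks how the phylogenetic and functional similarity between an
introduced ("exotic") freshwater fish and the native fish community of the
receiving lake jointly predict whether the introduction establishes.  The
two classic, opposing expectations are Darwin's naturalization hypothesis
(distant relatives establish more easily because they escape competition
and shared enemies) and the pre-adaptation hypothesis (close relatives
establish more easily because they share environmental adaptations).
Working with both successful and failed introductions lets the effect of
similarity be estimated directly instead of being inferred from the
survivors.

## Data model

An analysis consumes:

* **Introduction records** — one row per introduction event: lake,
  species, binary establishment outcome (1 = established), optional year.
  `(lake, species, year)` triples are unique after de-duplication.
* **Lake attributes** — area, elevation, latitude, longitude, optional
  depth and water-temperature fields.
* **Native presence matrix** — lake x species 0/1 (uncertain codes
  allowed on input).
* **Phylogeny** — rooted Newick with branch lengths, tips covering every
  species in records and communities.
* **Trait table** — ten continuous morphological traits per species
  (maximum body length, body elongation, eye position and size, oral gape
  position, maxillary length, body shape, pectoral-fin position and size,
  caudal-peduncle throttling), FISHMORPH-style.

### Exclusion rules

Five cleaning rules run before any analysis, each removal logged with its
rule number: (1) lakes with zero native richness are dropped (similarity
is undefined there); (2) hybrid introductions are dropped — hybrids are
detected by an explicit configured taxon list *plus* name markers ("×"),
because real files vary in how crosses are encoded; (3) records with a
blank species name are dropped; (4) native taxa resolved only to family
rank (configured list) are removed from communities; (5) uncertain
presence codes (default 0.5, configurable) are conservatively coerced to
absence before richness is computed.  Coercion (5) and family-rank
removal (4) run first so the richness screen (1) sees correct richness.
Filtering is idempotent and never fails.

### Water-temperature imputation

Accumulated and maximum water temperature are imputed in two ordinary
least squares stages: air temperature ~ latitude + elevation on the lakes
where it is observed, then water temperature ~ depth + area + predicted
air temperature; only missing values are filled.  When no air-temperature
column exists the two stages collapse algebraically into a single
regression of water temperature on depth, area, latitude, and elevation,
which yields identical predictions.  Lake area and depth enter on the raw
scale by default (a log-area switch exists); nothing in the data dictates
a transform, so the simplest choice is the default.

## Distances and metrics

* **Phylogenetic distance** is the cophenetic (patristic) distance: the
  sum of branch lengths on the tip-to-tip path.  An optional outgroup is
  pruned before computation.
* **Functional distance** is Euclidean distance over the first five
  principal components of the z-scored trait table.  PCA is run on the
  correlation matrix by default (traits are on incommensurate scales);
  covariance-matrix PCA is available.  Component signs follow a
  deterministic convention (largest-magnitude loading positive).
* The **functional dendrogram** is agglomerative clustering of the
  functional distances (complete linkage by default; average and Ward
  available), with species sorted lexicographically first so tied merges
  are deterministic.
* **Phylogenetic signal** is a Mantel test between the two distance
  matrices: Pearson r on the upper triangles, upper-tail permutation p
  with rows/columns of the second matrix permuted jointly,
  p = (1 + #{r_perm >= r_obs}) / (B + 1), seeded, B = 9999 by default.
  For n <= 8 species an exact mode enumerates all n! permutations.

Per lake, native diversity is summarized by the mean pairwise distance
(MPD phylogenetic, MFD functional) and the mean nearest-neighbor distance
(MNTD, MNFD).  Per introduction event, exotic-native similarity is the
mean (I-N MPD, I-N MFD) and the minimum (I-N MNTD, I-N MNFD) distance
from the introduced species to the lake's natives; larger values mean
less similar.  If a data error codes the exotic as native in its own
target lake it is removed from its native set and the event flagged.
Lakes with fewer than two natives cannot support the pairwise diversity
metrics; such events are dropped from modeling with a log entry.
Covariates are z-scored over the modeled event set (after drops).

## Hierarchical establishment model

For event *i* (species *s(i)* into lake *l(i)*):

    y_i ~ Bernoulli(p_i),
    logit p_i = beta_0 + x_i' beta + u_l(i) + v_s(i) + w_s(i),
    u ~ N(0, sigma_L^2 I),  v ~ N(0, sigma_S^2 I),  w ~ N(0, sigma_P^2 Sigma)

with eight standardized fixed effects (I-N MPD, I-N MFD, native MPD,
native MFD, richness, area, elevation, latitude — or the nearest-metric
family) and Sigma the Brownian-motion phylogenetic covariance of the
introduced species: the shared root-to-MRCA branch length, computed on
the full tree, sub-set to the introduced species, and scaled to unit
maximum diagonal.  Priors: N(0, 10^2) on fixed effects, Gamma(0.01, 0.01)
on the three precisions.

**Inference** is a nested Laplace approximation: for fixed variance
hyperparameters the latent field (fixed effects plus all random-effect
blocks) is maximized by Newton's method and integrated by a Laplace
approximation at the mode; the three hyperparameters are optimized
(Nelder-Mead) on the resulting marginal posterior; posterior draws are
taken from the Gaussian approximation at the modal hyperparameters.
This mirrors the deterministic-approximation family of methods normally
used for this model class rather than MCMC, and keeps a full fit around
one second so replication studies are cheap.  Two costs are accepted and
documented: hyperparameter uncertainty is not propagated into the
intervals, and the joint latent mode attenuates logistic coefficients
slightly (measured at roughly 5-8% at the default study scale —
well inside a 95% CI half-width).  70% and 95% intervals are equal-tailed
quantile intervals from the draws; convergence is reported via the outer
optimizer status and the gradient norm at the mode.

WAIC is computed from the pointwise posterior log-likelihood draws,
WAIC = -2(lppd - p_waic) with p_waic the summed posterior variance of the
pointwise log-likelihood; it compares the mean-metric and nearest-metric
model families.  Relative importance of predictor *j* is
|beta_j| / sum_k |beta_k| x 100 over the eight predictors (the absolute
value is required for the shares to be well defined; the alternative
reading |sum beta| would let opposite signs cancel).  Shares are also
aggregated into similarity / diversity / geography groups.  Prediction
curves hold the other predictors at their means (0 on the z scale) and
set random effects to zero (a typical lake and species).

## GLMM model averaging

The frequentist check fits logistic mixed models with the same fixed
effects and lake + species random intercepts (no phylogenetic term) by
maximum Laplace-approximate likelihood.  The engine profiles the fixed
effects jointly with the random-effect modes in the inner penalized
Newton solve and optimizes only the variance parameters in the outer
loop.  This is the fast profiling variant of the standard Laplace GLMM;
against lme4's default (which estimates the fixed effects in the outer
optimization) it agrees to well within a standard error on test problems
while being fast enough for an exhaustive 2^8-subset sweep.  All 256
fixed-effect subsets are ranked by AICc = -2logLik + 2k + 2k(k+1)/(n-k-1)
with k = |subset| + 1 + 2 variance parameters (whether variance
parameters belong in k is a genuine ambiguity; including them is the
conservative choice and is constant across models, so rankings are
unaffected).  Models within 2 AICc of the best are averaged with Akaike
weights using the full-average (zero-substitution) convention and
Burnham-Anderson unconditional standard errors.  The random-effect
structure is never subset.

## Piecewise SEM

The path model is a DAG over the measured variables with establishment as
the terminal node.  Each endogenous variable gets a component regression
in its own family — linear mixed for continuous variables, logistic mixed
for establishment — with lake and species random intercepts (plain OLS
when no grouping is requested).  The default initial DAG routes geography
(latitude, elevation, area) through native richness into native
diversity, diversity into exotic-native similarity, and similarity into
establishment, with one direct area -> establishment path; a temperature
variant swaps the geographic drivers for accumulated and maximum water
temperature.  The DAG is config-overridable via an edge list.

Model fit uses Shipley's d-separation test with the union basis set: one
claim per non-adjacent ordered pair (X, Y), Y later in a deterministic
lexicographic topological order, conditioning on parents(X) u parents(Y).
Each claim is tested by adding X to the regression of Y on the
conditioning set (family per Y) and taking the two-sided Wald p of X.
Fisher's C = -2 sum ln p is chi-square with 2k degrees of freedom under a
correct model; candidate models compare on the d-sep AIC = C + 2K, where
K counts all estimated parameters (coefficients plus variance
components) across component models.

Model selection adds, stepwise, the edge for the most significant
*violated* claim, requiring claim p below a Bonferroni-corrected alpha
(0.05 / #claims) and an AIC decrease.  The significance gate matters: an
AIC-only rule accepts any edge whose claim p < exp(-1) ~ 0.37, which adds
spurious edges to roughly half of faithful datasets; with the gate the
false-addition rate is near the nominal 5% familywise level while strong
true edges (claim p ~ 1e-6 or smaller) are recovered essentially always.

Standardized path coefficients are beta x sd(x)/sd(y) for linear
components; for the logistic component sd(y) is replaced by the
latent-scale response SD sqrt(var(Xb) + sigma_L^2 + sigma_S^2 + pi^2/3)
(the latent-theoretic method; pi^2/3 is the logistic residual variance).
Conditional R^2 follows Nakagawa: (fixed + random) / (fixed + random +
residual) variance, with residual pi^2/3 on the latent scale for the
binary component.  Effects on establishment decompose into direct (the
edge coefficient), indirect (sum over directed paths of length >= 2 of
edge-coefficient products), and total = direct + indirect; relative
totals are |total| shares summing to 100%.  By default only significant
paths (p < 0.05) enter the displayed decomposition, configurable, since
decomposing over all paths changes the totals.

## Synthetic data generator

The generator defines the study conditions for all end-to-end checks:

* **Tree** — Yule pure-birth tree, 38 species, birth rate 1 (dendropy's
  simulator, which starts from a bifurcated root, so the expected root
  depth is (H_{n-1} - 1)/b).
* **Traits** — 10 traits, each sqrt(lambda) x Brownian motion +
  sqrt(1-lambda) x independent noise scaled to the Brownian tip variance;
  lambda = 0.6 by default, enough for a clearly significant Mantel signal
  while keeping the phylogenetic-functional distance correlation well
  below 1 (r^2 < 0.9), as observed in real fish data.
* **Lakes** — 100 lakes; latitude U(55.3, 68.5) degrees, elevation
  U(0, 800) m, log-normal area (median ~20 ha) and depth; air
  temperatures linear in latitude/elevation plus noise, water
  temperatures linear in depth, area and air temperature, observed for a
  30% subset so the imputation path is exercised.
* **Communities** — expected log richness declines with z-scored latitude
  (slope -0.35) and elevation (-0.25) around a median of 6; Poisson
  richness clipped to [2, 27]; natives sampled around a focal species
  with weights decaying in phylogenetic distance (mild clustering).
* **Introductions** — 965 events; exotics drawn from a 23-species
  introduced pool with geometrically decaying frequencies (popular
  species are introduced repeatedly, exercising the species random
  effect); target lakes exclude lakes where the species is native;
  (lake, species, year) triples are unique.  Outcomes run the
  hierarchical model forward with beta(I-N MPD) = -0.6,
  beta(I-N MFD) = +0.5, small fixed coefficients on the remaining six
  predictors, beta_0 = 0, and sigma_L = sigma_S = sigma_P = 0.5.
  Covariates are z-scored before the coefficients are applied so the
  generating values live on the scale the models estimate.

What the generator does *not* emulate: propagule pressure, temporal
trends in introduction effort, observation error in outcomes, spatial
autocorrelation between neighboring lakes, and trait measurement error.
Passing end-to-end tests therefore demonstrates that the machinery
recovers the assumed data-generating structure at realistic size and
noise — not that real introduction data satisfy those assumptions.
Note also that the generator gives every predictor a (small) direct
effect on establishment, so the initial SEM, which routes geography and
diversity only indirectly, is deliberately slightly misspecified; the
d-sep selection stage is expected to add some direct paths.

## Numerical choices

* Variance parameters are optimized as log SDs inside [-6, 4]; the lower
  edge is the variance-to-zero boundary and is flagged.
* Phylogenetic correlation matrices get a relative jitter of 1e-8 before
  Cholesky factorization.
* Inner Newton uses step halving and runs to a 1e-9 relative gradient
  tolerance; the Gaussian family is solved in closed form (the Laplace
  approximation is exact there, and the engine matches statsmodels
  MixedLM maximum likelihood).
* Ties in dredge rankings break toward fewer parameters, then
  lexicographic subset order; species orderings are lexicographic
  throughout; all randomness flows from one root seed split per stage
  with numpy SeedSequence.
* Claim p-values are clipped at 1e-300 before Fisher's C.

## Problem sizes used by the test suite

Unit tests run on reduced problems (12-20 species, tens of lakes,
120-700 events) chosen so each check still has the power to fail;
parameter-recovery and calibration checks use 10-20 replicates at the
full default scale (965 events) or 300-500 replicates for cheap
closed-form simulations.  The pipeline's full default synthetic run
(both metric families, 256-model dredge, SEM selection) completes in
about two minutes on one CPU.

## Known limitations

* Posterior intervals condition on the modal variance hyperparameters;
  for very small species or lake counts they will be slightly narrow.
* The profiled-Laplace GLMM attenuates coefficients by a few percent
  relative to exact ML; AICc comparisons use the same approximation for
  every candidate, so rankings are internally consistent.
* With Sigma = I the phylogenetic effect is exchangeable with the species
  intercept: only the summed species-level variance is identifiable, and
  the reported split between sigma_S and sigma_P is then arbitrary.
* Correlated-error (double-headed) SEM edges are not supported; the
  d-sep basis assumes directed edges only.
* The relative-importance ratio is a descriptive partition of
  standardized coefficients, not a formal variance decomposition.
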