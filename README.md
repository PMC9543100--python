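# fishestab

Do exotic freshwater fishes establish more easily when they are
*phylogenetically close* to the native community but *functionally
distant* from it?  `fishestab` is a reusable pipeline for answering that
question from introduction records with known outcomes.  It targets
ecologists analyzing databases of intentional fish introductions into
lakes — cases where both successes and failures are documented — and
anyone who wants to test Darwin's naturalization conundrum (the tension
between Darwin's naturalization hypothesis, "distant relatives escape
competition", and the pre-adaptation hypothesis, "close relatives are
pre-adapted") with phylogenetic and functional similarity in one model.

## What it computes

From four inputs — an introduction-events table, a lake-attributes
table, a lake x species native presence matrix, a species trait table,
and a rooted Newick phylogeny — the pipeline derives, per lake and per
introduction event:

* native diversity: mean pairwise and mean nearest-neighbor distances on
  the phylogeny (MPD, MNTD) and in a 5-PC morphological trait space
  (MFD, MNFD);
* exotic-native similarity: the mean and minimum distance from the
  introduced species to the lake's natives (I-N MPD/MFD, I-N MNTD/MNFD);

and fits three complementary models of the binary establishment outcome
`y` with standardized predictors `x` (similarity, diversity, richness,
area, elevation, latitude):

1. **Phylogenetic Bayesian hierarchical model**

       logit P(y=1) = beta0 + x'beta + u_lake + v_species + w_species,
       u ~ N(0, s_L^2 I),  v ~ N(0, s_S^2 I),  w ~ N(0, s_P^2 Sigma)

   where `Sigma` is the Brownian-motion covariance of the introduced
   species (shared root-to-MRCA branch length, unit-scaled).  Fitted by
   a nested Laplace approximation; reports posterior means, 70%/95%
   credible intervals, WAIC, and a relative-importance partition
   |beta_j| / sum|beta| per predictor.
2. **All-subsets GLMM comparison** — all 2^8 fixed-effect subsets of the
   lake+species random-intercept logistic model, ranked by AICc and
   averaged (Akaike weights, full-average convention) over models with
   dAICc < 2.
3. **Piecewise SEM** — a DAG of component mixed models tested by
   Shipley's d-separation (Fisher's C = -2 sum ln p, chi-square with 2k
   df), selected by the d-sep AIC = C + 2K, with standardized paths
   (latent-theoretic pi^2/3 scale for the binary component), Nakagawa
   conditional R^2, and a direct/indirect/total effect decomposition.

A seeded synthetic-data generator (Yule tree, Brownian traits with
tunable phylogenetic signal, latitude/elevation-driven richness,
forward-simulated outcomes) makes every stage verifiable end to end
without access to any real dataset.  See `docs/methods.md` for the full
model descriptions and design choices.

## Worked example

```python
from fishestab.synth import SynthConfig, generate
from fishestab.metrics import assemble_covariates, MEAN_PREDICTORS
from fishestab.hiermodel import fit_hier, phylo_covariance, relative_importance
from fishestab.distances import mantel_test

data = generate(SynthConfig(n_species=20, n_lakes=50, n_events=300,
                            n_introduced_pool=10, seed=7))
sig = mantel_test(data.d_phy, data.d_fun.submatrix(data.d_phy.species),
                  n_perm=999, seed=7)
print(f"Mantel r = {sig.r:.3f}, p = {sig.p:.4f}")

natives = {lk: set(r.index[r >= 1]) for lk, r in data.communities.iterrows()}
cov = assemble_covariates(data.records, data.lakes, natives,
                          data.d_phy, data.d_fun).data
phylo = phylo_covariance(data.tree, sorted(cov["species_id"].unique()))
fit = fit_hier(cov, MEAN_PREDICTORS, phylo, seed=7)
print(fit.summary.loc[["in_mpd", "in_mfd"]].round(3)[["mean", "ci95_lo", "ci95_hi"]])
print(f"WAIC = {fit.waic:.1f}")
print(relative_importance(fit).round(1))
```

prints

```
Mantel r = 0.478, p = 0.0010
         mean  ci95_lo  ci95_hi
in_mpd -0.739   -1.188   -0.282
in_mfd  0.707    0.235    1.184
WAIC = 349.6
in_mpd        25.9
in_mfd        24.8
native_mpd    19.0
native_mfd    16.2
richness       0.4
area           8.8
elevation      1.8
latitude       3.3
```

Reading the output: traits carry significant phylogenetic signal
(Mantel r = 0.48, p = 0.001).  The exotic-native mean phylogenetic
distance has a clearly negative effect on establishment (posterior mean
-0.74, 95% CI excluding zero) — closer relatives establish more easily —
while the functional distance effect is positive (+0.71) — functionally
distinct exotics establish more easily.  Together the two similarity
metrics account for about half of the summed standardized effects.  This
synthetic dataset was generated with true effects -0.6 and +0.5, so both
signs and magnitudes are recovered within the credible intervals.

The same analysis runs from the shell:

```sh
fishestab synth --out inputs/ --seed 7          # write synthetic inputs
fishestab prep --records inputs/records.csv --lakes inputs/lakes.csv \
    --community inputs/communities.csv --traits inputs/traits.csv \
    --tree inputs/tree.nwk --out clean/         # validate/filter/impute
fishestab run --out run1/ --seed 7              # full pipeline
```

`run` writes distance matrices, the covariate table, per-family
hierarchical-fit JSON, the ranked GLMM table with averaged coefficients,
SEM path/effect tables, a `report.json`, and a `manifest.json` of file
hashes and stage seeds (identical seeds reproduce identical hashes).

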