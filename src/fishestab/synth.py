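"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a Scandinavian-style lake-introduction study: a
Yule phylogeny of ~40 fish species, Brownian-motion morphological traits
with tunable phylogenetic signal, lakes whose native richness declines
with latitude and elevation, mildly phylogenetically clustered native
communities, and Bernoulli establishment outcomes produced by running the
hierarchical establishment model forward — a negative coefficient on
exotic-native phylogenetic distance, a positive one on exotic-native
functional distance, plus lake, species, and phylogenetically correlated
random effects.  Covariates are z-scored before the coefficients are
applied, so the generating values live on the same scale the models
estimate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from . import metrics as _metrics
from .distances import DistanceMatrix, functional_distances, trait_pca, cophenetic_distances
from .hiermodel import phylo_covariance

__all__ = [
    "SynthConfig",
    "SynthData",
    "simulate_tree",
    "simulate_traits",
    "simulate_lakes_and_communities",
    "simulate_introductions",
    "generate",
]

DEFAULT_BETA = {
    "in_mpd": -0.6,
    "in_mfd": 0.5,
    "native_mpd": 0.15,
    "native_mfd": -0.10,
    "richness": -0.20,
    "area": -0.25,
    "elevation": -0.10,
    "latitude": -0.15,
}


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the study's scale."""

    n_species: int = 38
    n_lakes: int = 100
    n_events: int = 965
    n_introduced_pool: int = 23
    birth_rate: float = 1.0
    trait_signal: float = 0.6        # lambda in [0, 1]
    n_traits: int = 10
    richness_median: float = 6.0
    richness_max: int = 27
    richness_lat_slope: float = -0.35   # on log expected richness per SD latitude
    richness_elev_slope: float = -0.25
    clustering_scale: float = 0.5       # phylogenetic clustering of natives
    temp_observed_frac: float = 0.3
    beta0: float = 0.0
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_lake: float = 0.5
    sigma_species: float = 0.5
    sigma_phylo: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trait_signal <= 1.0):
            raise ValueError("trait_signal must be in [0, 1]")
        if min(self.sigma_lake, self.sigma_species, self.sigma_phylo) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) ultrametric tree with deterministically labeled tips."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    width = len(str(n_species))
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = dendropy.Taxon(label=f"s{i:0{width}d}")
        ns.add_taxon(taxon)
        leaf.taxon = taxon
    tree.taxon_namespace = ns
    tree.update_taxon_namespace()
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    trait_signal: float = 0.6,
    n_traits: int = 10,
    seed: int = 0,
    total_variance: float = 1.0,
) -> pd.DataFrame:
    """Brownian-motion traits blended with independent noise.

    Each trait is sqrt(lambda) * BM + sqrt(1-lambda) * iid Gaussian noise
    whose variance equals the mean Brownian tip variance, then rescaled so
    the expected tip variance is ``total_variance``.  lambda = 1 gives
    pure Brownian traits (strong phylogenetic signal); lambda = 0 gives
    signal-free traits.
    """
    species, cov = phylo_covariance(tree, scale=False)
    n = len(species)
    vbar = float(np.mean(np.diag(cov)))
    jitter = 1e-10 * max(vbar, 1.0)
    L = np.linalg.cholesky(cov + jitter * np.eye(n))
    rng = np.random.default_rng(seed)
    lam = trait_signal
    bm = L @ rng.standard_normal((n, n_traits))
    noise = np.sqrt(vbar) * rng.standard_normal((n, n_traits))
    X = np.sqrt(lam) * bm + np.sqrt(1.0 - lam) * noise
    X *= np.sqrt(total_variance / vbar)
    cols = [f"trait{j + 1:02d}" for j in range(n_traits)]
    df = pd.DataFrame(X, index=pd.Index(species, name="species_id"), columns=cols)
    return df


def simulate_lakes_and_communities(
    config: SynthConfig, tree: dendropy.Tree, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lake attributes and phylogenetically clustered native communities.

    Expected log richness decreases with (z-scored) latitude and
    elevation; realized richness is Poisson around the trend, clipped to
    [2, richness_max].  For each lake a focal native species seeds the
    community and the remaining natives are drawn with weights decaying in
    phylogenetic distance from the focal species.
    """
    rng = np.random.default_rng(seed)
    nl = config.n_lakes
    lat = rng.uniform(55.3, 68.5, nl)
    elev = rng.uniform(0.0, 800.0, nl)
    area = np.exp(rng.normal(3.0, 1.2, nl))          # hectares
    depth = np.exp(rng.normal(2.0, 0.6, nl))         # meters
    lon = rng.uniform(11.0, 24.0, nl)

    # air temperatures respond to latitude and elevation; water
    # temperatures respond to depth, area, and air temperature
    accum_air = 1500.0 - 60.0 * (lat - 55.0) - 0.8 * elev + rng.normal(0, 40.0, nl)
    max_air = 22.0 - 0.45 * (lat - 55.0) - 0.006 * elev + rng.normal(0, 0.7, nl)
    accum_water = 80.0 + 0.75 * accum_air - 6.0 * depth + 0.02 * np.log(area) + rng.normal(0, 30.0, nl)
    max_water = 1.5 + 0.85 * max_air - 0.12 * depth + 0.05 * np.log(area) + rng.normal(0, 0.5, nl)
    observed = rng.random(nl) < config.temp_observed_frac
    accum_obs = np.where(observed, accum_water, np.nan)
    max_obs = np.where(observed, max_water, np.nan)

    lat_z = (lat - lat.mean()) / lat.std()
    elev_z = (elev - elev.mean()) / elev.std()
    log_mu = (
        np.log(config.richness_median)
        + config.richness_lat_slope * lat_z
        + config.richness_elev_slope * elev_z
    )
    cop = cophenetic_distances(tree)
    species = cop.species
    D = cop.values
    rich_hi = min(config.richness_max, len(species))
    richness = np.clip(rng.poisson(np.exp(log_mu)), 2, rich_hi)
    mean_d = D[np.triu_indices(len(species), k=1)].mean()
    lake_ids = [f"L{i + 1:03d}" for i in range(nl)]
    presence = np.zeros((nl, len(species)), dtype=int)
    for i in range(nl):
        r = int(richness[i])
        focal = rng.integers(len(species))
        w = np.exp(-D[focal] / (config.clustering_scale * mean_d))
        w = np.maximum(w, 1e-9)  # keep every species reachable
        w[focal] = 0.0
        w = w / w.sum()
        others = rng.choice(len(species), size=r - 1, replace=False, p=w)
        presence[i, focal] = 1
        presence[i, others] = 1

    lakes = pd.DataFrame(
        {
            "area": area,
            "elevation": elev,
            "latitude": lat,
            "longitude": lon,
            "depth": depth,
            "accum_air_temp": accum_air,
            "max_air_temp": max_air,
            "accum_temp": accum_obs,
            "max_temp": max_obs,
        },
        index=pd.Index(lake_ids, name="lake_id"),
    )
    communities = pd.DataFrame(
        presence, index=pd.Index(lake_ids, name="lake_id"), columns=cop.species
    )
    return lakes, communities


def simulate_introductions(
    config: SynthConfig,
    lakes: pd.DataFrame,
    communities: pd.DataFrame,
    d_phy: DistanceMatrix,
    d_fun: DistanceMatrix,
    tree: dendropy.Tree,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Introduction events with outcomes from the forward hierarchical model.

    Exotic species are drawn from a fixed introduced pool with unequal
    (geometrically decaying) frequencies, mimicking repeated introductions
    of popular species; the target lake is drawn among lakes where the
    species is not native.  Covariates are computed with the metrics
    module, z-scored, and pushed through the logistic model with lake,
    species, and phylogenetically correlated random effects.
    """
    rng = np.random.default_rng(seed)
    species = list(communities.columns)
    pool = sorted(rng.choice(species, size=config.n_introduced_pool, replace=False))
    pool_w = 0.85 ** np.arange(len(pool))
    pool_w = pool_w / pool_w.sum()
    lake_ids = list(communities.index)
    native = {lk: set(communities.columns[communities.loc[lk] >= 1]) for lk in lake_ids}

    rows = []
    seen: set[tuple] = set()
    for _ in range(config.n_events):
        for _try in range(1000):
            sp = pool[rng.choice(len(pool), p=pool_w)]
            lk = lake_ids[rng.integers(len(lake_ids))]
            year = int(rng.integers(1900, 2003))
            if sp not in native[lk] and len(native[lk]) >= 2 and (lk, sp, year) not in seen:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not sample a feasible introduction event")
        seen.add((lk, sp, year))
        rows.append({"lake_id": lk, "species_id": sp, "outcome": 0, "year": year})
    records = pd.DataFrame(rows)

    table = _metrics.assemble_covariates(
        records, lakes, native, d_phy, d_fun, standardize=True
    )
    df = table.data
    assert len(df) == config.n_events

    psi = np.full(len(df), config.beta0)
    for pred, b in config.beta.items():
        psi += b * df[pred + "_z"].to_numpy()

    u = rng.normal(0.0, config.sigma_lake, len(lake_ids))
    lake_idx = df["lake_id"].map({l: i for i, l in enumerate(lake_ids)}).to_numpy()
    v = rng.normal(0.0, config.sigma_species, len(pool))
    sp_idx = df["species_id"].map({s: i for i, s in enumerate(pool)}).to_numpy()
    order, Sigma = phylo_covariance(tree, pool, scale=True)
    Lp = np.linalg.cholesky(Sigma + 1e-8 * np.eye(len(pool)))
    w = config.sigma_phylo * (Lp @ rng.standard_normal(len(pool)))
    w_idx = df["species_id"].map({s: i for i, s in enumerate(order)}).to_numpy()

    psi = psi + u[lake_idx] + v[sp_idx] + w[w_idx]
    outcome = rng.binomial(1, 1.0 / (1.0 + np.exp(-psi)))
    records = records.assign(outcome=outcome)
    truth = {
        "pool": pool,
        "linear_predictor": psi,
        "u_lake": u,
        "v_species": v,
        "w_phylo": w,
        "phylo_order": order,
    }
    return records, truth


@dataclass
class SynthData:
    config: SynthConfig
    tree: dendropy.Tree
    traits: pd.DataFrame
    lakes: pd.DataFrame
    communities: pd.DataFrame
    records: pd.DataFrame
    d_phy: DistanceMatrix
    d_fun: DistanceMatrix
    truth: dict

    def write_inputs(self, outdir) -> dict[str, str]:
        """Write the four CSV inputs + Newick tree in the io module formats."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": outdir / "records.csv",
            "lakes": outdir / "lakes.csv",
            "communities": outdir / "communities.csv",
            "traits": outdir / "traits.csv",
            "tree": outdir / "tree.nwk",
        }
        self.records.to_csv(paths["records"], index=False)
        self.lakes.to_csv(paths["lakes"], index_label="lake_id")
        self.communities.to_csv(paths["communities"], index_label="lake_id")
        self.traits.to_csv(paths["traits"], index_label="species_id")
        from .io import write_tree

        write_tree(self.tree, paths["tree"])
        return {k: str(v) for k, v in paths.items()}


def generate(config: SynthConfig | None = None) -> SynthData:
    """Run the whole generator; all randomness derives from config.seed."""
    config = config or SynthConfig()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_lakes, s_intro = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]
    tree = simulate_tree(config.n_species, config.birth_rate, s_tree)
    traits = simulate_traits(tree, config.trait_signal, config.n_traits, s_traits)
    d_phy = cophenetic_distances(tree)
    d_fun = functional_distances(trait_pca(traits))
    lakes, communities = simulate_lakes_and_communities(config, tree, s_lakes)
    records, truth = simulate_introductions(
        config, lakes, communities, d_phy, d_fun, tree, s_intro
    )
    return SynthData(
        config=config, tree=tree, traits=traits, lakes=lakes,
        communities=communities, records=records,
        d_phy=d_phy, d_fun=d_fun, truth=truth,
    )
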