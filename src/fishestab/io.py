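"""Input reading, validation, exclusion filtering, and temperature imputation.

The analysis consumes four tables and a tree:

* introduction records (lake, species, 0/1 establishment outcome, year),
* lake attributes (area, elevation, latitude, longitude, optional depth
  and temperature fields),
* a lake x species native presence matrix,
* a species x trait table of continuous morphological traits,
* a rooted Newick phylogeny with branch lengths.

Five exclusion rules clean the raw data: (1) lakes with zero native
richness are removed, (2) hybrid introductions are removed, (3) records
with a missing species name are removed, (4) native taxa resolved only to
family rank are removed from the communities, and (5) uncertain presence
codes are conservatively coerced to absence before richness is computed.
Every removal is logged with the rule that caused it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "IOConfig",
    "InputBundle",
    "FilterLog",
    "ImputationResult",
    "read_inputs",
    "read_tree",
    "apply_filters",
    "impute_water_temperature",
    "write_bundle",
]


@dataclass
class IOConfig:
    """Column mappings and filter configuration."""

    hybrid_taxa: tuple[str, ...] = ()          # explicit hybrid species ids
    hybrid_markers: tuple[str, ...] = ("×", " x ")  # name substrings also treated as hybrids
    family_rank_taxa: tuple[str, ...] = ()     # native taxa known only to family
    uncertain_presence_code: float = 0.5       # coerced to 0 (rule 5)
    log_area: bool = False                     # log-transform area on read
    drop_unmatched: bool = False               # drop records whose species miss tree/traits


@dataclass
class InputBundle:
    records: pd.DataFrame            # lake_id, species_id, outcome, [year]
    lakes: pd.DataFrame              # indexed by lake_id
    communities: pd.DataFrame        # lake_id x species presence (0/1/uncertain)
    traits: pd.DataFrame             # indexed by species_id
    tree: dendropy.Tree
    report: dict = field(default_factory=dict)

    def community_sets(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for lake_id, row in self.communities.iterrows():
            out[str(lake_id)] = {s for s, v in row.items() if v >= 1}
        return out


@dataclass
class FilterLog:
    entries: list[dict] = field(default_factory=list)
    counts: dict[int, int] = field(default_factory=dict)

    def add(self, rule: int, kind: str, **info) -> None:
        self.entries.append({"rule": rule, "kind": kind, **info})
        self.counts[rule] = self.counts.get(rule, 0) + 1

    def rules_applied(self) -> list[int]:
        return sorted(self.counts)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": self.entries,
                       "counts": {str(k): v for k, v in self.counts.items()}},
                      fh, indent=2)


def write_tree(tree: dendropy.Tree, path) -> None:
    """Write Newick preserving labels verbatim (quoting spaced labels)."""
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True, preserve_spaces=True,
    )


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    labels = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def read_inputs(
    records_path,
    lakes_path,
    community_path,
    traits_path,
    tree_path,
    config: IOConfig | None = None,
) -> InputBundle:
    """Read and cross-validate the five inputs.

    The report lists species appearing in one input but absent from
    another.  Species present in records or communities but missing from
    the tree or the trait table are fatal unless ``config.drop_unmatched``.
    """
    config = config or IOConfig()
    records = pd.read_csv(records_path, dtype={"lake_id": str, "species_id": str})
    _require_columns(records, ["lake_id", "species_id", "outcome"], "records table")
    lakes = pd.read_csv(lakes_path, dtype={"lake_id": str}).set_index("lake_id")
    _require_columns(
        lakes.reset_index(), ["lake_id", "area", "elevation", "latitude", "longitude"],
        "lakes table",
    )
    communities = pd.read_csv(community_path, dtype={"lake_id": str}).set_index("lake_id")
    traits = pd.read_csv(traits_path, dtype={"species_id": str}).set_index("species_id")
    tree = read_tree(tree_path)

    if config.log_area:
        lakes = lakes.assign(area=np.log(lakes["area"]))

    bad = records["outcome"].dropna().astype(float)
    if not bad.isin([0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")

    tips = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon}
    rec_species = set(records["species_id"].dropna())
    com_species = set(communities.columns)
    used = rec_species | com_species
    report = {
        "species_missing_from_tree": sorted(used - tips),
        "species_missing_from_traits": sorted(used - set(traits.index)),
        "tree_tips_unused": sorted(tips - used),
        "lakes_missing_from_lake_table": sorted(
            (set(records["lake_id"]) | set(communities.index)) - set(lakes.index)
        ),
    }
    fatal = (set(report["species_missing_from_tree"])
             | set(report["species_missing_from_traits"])) & rec_species
    if fatal:
        if config.drop_unmatched:
            records = records[~records["species_id"].isin(fatal)].reset_index(drop=True)
            report["records_dropped_unmatched"] = sorted(fatal)
        else:
            raise ValueError(
                f"recorded species missing from tree or traits: {sorted(fatal)}"
            )
    if report["lakes_missing_from_lake_table"]:
        raise ValueError(
            f"lakes absent from lake table: {report['lakes_missing_from_lake_table']}"
        )
    return InputBundle(records, lakes, communities, traits, tree, report)


def _is_hybrid(species_id: str, config: IOConfig) -> bool:
    if species_id in config.hybrid_taxa:
        return True
    return any(m in species_id for m in config.hybrid_markers)


def apply_filters(
    bundle: InputBundle, config: IOConfig | None = None
) -> tuple[InputBundle, FilterLog]:
    """Apply the five exclusion rules; removals only, never failures.

    Order of application: uncertain presence codes are coerced first
    (rule 5) and family-rank native taxa removed (rule 4) so that native
    richness is correct when richness-zero lakes are dropped (rule 1);
    hybrid (rule 2) and nameless (rule 3) introductions are then removed.
    Filtering is idempotent.
    """
    config = config or IOConfig()
    log = FilterLog()
    records = bundle.records.copy()
    communities = bundle.communities.copy().astype(float)

    # rule 5: uncertain presence -> absent
    code = config.uncertain_presence_code
    mask = communities.values == code
    n_uncertain = int(mask.sum())
    if n_uncertain:
        communities = communities.mask(pd.DataFrame(
            mask, index=communities.index, columns=communities.columns), 0.0)
        log.add(5, "presence_coerced", n_cells=n_uncertain)

    # rule 4: family-rank native taxa removed from communities
    for taxon in config.family_rank_taxa:
        if taxon in communities.columns:
            communities = communities.drop(columns=[taxon])
            log.add(4, "native_taxon", species_id=taxon)

    # rule 1: lakes with zero native richness (records in them dropped too)
    richness = (communities >= 1).sum(axis=1)
    empty_lakes = set(richness.index[richness == 0])
    for lake_id in sorted(empty_lakes):
        log.add(1, "lake", lake_id=lake_id)
    drop_mask = records["lake_id"].isin(empty_lakes)
    for rec in records[drop_mask].itertuples(index=False):
        log.add(1, "record", lake_id=rec.lake_id, species_id=rec.species_id)
    records = records[~drop_mask]
    communities = communities.drop(index=sorted(empty_lakes))

    # rule 2: hybrid introductions
    hybrid_mask = records["species_id"].fillna("").map(lambda s: _is_hybrid(s, config))
    for rec in records[hybrid_mask].itertuples(index=False):
        log.add(2, "record", lake_id=rec.lake_id, species_id=rec.species_id)
    records = records[~hybrid_mask]

    # rule 3: missing species name
    blank = records["species_id"].isna() | (records["species_id"].astype(str).str.strip() == "")
    for rec in records[blank].itertuples(index=False):
        log.add(3, "record", lake_id=rec.lake_id)
    records = records[~blank]

    # de-duplicate identical (lake, species, year) rows
    subset = [c for c in ("lake_id", "species_id", "year") if c in records.columns]
    records = records.drop_duplicates(subset=subset).reset_index(drop=True)

    lakes = bundle.lakes.drop(index=[l for l in empty_lakes if l in bundle.lakes.index])
    filtered = replace(bundle, records=records, lakes=lakes, communities=communities)
    return filtered, log


@dataclass
class ImputationResult:
    lakes: pd.DataFrame
    stages: dict[str, dict]  # per target variable: coefficients and R^2


def _ols(y: np.ndarray, X: pd.DataFrame, what: str):
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"{what}: only {n} observed lakes for {p} predictors")
    Xc = sm.add_constant(X, has_constant="add")
    # collinearity gate via VIF on the non-constant columns
    if p >= 2:
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        arr = Xc.to_numpy(dtype=float)
        vifs = {col: variance_inflation_factor(arr, j + 1) for j, col in enumerate(X.columns)}
        if any(not np.isfinite(v) or v > 1e6 for v in vifs.values()):
            raise ValueError(f"{what}: collinear design, VIFs {vifs}")
    res = sm.OLS(y, Xc).fit()
    return res


def impute_water_temperature(
    lakes: pd.DataFrame,
    water_cols: tuple[str, ...] = ("accum_temp", "max_temp"),
    air_cols: tuple[str | None, ...] = ("accum_air_temp", "max_air_temp"),
) -> ImputationResult:
    """Two-stage OLS imputation of missing water-temperature fields.

    Stage 1 regresses air temperature on latitude and elevation (on lakes
    where it is observed) and predicts it everywhere; stage 2 regresses
    water temperature on depth, area, and the predicted air temperature,
    and fills only the missing water values.  If the air-temperature
    column is absent, stage 1 collapses into stage 2 and water temperature
    is regressed on depth, area, latitude, and elevation directly (the
    predictions are algebraically identical).  Observed values are never
    modified.
    """
    out = lakes.copy()
    stages: dict[str, dict] = {}
    for water_col, air_col in zip(water_cols, air_cols):
        if water_col not in out.columns or out[water_col].notna().all():
            continue
        info: dict = {}
        if air_col is not None and air_col in out.columns and out[air_col].notna().any():
            obs_air = out[air_col].notna()
            s1 = _ols(
                out.loc[obs_air, air_col].to_numpy(float),
                out.loc[obs_air, ["latitude", "elevation"]],
                f"stage 1 ({air_col})",
            )
            air_pred = s1.predict(
                sm.add_constant(out[["latitude", "elevation"]], has_constant="add")
            )
            info["stage1"] = {"params": s1.params.to_dict(), "r2": float(s1.rsquared)}
            stage2_X = pd.DataFrame(
                {"depth": out["depth"], "area": out["area"], "air_pred": air_pred}
            )
        else:
            stage2_X = out[["depth", "area", "latitude", "elevation"]].copy()
        obs = out[water_col].notna()
        s2 = _ols(
            out.loc[obs, water_col].to_numpy(float), stage2_X.loc[obs],
            f"stage 2 ({water_col})",
        )
        pred = s2.predict(sm.add_constant(stage2_X, has_constant="add"))
        out.loc[~obs, water_col] = pred[~obs]
        info["stage2"] = {"params": s2.params.to_dict(), "r2": float(s2.rsquared)}
        info["n_observed"] = int(obs.sum())
        info["n_imputed"] = int((~obs).sum())
        stages[water_col] = info
    return ImputationResult(lakes=out, stages=stages)


def write_bundle(bundle: InputBundle, outdir) -> dict[str, str]:
    """Write the bundle back to the on-disk formats; returns path map."""
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
    bundle.records.to_csv(paths["records"], index=False)
    bundle.lakes.to_csv(paths["lakes"], index_label="lake_id")
    bundle.communities.to_csv(paths["communities"], index_label="lake_id")
    bundle.traits.to_csv(paths["traits"], index_label="species_id")
    write_tree(bundle.tree, paths["tree"])
    return {k: str(v) for k, v in paths.items()}
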