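"""Similarity and diversity covariates for introduction events.

For every lake the native-community diversity metrics are the mean pairwise
distance (MPD/MFD) and the mean nearest-neighbor distance (MNTD/MNFD),
computed on either the phylogenetic or the functional distance matrix.  For
every introduction event the exotic-native similarity metrics are the mean
(I-N MPD/MFD) and minimum (I-N MNTD/MNFD) distance from the introduced
species to the lake's native species.  Larger values always mean *less*
similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = [
    "UndefinedMetricError",
    "native_mean_pairwise",
    "native_mean_nearest",
    "introduced_native_mean",
    "introduced_native_nearest",
    "assemble_covariates",
    "CovariateTable",
    "MEAN_PREDICTORS",
    "NEAREST_PREDICTORS",
]

# predictor sets of the two metric families, in model order
MEAN_PREDICTORS = [
    "in_mpd", "in_mfd", "native_mpd", "native_mfd",
    "richness", "area", "elevation", "latitude",
]
NEAREST_PREDICTORS = [
    "in_mntd", "in_mnfd", "native_mntd", "native_mnfd",
    "richness", "area", "elevation", "latitude",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for a degenerate species set."""


def _subvalues(native_set, D: DistanceMatrix) -> np.ndarray:
    idx = D.indices(sorted(native_set))
    return D.values[np.ix_(idx, idx)]


def native_mean_pairwise(native_set, D: DistanceMatrix) -> float:
    """Mean distance over all unordered native pairs (MPD / MFD)."""
    if len(native_set) < 2:
        raise UndefinedMetricError("mean pairwise distance needs >= 2 natives")
    sub = _subvalues(native_set, D)
    iu = np.triu_indices(sub.shape[0], k=1)
    return float(sub[iu].mean())


def native_mean_nearest(native_set, D: DistanceMatrix) -> float:
    """Mean distance from each native to its nearest other native (MNTD / MNFD)."""
    if len(native_set) < 2:
        raise UndefinedMetricError("mean nearest distance needs >= 2 natives")
    sub = _subvalues(native_set, D).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _in_distances(introduced: str, native_set, D: DistanceMatrix) -> np.ndarray:
    natives = sorted(set(native_set) - {introduced})
    if not natives:
        raise UndefinedMetricError("empty native set for introduced-native metric")
    i = D.indices([introduced])[0]
    return D.values[i, D.indices(natives)]


def introduced_native_mean(introduced: str, native_set, D: DistanceMatrix) -> float:
    """Mean distance from the introduced species to all natives (I-N MPD / MFD).

    The introduced species is removed from the native set first, so a data
    error that codes the exotic as native in its own target lake cannot
    shrink the metric to zero.
    """
    return float(_in_distances(introduced, native_set, D).mean())


def introduced_native_nearest(introduced: str, native_set, D: DistanceMatrix) -> float:
    """Distance to the closest native relative/analog (I-N MNTD / MNFD)."""
    return float(_in_distances(introduced, native_set, D).min())


@dataclass
class CovariateTable:
    """Per-event covariate bundle plus a log of dropped/flagged events."""

    data: pd.DataFrame
    dropped: list[dict] = field(default_factory=list)
    flagged: list[dict] = field(default_factory=list)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)


def assemble_covariates(
    records: pd.DataFrame,
    lakes: pd.DataFrame,
    communities: dict[str, set],
    d_phy: DistanceMatrix,
    d_fun: DistanceMatrix,
    standardize: bool = True,
) -> CovariateTable:
    """One covariate row per introduction event.

    ``records`` needs columns lake_id, species_id, outcome (and optionally
    year); ``lakes`` is indexed by lake_id with columns area, elevation,
    latitude.  Events whose lake has fewer than two native species (after
    removing the introduced species itself, if present) are dropped with a
    log entry; an exotic coded native in its own target lake is flagged.
    Z-scored copies of every continuous covariate are appended with the
    ``_z`` suffix, computed over the retained event set.
    """
    rows = []
    dropped: list[dict] = []
    flagged: list[dict] = []
    lake_cache: dict[str, dict] = {}

    for rec in records.itertuples(index=False):
        lake_id, species_id = str(rec.lake_id), str(rec.species_id)
        natives_raw = communities.get(lake_id, set())
        if species_id in natives_raw:
            flagged.append(
                {"lake_id": lake_id, "species_id": species_id,
                 "reason": "introduced species coded native in target lake"}
            )
        natives = frozenset(natives_raw - {species_id})
        if len(natives) < 2:
            dropped.append(
                {"lake_id": lake_id, "species_id": species_id,
                 "reason": f"native richness {len(natives)} < 2"}
            )
            continue
        key = (lake_id, natives)
        if key not in lake_cache:
            lake_cache[key] = {
                "native_mpd": native_mean_pairwise(natives, d_phy),
                "native_mfd": native_mean_pairwise(natives, d_fun),
                "native_mntd": native_mean_nearest(natives, d_phy),
                "native_mnfd": native_mean_nearest(natives, d_fun),
                "richness": len(natives),
            }
        lk = lakes.loc[lake_id]
        row = {
            "lake_id": lake_id,
            "species_id": species_id,
            "outcome": int(rec.outcome),
            "in_mpd": introduced_native_mean(species_id, natives, d_phy),
            "in_mfd": introduced_native_mean(species_id, natives, d_fun),
            "in_mntd": introduced_native_nearest(species_id, natives, d_phy),
            "in_mnfd": introduced_native_nearest(species_id, natives, d_fun),
            **lake_cache[key],
            "area": float(lk["area"]),
            "elevation": float(lk["elevation"]),
            "latitude": float(lk["latitude"]),
        }
        for extra in ("accum_temp", "max_temp"):
            if extra in lakes.columns and pd.notna(lk[extra]):
                row[extra] = float(lk[extra])
        if hasattr(rec, "year"):
            row["year"] = rec.year
        rows.append(row)

    data = pd.DataFrame(rows)
    table = CovariateTable(data=data, dropped=dropped, flagged=flagged)
    if standardize and len(data):
        cont = [
            c for c in data.columns
            if c not in ("lake_id", "species_id", "outcome", "year")
        ]
        for c in cont:
            mu, sd = float(data[c].mean()), float(data[c].std(ddof=0))
            if sd == 0:
                continue
            data[c + "_z"] = (data[c] - mu) / sd
            table.standardization[c] = (mu, sd)
    return table
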