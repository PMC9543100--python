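import dendropy
import numpy as np
import pandas as pd
import pytest

from fishestab.distances import DistanceMatrix
from fishestab.synth import SynthConfig, generate


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture(scope="session")
def three_tip_tree():
    return tree_from("((A:1,B:1):2,C:3);")


@pytest.fixture(scope="session")
def synth_small():
    """A small but fully structured synthetic dataset shared across tests."""
    cfg = SynthConfig(n_species=15, n_lakes=40, n_events=200,
                      n_introduced_pool=8, seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def covariates_small(synth_small):
    from fishestab.metrics import assemble_covariates

    d = synth_small
    natives = {lk: set(row.index[row >= 1]) for lk, row in d.communities.iterrows()}
    return assemble_covariates(d.records, d.lakes, natives, d.d_phy, d.d_fun).data


def random_distance_matrix(rng: np.random.Generator, species: list[str]) -> DistanceMatrix:
    n = len(species)
    pts = rng.normal(size=(n, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(list(species), D, "functional")


@pytest.fixture
def toy_bundle(tmp_path):
    """Three-lake toy inputs written to disk for io round-trip tests."""
    from fishestab import io

    records = pd.DataFrame(
        {
            "lake_id": ["L1", "L1", "L2", "L3"],
            "species_id": ["A", "B", "A", "C"],
            "outcome": [1, 0, 1, 0],
            "year": [1950, 1960, 1970, 1980],
        }
    )
    lakes = pd.DataFrame(
        {
            "lake_id": ["L1", "L2", "L3"],
            "area": [10.0, 20.0, 30.0],
            "elevation": [100.0, 200.0, 300.0],
            "latitude": [56.0, 60.0, 64.0],
            "longitude": [12.0, 14.0, 16.0],
        }
    )
    communities = pd.DataFrame(
        {
            "lake_id": ["L1", "L2", "L3"],
            "A": [0, 1, 1],
            "B": [1, 0, 1],
            "C": [1, 1, 0],
            "D": [1, 1, 1],
        }
    )
    traits = pd.DataFrame(
        np.arange(4 * 10, dtype=float).reshape(4, 10) % 7,
        columns=[f"t{i}" for i in range(10)],
    )
    traits.insert(0, "species_id", ["A", "B", "C", "D"])
    paths = {
        "records_path": tmp_path / "records.csv",
        "lakes_path": tmp_path / "lakes.csv",
        "community_path": tmp_path / "communities.csv",
        "traits_path": tmp_path / "traits.csv",
        "tree_path": tmp_path / "tree.nwk",
    }
    records.to_csv(paths["records_path"], index=False)
    lakes.to_csv(paths["lakes_path"], index=False)
    communities.to_csv(paths["community_path"], index=False)
    traits.to_csv(paths["traits_path"], index=False)
    paths["tree_path"].write_text("((A:1,B:1):1,(C:1.5,D:1.5):0.5);\n")
    return paths
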