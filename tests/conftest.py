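import numpy as np
import pandas as pd
import pytest

from meltingpot.grid import BinaryMap, GridGeometry
from meltingpot.popgen import GenotypeTable
from meltingpot.synthetic import WorldConfig, generate_world


def small_world_config(**overrides) -> WorldConfig:
    """A reduced world for fast end-to-end tests.

    Ancestral-area radii are scaled down with the grid so stability areas
    stay patchy subsets of the refugia band (as in real landscapes) instead
    of blanketing it.
    """
    from meltingpot.synthetic import LineageSpec

    defaults = dict(
        grid_rows=30,
        grid_cols=40,
        n_populations=25,
        n_occurrences=150,
        n_target_group=400,
        dic_replicates=10,
        lineage_specs=(
            LineageSpec(center=(21, 6), dispersal_scale=25.0),
            LineageSpec(center=(21, 20), dispersal_scale=25.0),
            LineageSpec(center=(21, 33), dispersal_scale=25.0),
        ),
        seed=0,
    )
    defaults.update(overrides)
    return WorldConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_world_config(seed=5))


@pytest.fixture(scope="session")
def default_world():
    return generate_world(WorldConfig(seed=5))


@pytest.fixture
def geometry():
    return GridGeometry(rows=5, cols=6, x_origin=0.0, y_origin=0.0, cell_size=1.0, projected=True)


def make_binary(geometry, ones, nodata=-9999.0) -> BinaryMap:
    vals = np.zeros((geometry.rows, geometry.cols))
    for r, c in ones:
        vals[r, c] = 1.0
    return BinaryMap(geometry, vals, nodata=nodata)


def genotype_table(rows) -> GenotypeTable:
    """rows: (population, individual, locus, a, b) tuples; a/b None = missing."""
    df = pd.DataFrame(rows, columns=["population", "individual", "locus", "allele_a", "allele_b"])
    df["allele_a"] = df["allele_a"].astype(float)
    df["allele_b"] = df["allele_b"].astype(float)
    return GenotypeTable(df)


def table_from_allele_counts(counts: dict, locus: str = "L1", population: str = "A") -> GenotypeTable:
    """Build a single-locus population whose allele counts equal ``counts``
    (gene copies paired arbitrarily into diploid genotypes)."""
    copies = [allele for allele, k in counts.items() for _ in range(k)]
    assert len(copies) % 2 == 0, "need an even number of gene copies"
    rows = []
    for i in range(len(copies) // 2):
        rows.append((population, f"i{i}", locus, copies[2 * i], copies[2 * i + 1]))
    return genotype_table(rows)
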