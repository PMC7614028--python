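import numpy as np
import pandas as pd
import pytest

from narweb.grid_io import GridSpec, Metaweb, RangeStack
from narweb.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture
def chain_metaweb() -> Metaweb:
    """a <- b <- c : a basal, b intermediate, c top."""
    species = pd.DataFrame(
        {
            "species_id": ["a", "b", "c"],
            "name": ["A", "B", "C"],
            "group": ["", "", ""],
        }
    )
    return Metaweb(species=species, links=frozenset({("c", "b"), ("b", "a")}))


@pytest.fixture
def grid_2x2() -> GridSpec:
    return GridSpec(n_rows=2, n_cols=2)


@pytest.fixture(scope="session")
def small_scenario():
    cfg = ScenarioConfig(
        seed=7,
        s_pool=60,
        c_target=0.08,
        basal_fraction=0.5,
        n_rows=12,
        n_cols=12,
        n_regions=2,
        range_median=25.0,
        range_sigma=0.8,
        habitat_k=4,
        habitat_clustering=0.8,
    )
    return generate_scenario(cfg)


def make_metaweb(n: int, links) -> Metaweb:
    species = pd.DataFrame(
        {
            "species_id": [f"s{i}" for i in range(n)],
            "name": [f"s{i}" for i in range(n)],
            "group": [""] * n,
        }
    )
    return Metaweb(species=species, links=frozenset(links))


def singleton_ranges(n: int) -> tuple[GridSpec, Metaweb, RangeStack]:
    """n species, each occupying exactly one distinct cell of an n-cell
    region (forces S(A) = A along any aggregation path)."""
    rows = int(np.sqrt(n))
    while n % rows:
        rows -= 1
    grid = GridSpec(n_rows=rows, n_cols=n // rows)
    metaweb = make_metaweb(n, set())
    presence = np.eye(n, dtype=bool)
    ranges = RangeStack(
        grid=grid, species_ids=tuple(metaweb.species_ids), presence=presence
    )
    return grid, metaweb, ranges
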