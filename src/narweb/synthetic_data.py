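"""Synthetic generators for every input the pipeline needs: a trophically
hierarchical metaweb, contiguous autocorrelated species ranges, clustered
habitat mosaics, smooth-plus-noise climate fields and a contiguous region
partition of the grid.

All generators are pure functions of their parameters and a seed. Each draws
from its own RNG stream derived as ``default_rng([seed, offset])`` with a
fixed per-generator offset, so outputs do not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import (
    OUTSIDE,
    ClimateRaster,
    GridSpec,
    HabitatRaster,
    Metaweb,
    RangeStack,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "gen_metaweb",
    "gen_ranges",
    "gen_habitat",
    "gen_climate_field",
    "gen_bioregions",
    "generate_scenario",
]

# fixed RNG stream offsets, one per generator
_STREAM = {
    "metaweb": 11,
    "ranges": 23,
    "habitat": 37,
    "climate": 41,
    "regions": 53,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream], int(extra)])


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters for a full synthetic scenario."""

    seed: int = 0
    s_pool: int = 150
    c_target: float = 0.08
    basal_fraction: float = 0.5
    n_rows: int = 30
    n_cols: int = 30
    cell_size_km: float = 10.0
    n_regions: int = 4
    range_median: float = 60.0
    range_sigma: float = 1.0
    habitat_k: int = 6
    habitat_clustering: float = 0.8
    climate_variables: dict = field(
        default_factory=lambda: {
            "mean_annual_temperature": {"base": 8.0, "gradient": 0.3, "noise_sd": 1.5},
            "temperature_seasonality": {"base": 500.0, "gradient": 5.0, "noise_sd": 40.0},
            "annual_precipitation": {"base": 800.0, "gradient": -4.0, "noise_sd": 60.0},
            "precipitation_seasonality": {"base": 30.0, "gradient": 0.2, "noise_sd": 3.0},
        }
    )

    def __post_init__(self) -> None:
        if self.s_pool < 2:
            raise ValueError("s_pool must be >= 2")
        if not (0 <= self.basal_fraction <= 1):
            raise ValueError("basal_fraction must be in [0, 1]")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dims must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """All five inputs of a synthetic run."""

    config: ScenarioConfig
    grid: GridSpec
    metaweb: Metaweb
    ranges: RangeStack
    habitat: HabitatRaster
    climate: ClimateRaster


def gen_metaweb(
    s_pool: int, c_target: float, basal_fraction: float, seed: int
) -> Metaweb:
    """Niche-model metaweb with a forced basal fraction.

    Each species gets a niche value uniform on (0, 1). The ``basal_fraction``
    of species with the lowest niche values get feeding range 0. Each
    consumer draws a feeding-range scale from a Beta(1, b) with b tuned so
    the expected connectance over the whole pool equals ``c_target``; the
    feeding interval is centred uniformly below the consumer's niche value,
    and every species whose niche value falls inside it becomes its prey.
    """
    if s_pool < 2:
        raise ValueError("s_pool must be >= 2")
    if not (0 < c_target < 0.5):
        raise ValueError("c_target must be in (0, 0.5)")
    if not (0 <= basal_fraction <= 1):
        raise ValueError("basal_fraction must be in [0, 1]")
    rng = _rng(seed, "metaweb")
    niche = np.sort(rng.uniform(size=s_pool))
    n_basal = int(round(basal_fraction * s_pool))
    consumers = np.arange(n_basal, s_pool)
    links: set[tuple[str, str]] = set()
    if consumers.size:
        # diet size of consumer i ~ S * x * niche_i, so E[L] = S * E[x] *
        # sum of consumer niche values; solve E[x] so pool connectance
        # L / S^2 lands on c_target (consumers sit in the upper niche range,
        # so their niche sum, not S/2, sets the scale)
        mean_x = c_target * s_pool / niche[consumers].sum()
        if mean_x >= 0.5:
            raise ValueError(
                f"c_target {c_target} infeasible with basal_fraction "
                f"{basal_fraction}: required mean feeding-range scale "
                f"{mean_x:.3f} >= 0.5"
            )
        b = 1.0 / mean_x - 1.0
        for i in consumers:
            r = niche[i] * rng.beta(1.0, b)
            centre = rng.uniform(r / 2.0, min(niche[i], 1.0 - r / 2.0))
            lo, hi = centre - r / 2.0, centre + r / 2.0
            prey = np.flatnonzero((niche >= lo) & (niche <= hi))
            for j in prey:
                links.add((f"sp{i:04d}", f"sp{j:04d}"))
    species = pd.DataFrame(
        {
            "species_id": [f"sp{i:04d}" for i in range(s_pool)],
            "name": [f"species {i}" for i in range(s_pool)],
            "group": ["basal" if i < n_basal else "consumer" for i in range(s_pool)],
        }
    )
    return Metaweb(species=species, links=frozenset(links))


def _neighbors4(cell: int, n_rows: int, n_cols: int) -> list[int]:
    r, c = divmod(cell, n_cols)
    out = []
    if r > 0:
        out.append(cell - n_cols)
    if r < n_rows - 1:
        out.append(cell + n_cols)
    if c > 0:
        out.append(cell - 1)
    if c < n_cols - 1:
        out.append(cell + 1)
    return out


def _grow_patch(
    start: int,
    size: int,
    allowed: np.ndarray,
    grid: GridSpec,
    rng: np.random.Generator,
) -> set[int]:
    """Rook-connected patch of exactly ``size`` cells (capped by the reachable
    component) grown by randomised breadth-first accretion."""
    allowed_set = set(int(c) for c in allowed)
    patch = {start}
    frontier = [n for n in _neighbors4(start, grid.n_rows, grid.n_cols) if n in allowed_set]
    while len(patch) < size and frontier:
        k = rng.integers(len(frontier))
        cell = frontier.pop(k)
        if cell in patch:
            continue
        patch.add(cell)
        for n in _neighbors4(cell, grid.n_rows, grid.n_cols):
            if n in allowed_set and n not in patch:
                frontier.append(n)
    return patch


def gen_ranges(
    grid: GridSpec,
    metaweb: Metaweb,
    range_median: float,
    range_sigma: float,
    seed: int,
) -> RangeStack:
    """Contiguous species ranges with lognormal sizes.

    Per species: draw a range size (cells) from a lognormal with the given
    median and sigma, truncated to [1, number of in-region cells]; seed a
    uniformly random in-region cell and grow a rook-connected patch of that
    size by randomised accretion.
    """
    in_region = grid.in_region_cells()
    if in_region.size == 0:
        raise ValueError("grid has no in-region cells")
    rng = _rng(seed, "ranges")
    n_sp = metaweb.n_species
    sizes = np.exp(rng.normal(np.log(range_median), range_sigma, size=n_sp))
    sizes = np.clip(np.round(sizes).astype(int), 1, in_region.size)
    presence = np.zeros((n_sp, grid.n_cells), dtype=bool)
    for i in range(n_sp):
        start = int(rng.choice(in_region))
        patch = _grow_patch(start, int(sizes[i]), in_region, grid, rng)
        presence[i, list(patch)] = True
    return RangeStack(
        grid=grid, species_ids=tuple(metaweb.species_ids), presence=presence
    )


def gen_habitat(
    grid: GridSpec, k: int, clustering_strength: float, seed: int
) -> HabitatRaster:
    """Clustered one-hot habitat mosaic with K classes.

    K random seed cells define competing domains; each cell is assigned the
    class whose seed minimises Chebyshev distance plus uniform noise whose
    amplitude shrinks with ``clustering_strength``. High clustering gives
    compact Voronoi-like patches (high Moran's I); low clustering approaches
    a random labelling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > grid.n_cells:
        raise ValueError("more habitat classes than cells")
    rng = _rng(seed, "habitat")
    seeds = rng.choice(grid.n_cells, size=k, replace=False)
    rows, cols = np.divmod(np.arange(grid.n_cells), grid.n_cols)
    srows, scols = np.divmod(seeds, grid.n_cols)
    dist = np.maximum(
        np.abs(rows[:, None] - srows[None, :]),
        np.abs(cols[:, None] - scols[None, :]),
    ).astype(float)
    amp = (1.0 - np.clip(clustering_strength, 0.0, 1.0)) * max(
        grid.n_rows, grid.n_cols
    )
    score = dist + rng.uniform(0.0, 1.0, size=dist.shape) * amp
    winner = score.argmin(axis=1)
    props = np.zeros((grid.n_cells, k))
    props[np.arange(grid.n_cells), winner] = 1.0
    return HabitatRaster(
        grid=grid,
        class_ids=tuple(f"h{j:02d}" for j in range(k)),
        proportions=props,
    )


def gen_climate_field(
    grid: GridSpec,
    base: float,
    gradient_per_cell: float,
    noise_sd: float,
    seed: int,
    variable: str = "mean_annual_temperature",
    stream_extra: int = 0,
) -> ClimateRaster:
    """One climate layer: ``base + gradient * row + N(0, noise_sd)``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "climate", extra=stream_extra)
    rows = np.arange(grid.n_cells) // grid.n_cols
    values = base + gradient_per_cell * rows
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=grid.n_cells)
    return ClimateRaster(grid=grid, variables={variable: values})


def gen_bioregions(
    n_rows: int,
    n_cols: int,
    n_regions: int,
    seed: int,
    cell_size_km: float = 10.0,
) -> GridSpec:
    """Contiguous partition of the full grid into ``n_regions`` labelled
    regions, grown by randomised multi-source flood fill from random seeds."""
    n_cells = n_rows * n_cols
    if not (1 <= n_regions <= n_cells):
        raise ValueError("n_regions must be in [1, cells]")
    rng = _rng(seed, "regions")
    seeds = rng.choice(n_cells, size=n_regions, replace=False)
    label = np.full(n_cells, -1, dtype=int)
    frontier: list[tuple[int, int]] = []
    for lab, s in enumerate(seeds):
        label[s] = lab
        for n in _neighbors4(int(s), n_rows, n_cols):
            frontier.append((n, lab))
    while frontier:
        k = int(rng.integers(len(frontier)))
        cell, lab = frontier.pop(k)
        if label[cell] != -1:
            continue
        label[cell] = lab
        for n in _neighbors4(cell, n_rows, n_cols):
            if label[n] == -1:
                frontier.append((n, lab))
    names = [f"region{j + 1}" for j in range(n_regions)]
    return GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_km=cell_size_km,
        region_label=tuple(names[l] for l in label),
    )


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate all five pipeline inputs from one config."""
    grid = gen_bioregions(
        config.n_rows,
        config.n_cols,
        config.n_regions,
        config.seed,
        cell_size_km=config.cell_size_km,
    )
    metaweb = gen_metaweb(
        config.s_pool, config.c_target, config.basal_fraction, config.seed
    )
    ranges = gen_ranges(
        grid, metaweb, config.range_median, config.range_sigma, config.seed
    )
    habitat = gen_habitat(
        grid, config.habitat_k, config.habitat_clustering, config.seed
    )
    layers: dict[str, np.ndarray] = {}
    for i, (name, p) in enumerate(sorted(config.climate_variables.items())):
        one = gen_climate_field(
            grid,
            p["base"],
            p["gradient"],
            p["noise_sd"],
            config.seed,
            variable=name,
            stream_extra=i,
        )
        layers[name] = one.variables[name]
    climate = ClimateRaster(grid=grid, variables=layers)
    return Scenario(
        config=config,
        grid=grid,
        metaweb=metaweb,
        ranges=ranges,
        habitat=habitat,
        climate=climate,
    )
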