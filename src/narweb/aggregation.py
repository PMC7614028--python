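"""Spiral cell aggregation: spatially coherent nested areas grown outward
from a start cell.

The spiral is realised as Chebyshev-distance rings around the start cell,
each ring walked clockwise starting due north; cells outside the region are
simply skipped. Every prefix of the resulting order defines an aggregation
area, and the full order is a permutation of the region's cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .grid_io import GridSpec

__all__ = ["AggregationPath", "spiral_order", "sample_paths", "paths_to_table"]


@dataclass(frozen=True)
class AggregationPath:
    region: str
    start_cell: int
    order: tuple[int, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.order and self.order[0] != self.start_cell:
            raise ValueError("order must begin at start_cell")

    def __len__(self) -> int:
        return len(self.order)


def _ring(row: int, col: int, r: int) -> Iterator[tuple[int, int]]:
    """Perimeter of the Chebyshev ring of radius r, clockwise from due
    north."""
    if r == 0:
        yield row, col
        return
    # north edge, centre -> NE corner
    for c in range(col, col + r):
        yield row - r, c
    # east edge, NE -> SE corner
    for rr in range(row - r, row + r):
        yield rr, col + r
    # south edge, SE -> SW corner
    for c in range(col + r, col - r, -1):
        yield row + r, c
    # west edge, SW -> NW corner
    for rr in range(row + r, row - r, -1):
        yield rr, col - r
    # north edge, NW corner -> just before centre
    for c in range(col - r, col):
        yield row - r, c


def spiral_order(grid: GridSpec, region: str, start_cell: int) -> AggregationPath:
    """Deterministic spiral enumeration of a region's cells from a start
    cell.

    Rings r = 0, 1, 2, ... are walked clockwise from due north; cells outside
    the grid or the region are skipped. Stops when the whole region has been
    emitted.
    """
    region_cells = set(int(c) for c in grid.region_cells(region))
    if not region_cells:
        raise ValueError(f"region {region!r} has no cells")
    if start_cell not in region_cells:
        raise ValueError(f"start cell {start_cell} not in region {region!r}")
    row0, col0 = grid.row_col(start_cell)
    order: list[int] = []
    max_ring = grid.n_rows + grid.n_cols
    for r in range(max_ring + 1):
        for rr, cc in _ring(row0, col0, r):
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                cell = rr * grid.n_cols + cc
                if cell in region_cells:
                    order.append(cell)
        if len(order) == len(region_cells):
            break
    if len(order) != len(region_cells):  # pragma: no cover - ring bound proof
        raise RuntimeError("spiral did not cover the region")
    return AggregationPath(region=region, start_cell=start_cell, order=tuple(order))


def _random_order(
    grid: GridSpec, region: str, start_cell: int, rng: np.random.Generator
) -> AggregationPath:
    """Debug mode: uniformly random cell order after the start cell."""
    cells = [int(c) for c in grid.region_cells(region) if c != start_cell]
    rng.shuffle(cells)
    return AggregationPath(
        region=region, start_cell=start_cell, order=(start_cell, *cells)
    )


def sample_paths(
    grid: GridSpec,
    region: str,
    n_replicates: int,
    seed: int,
    order: str = "spiral",
) -> list[AggregationPath]:
    """Replicate aggregation paths from start cells drawn uniformly with
    replacement; replicate k uses a sub-seed derived from (seed, k)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cells = grid.region_cells(region)
    if cells.size == 0:
        raise ValueError(f"region {region!r} has no cells")
    paths = []
    for k in range(n_replicates):
        rng = np.random.default_rng([int(seed), 97, k])
        start = int(cells[rng.integers(cells.size)])
        if order == "spiral":
            path = spiral_order(grid, region, start)
        elif order == "random":
            path = _random_order(grid, region, start, rng)
        else:
            raise ValueError(f"unknown order {order!r}")
        paths.append(
            AggregationPath(
                region=region, start_cell=start, order=path.order, seed=seed
            )
        )
    return paths


def paths_to_table(paths: list[AggregationPath], grid: GridSpec) -> pd.DataFrame:
    """Audit table (replicate, step, row, col)."""
    recs = []
    for k, p in enumerate(paths):
        for step, cell in enumerate(p.order):
            r, c = grid.row_col(cell)
            recs.append({"replicate": k, "step": step, "row": r, "col": c})
    return pd.DataFrame(recs, columns=["replicate", "step", "row", "col"])
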