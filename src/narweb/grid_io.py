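"""Data model and CSV readers/writers for metawebs, gridded presence, habitat
and climate rasters, and tabular outputs.

All grids use 0-based ``(row, col)`` coordinates with row-major cell ids.
Every format is plain UTF-8 CSV with a mandatory header row; lines starting
with ``#`` are treated as provenance comments and skipped on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

OUTSIDE = "outside"

__all__ = [
    "OUTSIDE",
    "GridSpec",
    "Metaweb",
    "RangeStack",
    "HabitatRaster",
    "ClimateRaster",
    "read_metaweb",
    "write_metaweb",
    "read_presence",
    "write_presence",
    "upscale_presence",
    "read_cell_raster",
    "write_habitat",
    "write_climate",
    "read_region_map",
    "write_region_map",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of equal-area cells with a region label per cell.

    ``region_label`` holds one region name per cell (row-major order) or
    :data:`OUTSIDE` for cells that belong to no region.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 10.0
    region_label: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.region_label is None:
            object.__setattr__(
                self, "region_label", ("R1",) * (self.n_rows * self.n_cols)
            )
        else:
            object.__setattr__(self, "region_label", tuple(self.region_label))
        if len(self.region_label) != self.n_rows * self.n_cols:
            raise ValueError("region_label length must equal n_rows * n_cols")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def row_col(self, cell: int) -> tuple[int, int]:
        if not 0 <= cell < self.n_cells:
            raise ValueError(f"cell id {cell} out of range")
        return divmod(cell, self.n_cols)

    @property
    def regions(self) -> list[str]:
        """Region names in first-appearance order, excluding ``outside``."""
        seen: dict[str, None] = {}
        for lab in self.region_label:
            if lab != OUTSIDE:
                seen.setdefault(lab)
        return list(seen)

    def region_cells(self, region: str) -> np.ndarray:
        """Cell ids of a region, ascending."""
        labels = np.asarray(self.region_label, dtype=object)
        cells = np.flatnonzero(labels == region)
        return cells

    def in_region_cells(self) -> np.ndarray:
        labels = np.asarray(self.region_label, dtype=object)
        return np.flatnonzero(labels != OUTSIDE)


@dataclass(frozen=True)
class Metaweb:
    """Species pool plus the set of potential consumer->resource links."""

    species: pd.DataFrame  # columns: species_id, name, group
    links: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = self.species["species_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate species id {dup!r}")
        known = set(ids)
        for c, r in self.links:
            if c not in known:
                raise ValueError(f"unknown species id {c!r} in link list")
            if r not in known:
                raise ValueError(f"unknown species id {r!r} in link list")

    @property
    def species_ids(self) -> list[str]:
        return list(self.species["species_id"])

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def prey_of(self) -> dict[str, set[str]]:
        """consumer -> set of resources (self-links included as stored)."""
        out: dict[str, set[str]] = {s: set() for s in self.species_ids}
        for c, r in self.links:
            out[c].add(r)
        return out

    def consumers_of(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {s: set() for s in self.species_ids}
        for c, r in self.links:
            out[r].add(c)
        return out


@dataclass(frozen=True)
class RangeStack:
    """Boolean species x cells presence matrix on a grid."""

    grid: GridSpec
    species_ids: tuple[str, ...]
    presence: np.ndarray  # bool, shape (n_species, n_cells)

    def __post_init__(self) -> None:
        pres = np.asarray(self.presence)
        if pres.dtype != bool:
            raise ValueError("presence must be boolean")
        if pres.shape != (len(self.species_ids), self.grid.n_cells):
            raise ValueError("presence shape does not match species x cells")
        object.__setattr__(self, "species_ids", tuple(self.species_ids))

    def species_at(self, cells: Iterable[int]) -> set[str]:
        idx = np.fromiter(cells, dtype=int)
        if idx.size == 0:
            return set()
        mask = self.presence[:, idx].any(axis=1)
        return {s for s, m in zip(self.species_ids, mask) if m}


@dataclass(frozen=True)
class HabitatRaster:
    """Per-cell habitat-class cover proportions (rows sum to 1)."""

    grid: GridSpec
    class_ids: tuple[str, ...]
    proportions: np.ndarray  # float, shape (n_cells, K)

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (self.grid.n_cells, len(self.class_ids)):
            raise ValueError("proportions shape does not match cells x classes")
        if (props < 0).any():
            raise ValueError("negative habitat proportion")
        sums = props.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"habitat proportions of cell {bad} sum to {sums[bad]:.6f}, not 1"
            )
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "class_ids", tuple(self.class_ids))


@dataclass(frozen=True)
class ClimateRaster:
    """Named per-cell numeric climate layers."""

    grid: GridSpec
    variables: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        in_region = self.grid.in_region_cells()
        for name, layer in self.variables.items():
            arr = np.asarray(layer, dtype=float)
            if arr.shape != (self.grid.n_cells,):
                raise ValueError(f"layer {name!r} has wrong shape")
            if not np.all(np.isfinite(arr[in_region])):
                raise ValueError(f"layer {name!r} has non-finite in-region values")
            clean[name] = arr
        object.__setattr__(self, "variables", clean)


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=kw.pop("dtype", None), **kw)


def read_metaweb(
    species_table_path: str | Path,
    edge_list_path: str | Path,
    lenient: bool = False,
) -> Metaweb:
    """Load a metaweb from a species table and a consumer->resource edge list.

    Duplicate edge rows are a hard error unless ``lenient`` is set, in which
    case they are silently deduplicated.
    """
    species = _read_csv(species_table_path, dtype=str)
    if "species_id" not in species.columns:
        raise ValueError("species table must have a species_id column")
    for col in ("name", "group"):
        if col not in species.columns:
            species[col] = ""
    species = species[["species_id", "name", "group"]].fillna("")
    edges = _read_csv(edge_list_path, dtype=str)
    for col in ("consumer_id", "resource_id"):
        if col not in edges.columns:
            raise ValueError(f"edge list must have a {col} column")
    pairs = list(zip(edges["consumer_id"], edges["resource_id"]))
    if len(pairs) != len(set(pairs)) and not lenient:
        seen: set[tuple[str, str]] = set()
        for p in pairs:
            if p in seen:
                raise ValueError(f"duplicate link {p[0]!r}->{p[1]!r} in edge list")
            seen.add(p)
    return Metaweb(species=species, links=frozenset(pairs))


def write_metaweb(
    metaweb: Metaweb, species_table_path: str | Path, edge_list_path: str | Path
) -> None:
    write_table(metaweb.species, species_table_path)
    edges = pd.DataFrame(
        sorted(metaweb.links), columns=["consumer_id", "resource_id"]
    )
    write_table(edges, edge_list_path)


def read_presence(long_table_path: str | Path, grid: GridSpec) -> RangeStack:
    """Load presence from a long-format CSV (species_id, row, col).

    Repeated rows are tolerated (presence is idempotent); coordinates outside
    the grid are a hard error.
    """
    df = _read_csv(long_table_path)
    species: list[str] = []
    index: dict[str, int] = {}
    rows_list: list[tuple[int, int]] = []
    for sp, r, c in zip(
        df["species_id"].astype(str), df["row"].astype(int), df["col"].astype(int)
    ):
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
            raise ValueError(f"presence ({sp}, {r}, {c}) outside the grid")
        if sp not in index:
            index[sp] = len(species)
            species.append(sp)
        rows_list.append((index[sp], r * grid.n_cols + c))
    presence = np.zeros((len(species), grid.n_cells), dtype=bool)
    for i, cell in rows_list:
        presence[i, cell] = True
    return RangeStack(grid=grid, species_ids=tuple(species), presence=presence)


def write_presence(ranges: RangeStack, path: str | Path) -> None:
    recs = []
    for i, sp in enumerate(ranges.species_ids):
        for cell in np.flatnonzero(ranges.presence[i]):
            r, c = ranges.grid.row_col(int(cell))
            recs.append((sp, r, c))
    write_table(pd.DataFrame(recs, columns=["species_id", "row", "col"]), path)


def upscale_presence(fine: RangeStack, factor: int) -> RangeStack:
    """Boolean max-pool presence onto a coarser grid.

    A coarse cell is occupied iff any constituent fine cell is. When the fine
    dimensions are not divisible by ``factor``, the fine grid is padded with
    absences on the bottom/right.
    """
    if factor <= 0:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return fine
    g = fine.grid
    n_rows = -(-g.n_rows // factor)
    n_cols = -(-g.n_cols // factor)
    pres = fine.presence.reshape(len(fine.species_ids), g.n_rows, g.n_cols)
    padded = np.zeros(
        (len(fine.species_ids), n_rows * factor, n_cols * factor), dtype=bool
    )
    padded[:, : g.n_rows, : g.n_cols] = pres
    coarse = (
        padded.reshape(len(fine.species_ids), n_rows, factor, n_cols, factor)
        .any(axis=(2, 4))
        .reshape(len(fine.species_ids), -1)
    )
    coarse_grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_km=g.cell_size_km * factor,
    )
    return RangeStack(
        grid=coarse_grid, species_ids=fine.species_ids, presence=coarse
    )


def read_cell_raster(
    long_table_path: str | Path, grid: GridSpec, kind: str
) -> HabitatRaster | ClimateRaster:
    """Load a habitat (row,col,class_id,proportion) or climate
    (row,col,variable,value) long table onto a grid.

    Habitat proportions are renormalised to sum exactly 1 per cell when the
    raw sum is within 1e-3 of 1, and rejected otherwise.
    """
    if kind not in ("habitat", "climate"):
        raise ValueError("kind must be 'habitat' or 'climate'")
    df = _read_csv(long_table_path)
    if kind == "habitat":
        classes = sorted(df["class_id"].astype(str).unique())
        cidx = {c: k for k, c in enumerate(classes)}
        props = np.zeros((grid.n_cells, len(classes)))
        for r, c, cls, p in zip(
            df["row"].astype(int),
            df["col"].astype(int),
            df["class_id"].astype(str),
            df["proportion"].astype(float),
        ):
            if p < 0:
                raise ValueError(f"negative proportion at ({r}, {c})")
            props[grid.cell_id(r, c), cidx[cls]] += p
        sums = props.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-3
        if bad.any():
            cell = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"habitat proportions of cell {cell} sum to {sums[cell]:.4f}"
            )
        props /= sums[:, None]
        return HabitatRaster(grid=grid, class_ids=tuple(classes), proportions=props)
    variables: dict[str, np.ndarray] = {}
    for name, sub in df.groupby("variable"):
        layer = np.full(grid.n_cells, np.nan)
        for r, c, v in zip(
            sub["row"].astype(int), sub["col"].astype(int), sub["value"].astype(float)
        ):
            layer[grid.cell_id(r, c)] = v
        variables[str(name)] = layer
    in_region = grid.in_region_cells()
    for name, layer in variables.items():
        if not np.all(np.isfinite(layer[in_region])):
            cell = int(in_region[~np.isfinite(layer[in_region])][0])
            raise ValueError(f"missing climate value for {name!r} at cell {cell}")
    return ClimateRaster(grid=grid, variables=variables)


def write_habitat(habitat: HabitatRaster, path: str | Path) -> None:
    recs = []
    for cell in range(habitat.grid.n_cells):
        r, c = habitat.grid.row_col(cell)
        for k, cls in enumerate(habitat.class_ids):
            p = habitat.proportions[cell, k]
            if p > 0:
                recs.append((r, c, cls, p))
    write_table(
        pd.DataFrame(recs, columns=["row", "col", "class_id", "proportion"]), path
    )


def write_climate(climate: ClimateRaster, path: str | Path) -> None:
    recs = []
    for name, layer in climate.variables.items():
        for cell in range(climate.grid.n_cells):
            if np.isfinite(layer[cell]):
                r, c = climate.grid.row_col(cell)
                recs.append((r, c, name, layer[cell]))
    write_table(pd.DataFrame(recs, columns=["row", "col", "variable", "value"]), path)


def read_region_map(
    path: str | Path, n_rows: int, n_cols: int, cell_size_km: float = 10.0
) -> GridSpec:
    """Build a GridSpec from a (row, col, region) table; unlisted cells are
    labelled ``outside``."""
    df = _read_csv(path)
    labels = [OUTSIDE] * (n_rows * n_cols)
    for r, c, reg in zip(
        df["row"].astype(int), df["col"].astype(int), df["region"].astype(str)
    ):
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"region cell ({r}, {c}) outside the grid")
        labels[r * n_cols + c] = reg
    return GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_km=cell_size_km,
        region_label=tuple(labels),
    )


def write_region_map(grid: GridSpec, path: str | Path) -> None:
    recs = []
    for cell, lab in enumerate(grid.region_label):
        if lab != OUTSIDE:
            r, c = grid.row_col(cell)
            recs.append((r, c, lab))
    write_table(pd.DataFrame(recs, columns=["row", "col", "region"]), path)


def write_table(
    records: pd.DataFrame | Sequence[Mapping],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a CSV with header, given column/row order, floats at 10
    significant digits. Successive writes of equal records are byte-identical.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path)
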