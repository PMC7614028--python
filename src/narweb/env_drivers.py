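"""Per-region environmental predictors and their statistical link to
scaling exponents.

Covers pairwise Bray-Curtis dissimilarity of habitat composition, Moran's I
spatial autocorrelation of habitat presence, climate mean/SD summaries,
commonality analysis (variance partitioning of a multiple regression R^2
over all predictor subsets) and the final OLS of z-exponents on selected
predictors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist

from .grid_io import ClimateRaster, GridSpec, HabitatRaster

__all__ = [
    "AdjacencySpec",
    "EnvSummary",
    "CommonalityResult",
    "bray_curtis_pair",
    "region_bray_curtis",
    "morans_i_layer",
    "region_habitat_clustering",
    "climate_summary",
    "region_env_summary",
    "env_summary_table",
    "commonality_analysis",
    "select_predictors",
    "fit_z_regression",
]


@dataclass(frozen=True)
class AdjacencySpec:
    """Binary symmetric spatial weights between grid cells."""

    scheme: str = "rook"  # or "queen"

    def __post_init__(self) -> None:
        if self.scheme not in ("rook", "queen"):
            raise ValueError("scheme must be 'rook' or 'queen'")

    def neighbor_pairs(self, grid: GridSpec, cells: np.ndarray) -> np.ndarray:
        """Ordered (i, j) index pairs into ``cells`` that are adjacent
        (both directions), restricted to the given cells."""
        cells = np.asarray(cells, dtype=int)
        index = {int(c): k for k, c in enumerate(cells)}
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if self.scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        pairs = []
        for k, cell in enumerate(cells):
            r, c = divmod(int(cell), grid.n_cols)
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                    other = index.get(rr * grid.n_cols + cc)
                    if other is not None:
                        pairs.append((k, other))
        return np.asarray(pairs, dtype=int).reshape(-1, 2)


@dataclass(frozen=True)
class EnvSummary:
    region: str
    area_cells: int
    n_habitats: int
    bray_curtis: Optional[float]
    bray_curtis_estimated: bool
    morans_i: Optional[float]
    climate: dict  # variable -> (mean, sd)


@dataclass(frozen=True)
class CommonalityResult:
    predictors: tuple[str, ...]
    subset_r2: dict  # frozenset of names -> R^2
    coefficients: dict  # frozenset of names -> commonality coefficient
    full_r2: float

    def unique_effect(self, name: str) -> float:
        return self.coefficients[frozenset([name])]


def bray_curtis_pair(
    cell_i: np.ndarray, cell_j: np.ndarray, convention: str = "abundance"
) -> float:
    """1 - 2*sum(min)/(S_i + S_j) over habitat-cover vectors.

    ``abundance`` (default, the vegan convention): S_i is the sum of cover
    proportions. ``richness``: S_i is the count of habitats present
    (proportion > 0), a literal reading of "total number of habitats".
    """
    u = np.asarray(cell_i, dtype=float)
    v = np.asarray(cell_j, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("negative proportions")
    if convention == "abundance":
        denom = u.sum() + v.sum()
    elif convention == "richness":
        denom = float((u > 0).sum() + (v > 0).sum())
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * np.minimum(u, v).sum() / denom


def region_bray_curtis(
    habitat: HabitatRaster,
    region: str,
    pair_budget: int = 200_000,
    seed: int = 0,
    convention: str = "abundance",
) -> tuple[Optional[float], bool]:
    """Mean pairwise Bray-Curtis over a region's cells.

    Exact all-pairs mean when the pair count fits in ``pair_budget``;
    otherwise the mean over a seeded uniform sample of pairs (without
    replacement), flagged estimated. Returns (mean, estimated);
    (None, False) for regions of fewer than two cells.
    """
    cells = habitat.grid.region_cells(region)
    n = cells.size
    if n < 2:
        return None, False
    props = habitat.proportions[cells]
    if convention == "richness":
        counts = (props > 0).sum(axis=1).astype(float)
    elif convention == "abundance":
        counts = props.sum(axis=1)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    n_pairs = n * (n - 1) // 2
    if n_pairs <= pair_budget:
        if convention == "abundance":
            # for non-negative rows pdist's braycurtis equals the 2*min form
            return float(pdist(props, metric="braycurtis").mean()), False
        total = 0.0
        for a, b in itertools.combinations(range(n), 2):
            denom = counts[a] + counts[b]
            if denom > 0:
                total += 1.0 - 2.0 * np.minimum(props[a], props[b]).sum() / denom
        return total / n_pairs, False
    rng = np.random.default_rng([int(seed), 149])
    # sample distinct unordered pairs without replacement
    if n_pairs <= 4 * pair_budget:
        idx = rng.choice(n_pairs, size=pair_budget, replace=False)
        chosen = set(int(k) for k in idx)
        pairs = [
            p
            for k, p in enumerate(itertools.combinations(range(n), 2))
            if k in chosen
        ]
    else:
        seen: set[tuple[int, int]] = set()
        while len(seen) < pair_budget:
            a = int(rng.integers(0, n))
            b = int(rng.integers(0, n - 1))
            if b >= a:
                b += 1
            seen.add((min(a, b), max(a, b)))
        pairs = sorted(seen)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    mins = np.minimum(props[i], props[j]).sum(axis=1)
    sums = counts[i] + counts[j]
    vals = 1.0 - 2.0 * mins / np.where(sums == 0, 1.0, sums)
    return float(vals.mean()), True


def morans_i_layer(
    x: np.ndarray,
    grid: GridSpec,
    region: str,
    adjacency: AdjacencySpec = AdjacencySpec(),
) -> Optional[float]:
    """Moran's I of a per-cell layer over one region.

    I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with binary adjacency weights restricted to in-region pairs. Undefined
    (None) for a constant layer.
    """
    cells = grid.region_cells(region)
    xv = np.asarray(x, dtype=float)[cells]
    n = cells.size
    dev = xv - xv.mean()
    denom = float((dev**2).sum())
    if denom == 0:
        return None
    pairs = adjacency.neighbor_pairs(grid, cells)
    w = pairs.shape[0]
    if w == 0:
        return None
    num = float((dev[pairs[:, 0]] * dev[pairs[:, 1]]).sum())
    return (n / w) * num / denom


def region_habitat_clustering(
    habitat: HabitatRaster,
    region: str,
    adjacency: AdjacencySpec = AdjacencySpec(),
    presence_threshold: float = 0.0,
) -> Optional[float]:
    """Mean Moran's I over habitat presence layers.

    Presence of a habitat in a cell means its cover proportion exceeds
    ``presence_threshold``; layers with undefined I (habitat everywhere or
    nowhere) are skipped. None when no layer has a defined I.
    """
    values = []
    for k in range(len(habitat.class_ids)):
        layer = (habitat.proportions[:, k] > presence_threshold).astype(float)
        i_val = morans_i_layer(layer, habitat.grid, region, adjacency)
        if i_val is not None:
            values.append(i_val)
    if not values:
        return None
    return float(np.mean(values))


def climate_summary(
    climate: ClimateRaster, region: str
) -> dict[str, tuple[float, float]]:
    """(mean, sample SD) of every climate variable over a region's cells;
    SD of a single-cell region is 0."""
    cells = climate.grid.region_cells(region)
    if cells.size == 0:
        raise ValueError(f"region {region!r} has no cells")
    out = {}
    for name, layer in climate.variables.items():
        vals = np.asarray(layer, dtype=float)[cells]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(np.mean(vals)), sd)
    return out


def region_env_summary(
    habitat: HabitatRaster,
    climate: ClimateRaster,
    region: str,
    adjacency: AdjacencySpec = AdjacencySpec(),
    presence_threshold: float = 0.0,
    pair_budget: int = 200_000,
    seed: int = 0,
    bc_convention: str = "abundance",
) -> EnvSummary:
    cells = habitat.grid.region_cells(region)
    bc, est = region_bray_curtis(
        habitat, region, pair_budget=pair_budget, seed=seed,
        convention=bc_convention,
    )
    present = (habitat.proportions[cells] > presence_threshold).any(axis=0)
    return EnvSummary(
        region=region,
        area_cells=int(cells.size),
        n_habitats=int(present.sum()),
        bray_curtis=bc,
        bray_curtis_estimated=est,
        morans_i=region_habitat_clustering(
            habitat, region, adjacency, presence_threshold
        ),
        climate=climate_summary(climate, region),
    )


def env_summary_table(summaries: Sequence[EnvSummary]) -> pd.DataFrame:
    recs = []
    for s in summaries:
        rec = {
            "region": s.region,
            "area_cells": s.area_cells,
            "n_habitats": s.n_habitats,
            "bray_curtis": np.nan if s.bray_curtis is None else s.bray_curtis,
            "morans_i": np.nan if s.morans_i is None else s.morans_i,
        }
        for name, (mean, sd) in sorted(s.climate.items()):
            rec[f"{name}_mean"] = mean
            rec[f"{name}_sd"] = sd
        recs.append(rec)
    return pd.DataFrame(recs)


def _subset_r2(X: np.ndarray, y: np.ndarray, idx: tuple[int, ...]) -> float:
    if not idx:
        return 0.0
    design = sm.add_constant(X[:, list(idx)])
    model = sm.OLS(y, design).fit()
    return float(model.rsquared)


def commonality_analysis(
    X: pd.DataFrame, y: Sequence[float] | np.ndarray
) -> CommonalityResult:
    """Decompose the full-model R^2 into 2^p - 1 unique and common effects.

    The commonality coefficient of a predictor set S is
    ``-sum over T subset of S of (-1)^|T| R^2(T + complement(S))``; the
    coefficients sum to the full-model R^2 (asserted by tests to 1e-10).
    """
    names = list(X.columns)
    p = len(names)
    if p < 1 or p > 10:
        raise ValueError("need between 1 and 10 predictors")
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != Xv.shape[0]:
        raise ValueError("X and y lengths differ")
    if yv.shape[0] <= p + 1:
        raise ValueError("need more observations than predictors + 1")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(yv)), Xv])) < p + 1:
        raise ValueError(f"rank-deficient design over columns {names}")

    all_idx = tuple(range(p))
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, p + 1):
        for combo in itertools.combinations(all_idx, k):
            r2[frozenset(combo)] = _subset_r2(Xv, yv, combo)

    coefficients: dict[frozenset, float] = {}
    for k in range(1, p + 1):
        for combo in itertools.combinations(all_idx, k):
            s = frozenset(combo)
            comp = frozenset(all_idx) - s
            total = 0.0
            for t_size in range(len(combo) + 1):
                for t in itertools.combinations(combo, t_size):
                    total += (-1) ** len(t) * r2[frozenset(t) | comp]
            coefficients[frozenset(names[i] for i in s)] = -total

    subset_r2_named = {
        frozenset(names[i] for i in key): val for key, val in r2.items() if key
    }
    return CommonalityResult(
        predictors=tuple(names),
        subset_r2=subset_r2_named,
        coefficients=coefficients,
        full_r2=r2[frozenset(all_idx)],
    )


def select_predictors(
    X: pd.DataFrame,
    y: Sequence[float] | np.ndarray,
    n_select: int = 2,
    max_abs_corr: float = 0.7,
) -> list[str]:
    """Commonality-guided selection: rank predictors by unique effect and
    greedily keep those whose pairwise correlation with already-selected
    ones stays below ``max_abs_corr``."""
    ca = commonality_analysis(X, y)
    ranked = sorted(X.columns, key=lambda n: ca.unique_effect(n), reverse=True)
    corr = X.corr().abs()
    chosen: list[str] = []
    for name in ranked:
        if len(chosen) >= n_select:
            break
        if all(corr.loc[name, other] < max_abs_corr for other in chosen):
            chosen.append(name)
    return chosen


def fit_z_regression(
    X: pd.DataFrame, y: Sequence[float] | np.ndarray
) -> pd.DataFrame:
    """OLS (with intercept) of z-exponents on selected predictors.

    Returns one row per term with coefficient, SE, t, p, plus model-level
    R^2 and residual degrees of freedom repeated on each row.
    """
    yv = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError(f"collinear predictors among {list(X.columns)}")
    model = sm.OLS(yv, design).fit()
    terms = ["intercept"] + list(X.columns)
    return pd.DataFrame(
        {
            "term": terms,
            "coef": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
            "r2": model.rsquared,
            "r2_adj": model.rsquared_adj,
            "df_resid": int(model.df_resid),
        }
    )
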