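"""Build species-/network-area curves along aggregation paths, fit power
laws y = c * A**z, and regress network properties on species richness.

Curves are built incrementally: walking a path adds one cell's species at a
time, and only links touching newly arrived species need to be inserted, so
a full curve costs O(cells * pool) rather than re-inducing each prefix from
scratch. Equality with the direct induced-subgraph route is covered by
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .aggregation import AggregationPath
from .grid_io import Metaweb, RangeStack
from .metaweb_core import METRIC_COLUMNS

__all__ = [
    "NARCurve",
    "PowerFit",
    "RichnessRegression",
    "LEVEL_COLUMNS",
    "LOG_SCALE_PROPERTIES",
    "build_curve",
    "fit_power",
    "fit_region",
    "per_level_sar",
    "normalize_curve",
    "richness_regressions",
    "curves_to_table",
    "fits_to_table",
]

#: per-trophic-level species counts carried alongside the metrics
LEVEL_COLUMNS = ["n_basal", "n_intermediate", "n_top"]

#: properties regressed on log-log scale against richness (everything that
#: grows with web size; proportions and overlap stay on the raw scale)
LOG_SCALE_PROPERTIES = {
    "L",
    "links_per_species",
    "gen_mean",
    "gen_sd",
    "vul_mean",
    "vul_sd",
}

CURVE_COLUMNS = ["A"] + METRIC_COLUMNS + LEVEL_COLUMNS


@dataclass(frozen=True)
class NARCurve:
    """Metric values along the nested prefixes of one aggregation path."""

    region: str
    replicate: int
    table: pd.DataFrame  # columns CURVE_COLUMNS, A strictly increasing
    normalized: bool = False


@dataclass(frozen=True)
class PowerFit:
    property_name: str
    c: float
    z: float
    se_c: float
    se_z: float
    r2: float
    n_points: int
    converged: bool
    method: str  # "nls" or "loglog-fallback"


@dataclass(frozen=True)
class RichnessRegression:
    property_name: str
    slope: float
    intercept: float
    r2_adj: float
    n_points: int
    scale: str  # "loglog" or "raw"


def _sample_sd(values: list[int]) -> float:
    n = len(values)
    if n == 1:
        return 0.0
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def build_curve(
    metaweb: Metaweb,
    ranges: RangeStack,
    path: AggregationPath,
    thin: Optional[Sequence[int]] = None,
    replicate: int = 0,
) -> NARCurve:
    """Metrics of the induced web at each retained prefix of ``path``.

    At prefix length A the species set is the union of presences over the
    first A cells and the web is the metaweb restricted to that set
    (self-links dropped). ``thin`` selects which prefix lengths to retain
    (default: every A from 1 to the region size; the final A is always
    retained).
    """
    n_cells = len(path.order)
    retain = set(range(1, n_cells + 1)) if thin is None else set(int(a) for a in thin)
    retain.add(n_cells)

    prey = {s: set() for s in metaweb.species_ids}
    predators = {s: set() for s in metaweb.species_ids}
    for c, r in metaweb.links:
        if c != r:  # self-links never enter local webs
            prey[c].add(r)
            predators[r].add(c)

    sp_index = {s: i for i, s in enumerate(ranges.species_ids)}
    cell_species: dict[int, list[str]] = {}
    for cell in path.order:
        present_idx = np.flatnonzero(ranges.presence[:, cell])
        cell_species[cell] = [ranges.species_ids[i] for i in present_idx]

    present: set[str] = set()
    out_deg: dict[str, int] = {}
    in_deg: dict[str, int] = {}
    L = 0
    shared = 0  # links whose resource has >= 2 consumers

    def _bump_in(r: str) -> None:
        nonlocal shared
        in_deg[r] += 1
        if in_deg[r] == 2:
            shared += 2
        elif in_deg[r] > 2:
            shared += 1

    rows = []
    for a, cell in enumerate(path.order, start=1):
        for s in cell_species[cell]:
            if s in present or s not in sp_index or s not in prey:
                continue
            present.add(s)
            out_deg[s] = 0
            in_deg[s] = 0
            for r in prey[s]:
                if r in present:
                    L += 1
                    out_deg[s] += 1
                    _bump_in(r)
            for c in predators[s]:
                if c in present and c != s:
                    L += 1
                    out_deg[c] += 1
                    _bump_in(s)
        if a not in retain:
            continue
        rows.append({"A": a, **_metrics_from_degrees(present, out_deg, in_deg, L, shared)})

    table = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    return NARCurve(region=path.region, replicate=replicate, table=table)


def _metrics_from_degrees(
    present: set[str],
    out_deg: dict[str, int],
    in_deg: dict[str, int],
    L: int,
    shared: int,
) -> dict:
    S = len(present)
    if S == 0:
        row = {k: math.nan for k in METRIC_COLUMNS + LEVEL_COLUMNS}
        row["S"] = 0
        return row
    gen = [out_deg[s] for s in present if out_deg[s] > 0]
    vul = [in_deg[s] for s in present if in_deg[s] > 0]
    n_basal = sum(1 for s in present if out_deg[s] == 0)
    n_top = sum(1 for s in present if out_deg[s] > 0 and in_deg[s] == 0)
    n_inter = S - n_basal - n_top
    return {
        "S": S,
        "L": L,
        "links_per_species": L / S,
        "gen_mean": (sum(gen) / len(gen)) if gen else math.nan,
        "gen_sd": _sample_sd(gen) if gen else math.nan,
        "vul_mean": (sum(vul) / len(vul)) if vul else math.nan,
        "vul_sd": _sample_sd(vul) if vul else math.nan,
        "frac_basal": n_basal / S,
        "frac_intermediate": n_inter / S,
        "frac_top": n_top / S,
        "consumer_overlap": (shared / L) if L > 0 else math.nan,
        "modularity": math.nan,
        "n_basal": n_basal,
        "n_intermediate": n_inter,
        "n_top": n_top,
    }


def fit_power(
    points: Iterable[tuple[float, float]] | np.ndarray,
    property_name: str = "y",
) -> PowerFit:
    """Fit y = c * A**z by damped (Levenberg-Marquardt) least squares.

    Initial values come from OLS of log y on log A over the positive points;
    on non-convergence the log-log fit itself is returned, flagged
    ``loglog-fallback``. R^2 is computed on the raw scale.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (A, y) pairs")
    mask = np.isfinite(pts).all(axis=1)
    A, y = pts[mask, 0], pts[mask, 1]
    if A.size < 3:
        raise ValueError("need >= 3 finite points for a power fit")
    if np.any(A < 1):
        raise ValueError("areas must be >= 1")
    pos = y > 0
    if not pos.any():
        raise ValueError("all y <= 0: cannot fit a power law")

    logA, logy = np.log(A[pos]), np.log(y[pos])
    if np.ptp(logA) == 0:
        raise ValueError("need variation in A")
    slope, intercept = np.polyfit(logA, logy, 1)
    c0, z0 = math.exp(intercept), slope

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.power(A, p[1]) - y

    sol = least_squares(
        resid,
        x0=[c0, z0],
        method="lm",
        xtol=1e-8,
        ftol=1e-8,
        gtol=1e-8,
        max_nfev=1000 * 3,
    )
    sst = float(np.sum((y - y.mean()) ** 2))
    if sol.success and np.isfinite(sol.x).all():
        c, z = float(sol.x[0]), float(sol.x[1])
        sse = float(np.sum(sol.fun**2))
        se_c, se_z = _param_se(sol.jac, sse, A.size)
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        return PowerFit(
            property_name=property_name,
            c=c,
            z=z,
            se_c=se_c,
            se_z=se_z,
            r2=max(0.0, min(1.0, r2)),
            n_points=int(A.size),
            converged=True,
            method="nls",
        )
    # log-log fallback
    pred = c0 * np.power(A, z0)
    sse = float(np.sum((pred - y) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return PowerFit(
        property_name=property_name,
        c=c0,
        z=z0,
        se_c=math.nan,
        se_z=math.nan,
        r2=max(0.0, min(1.0, r2)),
        n_points=int(A.size),
        converged=False,
        method="loglog-fallback",
    )


def _param_se(jac: np.ndarray, sse: float, n: int) -> tuple[float, float]:
    dof = max(n - 2, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
        return float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return math.nan, math.nan


def _pool_points(curves: Sequence[NARCurve], prop: str) -> np.ndarray:
    if not curves:
        raise ValueError("need at least one curve")
    cols = []
    for cur in curves:
        if prop not in cur.table.columns:
            raise ValueError(f"property {prop!r} absent from curve table")
        cols.append(cur.table[["A", prop]].to_numpy(dtype=float))
    return np.vstack(cols)


def fit_region(
    curves: Sequence[NARCurve], property_name: str, mode: str = "pooled"
) -> PowerFit | list[PowerFit]:
    """Power fit of one property across replicates.

    ``pooled`` (default) stacks the (A, y) points of all replicates into a
    single fit; ``per-replicate`` returns one fit per curve for sensitivity
    analysis.
    """
    if mode == "pooled":
        return fit_power(_pool_points(curves, property_name), property_name)
    if mode == "per-replicate":
        return [
            fit_power(
                c.table[["A", property_name]].to_numpy(dtype=float), property_name
            )
            for c in curves
        ]
    raise ValueError(f"unknown mode {mode!r}")


def per_level_sar(curves: Sequence[NARCurve], level: str) -> PowerFit:
    """SAR restricted to one trophic level (species counts, not fractions)."""
    col = f"n_{level}"
    if col not in LEVEL_COLUMNS:
        raise ValueError(f"level must be one of basal/intermediate/top, got {level!r}")
    pts = _pool_points(curves, col)
    if not (pts[:, 1] > 0).any():
        raise ValueError(f"trophic level {level!r} is never populated in these curves")
    return fit_power(pts, property_name=f"S_{level}")


def normalize_curve(curve: NARCurve) -> NARCurve:
    """Divide the extensive properties by S at the same A (guarded against
    double application)."""
    if curve.normalized:
        raise ValueError("curve is already normalised")
    table = curve.table.copy()
    S = table["S"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in sorted(LOG_SCALE_PROPERTIES):
            table[col] = np.where(S > 0, table[col] / S, np.nan)
    return NARCurve(
        region=curve.region,
        replicate=curve.replicate,
        table=table,
        normalized=True,
    )


def richness_regressions(
    curves: Sequence[NARCurve], property_name: str
) -> RichnessRegression:
    """OLS of one property against species richness, pooled over curves.

    Size-like properties are regressed in log-log space; proportions and
    overlap on the raw scale. Adjusted R^2 is reported.
    """
    frames = [c.table[["S", property_name]] for c in curves]
    data = pd.concat(frames, ignore_index=True).dropna()
    data = data[data["S"] > 0]
    if data["S"].nunique() < 3:
        raise ValueError("need >= 3 distinct S values")
    if data["S"].nunique() == 1:
        raise ValueError("zero variance in S")
    log_scale = property_name in LOG_SCALE_PROPERTIES
    if log_scale:
        data = data[data[property_name] > 0]
        x = np.log(data["S"].to_numpy(dtype=float))
        y = np.log(data[property_name].to_numpy(dtype=float))
    else:
        x = data["S"].to_numpy(dtype=float)
        y = data[property_name].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_adj = float(model.rsquared_adj)  # y may be exactly constant
    return RichnessRegression(
        property_name=property_name,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2_adj=r2_adj,
        n_points=int(model.nobs),
        scale="loglog" if log_scale else "raw",
    )


def curves_to_table(curves: Sequence[NARCurve]) -> pd.DataFrame:
    frames = []
    for k, cur in enumerate(curves):
        t = cur.table.copy()
        t.insert(0, "replicate", k)
        t.insert(0, "region", cur.region)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def fits_to_table(fits: Sequence[tuple[str, PowerFit]]) -> pd.DataFrame:
    recs = [
        {
            "region": region,
            "property": f.property_name,
            "c": f.c,
            "z": f.z,
            "se_c": f.se_c,
            "se_z": f.se_z,
            "r2": f.r2,
            "n_points": f.n_points,
            "method": f.method,
        }
        for region, f in fits
    ]
    return pd.DataFrame(
        recs,
        columns=[
            "region",
            "property",
            "c",
            "z",
            "se_c",
            "se_z",
            "r2",
            "n_points",
            "method",
        ],
    )
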