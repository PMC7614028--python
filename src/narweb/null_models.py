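"""Richness-matched null models.

Model 1 ("subsampled"): at each step of an observed curve, the null
assemblage holds the same number of species, drawn uniformly from the
metaweb pool and nested across steps; links are induced from the metaweb.

Model 2 ("random"): species are drawn the same way, but the observed link
count at each step is scattered uniformly at random over ordered pairs of
distinct selected species (no self-links, no duplicates), discarding any
trophic structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_io import Metaweb
from .metaweb_core import LocalWeb, compute_metrics
from .nar_pipeline import CURVE_COLUMNS, NARCurve, _metrics_from_degrees

__all__ = [
    "NullCurve",
    "null_subsampled_curve",
    "null_random_curve",
    "random_web",
    "z_ratio_table",
]


@dataclass(frozen=True)
class NullCurve:
    model: str  # "subsampled" or "random"
    region: str
    replicate: int
    table: pd.DataFrame  # same columns as NARCurve tables


def _observed_richness(observed: NARCurve) -> tuple[np.ndarray, np.ndarray]:
    A = observed.table["A"].to_numpy(dtype=int)
    S = observed.table["S"].to_numpy(dtype=int)
    if np.any(np.diff(S) < 0):
        raise ValueError("observed S must be non-decreasing along the curve")
    return A, S


def null_subsampled_curve(
    metaweb: Metaweb,
    observed: NARCurve,
    seed: int,
    nested: bool = True,
) -> NullCurve:
    """Null model 1: same richness trajectory, species drawn uniformly from
    the pool, links induced from the metaweb.

    ``nested`` keeps species sets nested across steps (default); with
    ``nested=False`` each step re-draws its species independently.
    """
    A, S = _observed_richness(observed)
    pool = metaweb.species_ids
    if S.max(initial=0) > len(pool):
        raise ValueError("observed richness exceeds the metaweb pool")
    rng = np.random.default_rng([int(seed), 131])

    prey = {s: set() for s in pool}
    predators = {s: set() for s in pool}
    for c, r in metaweb.links:
        if c != r:
            prey[c].add(r)
            predators[r].add(c)

    rows = []
    if nested:
        perm = list(rng.permutation(pool))
        present: set[str] = set()
        out_deg: dict[str, int] = {}
        in_deg: dict[str, int] = {}
        L = 0
        shared = 0

        def bump_in(r: str) -> None:
            nonlocal shared
            in_deg[r] += 1
            if in_deg[r] == 2:
                shared += 2
            elif in_deg[r] > 2:
                shared += 1

        cursor = 0
        for a, s_t in zip(A, S):
            while cursor < s_t:
                sp = perm[cursor]
                cursor += 1
                present.add(sp)
                out_deg[sp] = 0
                in_deg[sp] = 0
                for r in prey[sp]:
                    if r in present:
                        L += 1
                        out_deg[sp] += 1
                        bump_in(r)
                for c in predators[sp]:
                    if c in present and c != sp:
                        L += 1
                        out_deg[c] += 1
                        bump_in(sp)
            rows.append(
                {"A": int(a), **_metrics_from_degrees(present, out_deg, in_deg, L, shared)}
            )
    else:
        from .metaweb_core import induced_web

        for a, s_t in zip(A, S):
            subset = rng.choice(pool, size=int(s_t), replace=False)
            web = induced_web(metaweb, subset)
            row = compute_metrics(web).as_row()
            from .metaweb_core import trophic_classes

            if web.S:
                b, i, t = trophic_classes(web)
                row.update(n_basal=len(b), n_intermediate=len(i), n_top=len(t))
            rows.append({"A": int(a), **row})

    table = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    return NullCurve(
        model="subsampled",
        region=observed.region,
        replicate=observed.replicate,
        table=table,
    )


def random_web(species: Sequence[str], n_links: int, rng: np.random.Generator) -> LocalWeb:
    """Uniform simple directed graph: ``n_links`` links over ordered pairs of
    distinct species, without duplicates or self-links."""
    S = len(species)
    capacity = S * (S - 1)
    if n_links > capacity:
        raise ValueError(f"{n_links} links exceed capacity {capacity} for S={S}")
    if n_links == 0 or S < 2:
        return LocalWeb(species=frozenset(species), links=frozenset())
    pair_idx = rng.choice(capacity, size=int(n_links), replace=False)
    links = set()
    for p in pair_idx:
        i, j = divmod(int(p), S - 1)
        if j >= i:
            j += 1  # skip the diagonal
        links.add((species[i], species[j]))
    return LocalWeb(species=frozenset(species), links=frozenset(links))


def null_random_curve(
    metaweb: Metaweb,
    observed: NARCurve,
    seed: int,
) -> NullCurve:
    """Null model 2: same richness and link-count trajectories, links placed
    uniformly at random at every step."""
    A, S = _observed_richness(observed)
    L_obs = observed.table["L"].to_numpy()
    pool = metaweb.species_ids
    if S.max(initial=0) > len(pool):
        raise ValueError("observed richness exceeds the metaweb pool")
    rng = np.random.default_rng([int(seed), 137])
    perm = list(rng.permutation(pool))

    from .metaweb_core import trophic_classes

    rows = []
    for a, s_t, l_t in zip(A, S, L_obs):
        if s_t == 0:
            row = compute_metrics(LocalWeb(frozenset(), frozenset())).as_row()
            rows.append({"A": int(a), **row})
            continue
        l_t = int(l_t) if np.isfinite(l_t) else 0
        if l_t > s_t * (s_t - 1):
            raise ValueError(
                f"observed L={l_t} exceeds capacity for S={s_t} at A={a}"
            )
        web = random_web(perm[: int(s_t)], l_t, rng)
        row = compute_metrics(web).as_row()
        b, i, t = trophic_classes(web)
        row.update(n_basal=len(b), n_intermediate=len(i), n_top=len(t))
        rows.append({"A": int(a), **row})
    table = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    return NullCurve(
        model="random",
        region=observed.region,
        replicate=observed.replicate,
        table=table,
    )


def z_ratio_table(
    null_fits: pd.DataFrame, observed_fits: pd.DataFrame
) -> pd.DataFrame:
    """Per-(region, property) ratio z_null / z_observed.

    Keys present in only one table are kept with a diagnostic note instead of
    being dropped; a zero observed exponent yields a missing ratio.
    """
    for df, name in ((null_fits, "null"), (observed_fits, "observed")):
        for col in ("region", "property", "z"):
            if col not in df.columns:
                raise ValueError(f"{name} fits table lacks column {col!r}")
    merged = pd.merge(
        null_fits[["region", "property", "z"]].rename(columns={"z": "z_null"}),
        observed_fits[["region", "property", "z"]].rename(columns={"z": "z_observed"}),
        on=["region", "property"],
        how="outer",
        indicator=True,
    )
    ratio = merged["z_null"] / merged["z_observed"].replace(0.0, np.nan)
    merged["z_ratio"] = ratio.where(merged["_merge"] == "both")
    merged["note"] = merged["_merge"].map(
        {
            "both": "",
            "left_only": "missing in observed fits",
            "right_only": "missing in null fits",
        }
    ).astype(str)
    merged.loc[
        (merged["_merge"] == "both") & (merged["z_observed"] == 0.0), "note"
    ] = "observed z is zero"
    return merged.drop(columns="_merge").sort_values(
        ["region", "property"], ignore_index=True
    )
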