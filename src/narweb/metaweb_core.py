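"""Local food-web induction from a metaweb and the network properties used
throughout the pipeline.

Conventions
-----------
* A link ``(c, r)`` means consumer ``c`` eats resource ``r``.
* Self-links are accepted in a metaweb but dropped when inducing local webs.
* Basal species have no prey within the web; isolated species count as basal.
* Generality statistics are taken over species with at least one prey,
  vulnerability statistics over species with at least one predator; standard
  deviations use the n-1 sample convention, with 0 for a single member.
* Consumer overlap defaults to the fraction of links whose resource is eaten
  by at least two distinct consumers; a mean pairwise Jaccard variant of diet
  similarity is available via ``overlap="jaccard"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .grid_io import Metaweb

__all__ = [
    "LocalWeb",
    "WebMetrics",
    "METRIC_COLUMNS",
    "induced_web",
    "trophic_classes",
    "degree_stats",
    "consumer_overlap",
    "compute_metrics",
    "default_modularity",
]

#: column order for serialised metrics rows
METRIC_COLUMNS = [
    "S",
    "L",
    "links_per_species",
    "gen_mean",
    "gen_sd",
    "vul_mean",
    "vul_sd",
    "frac_basal",
    "frac_intermediate",
    "frac_top",
    "consumer_overlap",
    "modularity",
]


@dataclass(frozen=True)
class LocalWeb:
    """A species subset plus the links among them (no self-links when
    induced)."""

    species: frozenset[str]
    links: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for c, r in self.links:
            if c not in self.species or r not in self.species:
                raise ValueError(f"link ({c!r}, {r!r}) has endpoint outside subset")

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def L(self) -> int:
        return len(self.links)

    def out_degrees(self) -> dict[str, int]:
        """Prey counts (generality) per species."""
        deg = dict.fromkeys(self.species, 0)
        for c, _ in self.links:
            deg[c] += 1
        return deg

    def in_degrees(self) -> dict[str, int]:
        """Predator counts (vulnerability) per species."""
        deg = dict.fromkeys(self.species, 0)
        for _, r in self.links:
            deg[r] += 1
        return deg


@dataclass(frozen=True)
class WebMetrics:
    S: int
    L: Optional[int] = None
    links_per_species: Optional[float] = None
    gen_mean: Optional[float] = None
    gen_sd: Optional[float] = None
    vul_mean: Optional[float] = None
    vul_sd: Optional[float] = None
    frac_basal: Optional[float] = None
    frac_intermediate: Optional[float] = None
    frac_top: Optional[float] = None
    consumer_overlap: Optional[float] = None
    modularity: Optional[float] = None

    def as_row(self) -> dict:
        return {
            k: (math.nan if getattr(self, k) is None else getattr(self, k))
            for k in METRIC_COLUMNS
        }


def induced_web(metaweb: Metaweb, subset: Iterable[str]) -> LocalWeb:
    """Restrict the metaweb to ``subset``: links are exactly the metaweb
    links with both endpoints in the subset, self-links dropped."""
    sub = frozenset(subset)
    unknown = sub - set(metaweb.species_ids)
    if unknown:
        raise ValueError(f"unknown species in subset: {sorted(unknown)[:5]}")
    links = frozenset(
        (c, r) for c, r in metaweb.links if c != r and c in sub and r in sub
    )
    return LocalWeb(species=sub, links=links)


def trophic_classes(
    web: LocalWeb, inherited_basal: Optional[frozenset[str]] = None
) -> tuple[set[str], set[str], set[str]]:
    """Partition species into (basal, intermediate, top).

    Topological default: basal = no prey within the web (isolated species
    included), top = has prey but no predators, intermediate = both prey and
    predators. With ``inherited_basal``, species in that set are frozen basal
    regardless of local links; remaining species are split by local predator
    status.
    """
    if web.S == 0:
        raise ValueError("empty web has no trophic classes")
    out_deg = web.out_degrees()
    in_deg = web.in_degrees()
    basal: set[str] = set()
    intermediate: set[str] = set()
    top: set[str] = set()
    for sp in web.species:
        if inherited_basal is not None:
            is_basal = sp in inherited_basal
        else:
            is_basal = out_deg[sp] == 0
        if is_basal:
            basal.add(sp)
        elif in_deg[sp] > 0:
            intermediate.add(sp)
        else:
            top.add(sp)
    return basal, intermediate, top


def _mean_sd(values: list[int]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def degree_stats(
    web: LocalWeb,
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """(gen_mean, gen_sd, vul_mean, vul_sd); None where the base set is
    empty."""
    gen = [d for d in web.out_degrees().values() if d > 0]
    vul = [d for d in web.in_degrees().values() if d > 0]
    gen_mean = gen_sd = vul_mean = vul_sd = None
    if gen:
        gen_mean, gen_sd = _mean_sd(gen)
    if vul:
        vul_mean, vul_sd = _mean_sd(vul)
    return gen_mean, gen_sd, vul_mean, vul_sd


def consumer_overlap(web: LocalWeb, definition: str = "shared") -> Optional[float]:
    """Diet overlap among consumers.

    ``shared`` (default): fraction of links whose resource has >= 2 distinct
    consumers. ``jaccard``: mean pairwise Jaccard similarity of consumer
    diets.
    """
    if web.L == 0:
        return None
    if definition == "shared":
        in_deg = web.in_degrees()
        shared = sum(1 for _, r in web.links if in_deg[r] >= 2)
        return shared / web.L
    if definition == "jaccard":
        diets: dict[str, set[str]] = {}
        for c, r in web.links:
            diets.setdefault(c, set()).add(r)
        consumers = sorted(diets)
        if len(consumers) < 2:
            return 0.0
        total = 0.0
        n_pairs = 0
        for i, a in enumerate(consumers):
            for b in consumers[i + 1 :]:
                inter = len(diets[a] & diets[b])
                union = len(diets[a] | diets[b])
                total += inter / union
                n_pairs += 1
        return total / n_pairs
    raise ValueError(f"unknown overlap definition {definition!r}")


def default_modularity(web: LocalWeb) -> Optional[float]:
    """Greedy undirected modularity (networkx); a generic score, not the
    formulation of any particular study."""
    if web.L == 0:
        return None
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(web.species)
    g.add_edges_from(web.links)
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    return nx.algorithms.community.modularity(g, comms)


def compute_metrics(
    web: LocalWeb,
    overlap: str = "shared",
    inherited_basal: Optional[frozenset[str]] = None,
    modularity_fn: Optional[Callable[[LocalWeb], Optional[float]]] = None,
) -> WebMetrics:
    """All metrics of one web; fields left None where undefined (S = 0, or
    no links for the degree statistics)."""
    if web.S == 0:
        return WebMetrics(S=0)
    basal, inter, top = trophic_classes(web, inherited_basal=inherited_basal)
    gen_mean, gen_sd, vul_mean, vul_sd = degree_stats(web)
    return WebMetrics(
        S=web.S,
        L=web.L,
        links_per_species=web.L / web.S,
        gen_mean=gen_mean,
        gen_sd=gen_sd,
        vul_mean=vul_mean,
        vul_sd=vul_sd,
        frac_basal=len(basal) / web.S,
        frac_intermediate=len(inter) / web.S,
        frac_top=len(top) / web.S,
        consumer_overlap=consumer_overlap(web, definition=overlap),
        modularity=modularity_fn(web) if modularity_fn is not None else None,
    )
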