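"""Dense-module extraction, hub detection and hypergeometric enrichment.

Functional labels are transferred from protein-coding genes to eRNAs through
network neighbourhoods: tightly connected modules are pulled out of the
interactome with a greedy seed-and-expand clustering (the unweighted variant
of the SPICi algorithm), hubs are selected by degree, and the PCGs connected
to an eRNA are tested for gene-set over-representation with the upper-tail
hypergeometric test.

Module extraction operates on the unweighted simple graph induced by the edge
table: repeated edges between the same node pair (e.g. a co-expression and a
loop edge) count once, and edge weights are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .networks import Network, adjust_bh

logger = logging.getLogger("ernakit")

__all__ = [
    "Module",
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "extract_modules",
    "extract_hubs",
    "hypergeom_enrich",
    "annotate_erna",
    "ErnaAnnotation",
]


@dataclass(frozen=True)
class Module:
    """A dense cluster of network nodes.

    density = 2 * (edges within) / (|members| * (|members| - 1)).
    """

    member_ids: frozenset[str]
    density: float
    contains_ernas: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a module needs at least 2 members")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if not self.contains_ernas <= self.member_ids:
            raise ValueError("contains_ernas must be a subset of member_ids")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a finite universe (sets restricted to the universe)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        restricted = {
            name: frozenset(genes) & self.universe for name, genes in self.sets.items()
        }
        object.__setattr__(self, "sets", restricted)
        object.__setattr__(self, "universe", frozenset(self.universe))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # |query ∩ set|
    n: int  # |query|
    K: int  # |set|
    N: int  # |universe|
    p: float
    q: float
    genes: tuple[str, ...]


def read_gmt(
    path: str | Path, universe: set[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated gene ids).

    The universe defaults to the union of all sets in the file.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, frozenset(universe))


# ---------------------------------------------------------------------------
# greedy dense-module extraction (SPICi-style, unweighted)
# ---------------------------------------------------------------------------

def _density(g: nx.Graph, members: set[str]) -> float:
    k = len(members)
    if k < 2:
        return 1.0
    within = g.subgraph(members).number_of_edges()
    return 2.0 * within / (k * (k - 1))


def extract_modules(
    net: Network,
    density_threshold: float = 0.5,
    support_threshold: float = 0.5,
) -> list[Module]:
    """Greedy seed-and-expand clustering of the unweighted interaction graph.

    Repeatedly seed at the unclustered node of highest degree (ties broken by
    lexicographic id), pair it with its best unclustered neighbour (unweighted:
    lexicographic), then grow by the candidate with the highest *support* (the
    fraction of current members it connects to), accepting while support >=
    ``support_threshold`` and the resulting density stays >=
    ``density_threshold``.  Emitted clusters are removed from the graph;
    singletons are discarded.  Output modules are pairwise disjoint.
    """
    for name, value in (("density", density_threshold), ("support", support_threshold)):
        if not 0.0 < value <= 1.0:
            raise ValueError(f"{name} threshold must lie in (0, 1], got {value}")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(tuple(sorted(pair)) for pair in net.edge_pairs() if len(pair) == 2)
    erna_ids = {n for n, role in net.nodes.items() if role == "erna"}

    modules: list[Module] = []
    work = g.copy()
    while work.number_of_edges() > 0:
        seed = min(work.nodes, key=lambda n: (-work.degree(n), n))
        partner = min(work.neighbors(seed))
        cluster = {seed, partner}
        while True:
            candidates = (
                set().union(*(set(work.neighbors(m)) for m in cluster)) - cluster
            )
            if not candidates:
                break
            support = {
                c: sum(1 for m in cluster if work.has_edge(c, m)) / len(cluster)
                for c in candidates
            }
            best = min(candidates, key=lambda c: (-support[c], c))
            if support[best] < support_threshold:
                break
            if _density(work, cluster | {best}) < density_threshold:
                break
            cluster.add(best)
        modules.append(
            Module(
                frozenset(cluster),
                _density(work, cluster),
                frozenset(cluster & erna_ids),
            )
        )
        work.remove_nodes_from(cluster)
    return modules


def extract_hubs(
    net: Network, top_fraction: float = 0.05, min_degree: int = 5
) -> list[str]:
    """Highest-degree nodes: degree >= max(min_degree, (1 - top_fraction) quantile).

    Returned sorted by degree descending, ties by id.  The degree quantile is
    taken over all network nodes (including isolated ones).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    deg = net.degrees()
    if not deg:
        return []
    cutoff = max(
        float(min_degree), float(np.quantile(list(deg.values()), 1.0 - top_fraction))
    )
    hubs = [n for n, d in deg.items() if d >= cutoff]
    return sorted(hubs, key=lambda n: (-deg[n], n))


# ---------------------------------------------------------------------------
# hypergeometric gene-set enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    query: set[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of the query in every set.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size, K the
    set size, n the query size and k the overlap.  Query ids outside the
    universe are dropped with a warning; q is Benjamini-Hochberg across the
    sets of the collection.  Results sorted by (p, set name).
    """
    dropped = set(query) - collection.universe
    if dropped:
        logger.warning(
            "%d query ids outside the universe dropped: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:5]),
        )
    query_u = set(query) & collection.universe
    N = len(collection.universe)
    n = len(query_u)
    names = sorted(collection.sets)
    ps = []
    partial = []
    for name in names:
        genes = collection.sets[name]
        K = len(genes)
        overlap = sorted(query_u & genes)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        ps.append(min(p, 1.0))
        partial.append((name, k, K, overlap))
    qs = adjust_bh(ps) if ps else np.array([])
    results = [
        EnrichmentResult(name, k, n, K, N, p, float(q), tuple(overlap))
        for (name, k, K, overlap), p, q in zip(partial, ps, qs)
    ]
    return sorted(results, key=lambda r: (r.p, r.set_name))


@dataclass
class ErnaAnnotation:
    """The three enrichment views used to annotate one eRNA."""

    erna_id: str
    neighbor_query: set[str]
    neighbor_enrichment: list[EnrichmentResult]
    module_queries: list[tuple[Module, set[str]]]
    module_enrichments: list[list[EnrichmentResult]]
    hub_query: set[str]
    hub_enrichment: list[EnrichmentResult]


def annotate_erna(
    erna_id: str,
    net: Network,
    modules: list[Module],
    collection: GeneSetCollection,
    hub_top_fraction: float = 0.05,
    hub_min_degree: int = 5,
) -> ErnaAnnotation:
    """Annotate one eRNA by the functions of the PCGs around it.

    Three queries are enriched against the collection: (i) all PCG neighbours
    of the eRNA, (ii) the PCG members of each module containing the eRNA, and
    (iii) the PCG hubs adjacent to the eRNA.
    """
    if erna_id not in net.nodes:
        raise KeyError(f"{erna_id!r} is not a node of the network")

    def pcgs(ids: set[str]) -> set[str]:
        return {n for n in ids if net.nodes.get(n) == "pcg"}

    neighbors = net.neighbors(erna_id)
    neighbor_query = pcgs(neighbors)
    if not neighbor_query:
        logger.warning("eRNA %s has no PCG neighbours in the network", erna_id)

    module_queries = [
        (m, pcgs(set(m.member_ids))) for m in modules if erna_id in m.member_ids
    ]
    hubs = set(extract_hubs(net, hub_top_fraction, hub_min_degree))
    hub_query = pcgs(hubs & neighbors)

    return ErnaAnnotation(
        erna_id=erna_id,
        neighbor_query=neighbor_query,
        neighbor_enrichment=hypergeom_enrich(neighbor_query, collection),
        module_queries=module_queries,
        module_enrichments=[hypergeom_enrich(q, collection) for _, q in module_queries],
        hub_query=hub_query,
        hub_enrichment=hypergeom_enrich(hub_query, collection),
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results to a DataFrame (set, k, n, K, N, p, q, genes)."""
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "genes": ",".join(r.genes),
            }
            for r in results
        ],
        columns=["set", "k", "n", "K", "N", "p", "q", "genes"],
    )


def module_table(modules: list[Module]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": f"M{i + 1}",
                "size": len(m.member_ids),
                "density": m.density,
                "ernas": ",".join(sorted(m.contains_ernas)),
                "members": ",".join(sorted(m.member_ids)),
            }
            for i, m in enumerate(modules)
        ],
        columns=["module", "size", "density", "ernas", "members"],
    )
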