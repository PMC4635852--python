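"""Gene-set over-representation and interaction-network construction.

Over-representation uses the hypergeometric upper tail against a stated
gene universe, with BH q-values over all tested sets but reporting gated
on the classical p < 0.01 / minimum-two-gene-overlap rule.  Enriched sets
become nodes of a pathway-overlap graph whose edges require a minimum
shared-gene fraction (default 30%).  Query gene lists also induce modules
from interaction tables: PPI edges need both endpoints in the list, while
regulatory and drug-target edges anchor on a target in the list and
attach the outside regulator or drug as a satellite node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .diffexpr import GenePartition, bh_fdr
from .io_formats import GeneSetCollection, InteractionTable

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "hypergeom_pvalue",
    "overrepresentation",
    "pathway_overlap_network",
    "induce_module",
    "run_three_way",
    "ThreeWayResult",
]


def hypergeom_pvalue(n_universe: int, n_set: int, n_input: int, n_overlap: int
                     ) -> float:
    """Upper-tail hypergeometric probability P[X >= n_overlap] for the
    overlap between a gene set of size *n_set* and an input list of size
    *n_input* drawn from *n_universe* genes."""
    if not (0 <= n_set <= n_universe and 0 <= n_input <= n_universe):
        raise ValueError("set and input sizes must lie within the universe")
    if not 0 <= n_overlap <= min(n_set, n_input):
        raise ValueError(
            f"overlap {n_overlap} inconsistent with set {n_set} / input {n_input}")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set, n_input))


@dataclass(frozen=True)
class EnrichmentConfig:
    """Reporting thresholds for over-representation analysis."""

    min_overlap: int = 2     # minimum input genes in a reported set
    p_cutoff: float = 0.01   # hypergeometric p gate for reported sets
    edge_min: float = 0.30   # minimum overlap fraction for pathway edges
    overlap_basis: str = "input_members"  # or "all_members"
    confidence_min: float = 0.9  # "high-confidence" interaction floor


@dataclass
class EnrichmentResult:
    """Hypergeometric results for every tested set, plus the reported hits.

    ``table`` holds all tested sets (q-values computed across all of
    them); ``hits`` is the subset passing the overlap and p gates, sorted
    ascending by p.
    """

    table: pd.DataFrame = field(repr=False)
    min_overlap: int = 2
    p_cutoff: float = 0.01

    @property
    def hits(self) -> pd.DataFrame:
        mask = (self.table["n_overlap"] >= self.min_overlap) & \
               (self.table["p"] < self.p_cutoff)
        return self.table[mask]

    @property
    def hit_ids(self) -> list[str]:
        return list(self.hits.index)


def overrepresentation(input_genes, collection: GeneSetCollection, universe,
                       min_overlap: int = 2, p_cutoff: float = 0.01
                       ) -> EnrichmentResult:
    """Hypergeometric over-representation of *input_genes* in every set of
    *collection*, against *universe*.

    Set members outside the universe are ignored (they could never have
    been in the input).  q-values are BH-corrected across all tested sets;
    the reported hits additionally require at least *min_overlap* input
    genes and p < *p_cutoff*.
    """
    universe = set(universe)
    input_set = set(input_genes)
    if not universe:
        raise ValueError("empty universe")
    if not input_set:
        raise ValueError("empty input gene list")
    stray = input_set - universe
    if stray:
        raise ValueError(
            f"{len(stray)} input genes outside the universe, e.g. {sorted(stray)[:3]}")
    rows = []
    overlaps: dict[str, list[str]] = {}
    for s in collection:
        members = s.members & universe
        overlap = sorted(members & input_set)
        overlaps[s.set_id] = overlap
        p = hypergeom_pvalue(len(universe), len(members), len(input_set),
                             len(overlap)) if members else 1.0
        rows.append((s.set_id, s.description, len(universe), len(members),
                     len(input_set), len(overlap), p))
    table = pd.DataFrame(
        rows, columns=["set_id", "description", "n_universe", "n_set",
                       "n_input", "n_overlap", "p"],
    ).set_index("set_id")
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table["overlap_genes"] = [overlaps[i] for i in table.index]
    table = table.sort_values(["p", "set_id"], kind="stable")
    return EnrichmentResult(table, min_overlap=min_overlap, p_cutoff=p_cutoff)


def pathway_overlap_network(result: EnrichmentResult,
                            collection: GeneSetCollection,
                            edge_min: float = 0.30,
                            overlap_basis: str = "input_members") -> nx.Graph:
    """Graph over the enriched sets; an undirected edge joins two sets
    whose shared-gene fraction reaches *edge_min*.

    The fraction is |shared| / min(|genes_i|, |genes_j|) computed either on
    the input genes falling in each set (``input_members``, how pathway
    graphs are usually drawn from a query list) or on full set memberships
    (``all_members``).
    """
    if overlap_basis not in ("input_members", "all_members"):
        raise ValueError(f"unknown overlap_basis {overlap_basis!r}")
    hits = result.hits
    genes_of: dict[str, set[str]] = {}
    for set_id in hits.index:
        if overlap_basis == "input_members":
            genes_of[set_id] = set(hits.loc[set_id, "overlap_genes"])
        else:
            genes_of[set_id] = set(collection[set_id].members)
    graph = nx.Graph()
    for set_id in hits.index:
        graph.add_node(set_id, type="pathway",
                       p=float(hits.loc[set_id, "p"]),
                       q=float(hits.loc[set_id, "q"]),
                       n_overlap=int(hits.loc[set_id, "n_overlap"]))
    ids = list(hits.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = genes_of[ids[i]], genes_of[ids[j]]
            smaller = min(len(a), len(b))
            if smaller == 0:
                continue
            fraction = len(a & b) / smaller
            if fraction >= edge_min:
                graph.add_edge(ids[i], ids[j], overlap_fraction=fraction)
    return graph


def induce_module(input_genes, interactions: InteractionTable, kind: str,
                  confidence_min: float = 0.9) -> nx.DiGraph:
    """Module induced by *input_genes* from one interaction kind.

    Edges below *confidence_min* are dropped first ("high-confidence"
    interactions only).  For ``ppi``, an edge survives only when both
    endpoints are input genes.  For ``regulatory`` and ``drug_target``,
    an edge survives when its target is an input gene; the outside
    regulator or drug is attached as a satellite node.  Node attributes:
    ``type`` (gene/tf/drug), ``in_input``, and the edge role when present.
    """
    input_set = set(input_genes)
    edges = [e for e in interactions.of_kind(kind)
             if e.confidence >= confidence_min]
    graph = nx.DiGraph()
    attached_type = {"regulatory": "tf", "drug_target": "drug"}.get(kind)
    for e in edges:
        if kind == "ppi":
            if e.source in input_set and e.target in input_set:
                for node in (e.source, e.target):
                    graph.add_node(node, type="gene", in_input=True)
                graph.add_edge(e.source, e.target, kind=kind,
                               confidence=e.confidence)
        else:
            if e.target in input_set:
                graph.add_node(e.target, type="gene", in_input=True)
                if e.source not in graph:
                    graph.add_node(e.source, type=attached_type,
                                   in_input=e.source in input_set)
                graph.add_edge(e.source, e.target, kind=kind,
                               confidence=e.confidence,
                               **({"role": e.role} if e.role else {}))
    return graph


@dataclass
class ThreeWayResult:
    """Enrichment, pathway graph, and induced modules for one gene list."""

    name: str
    genes: list[str]
    enrichment: EnrichmentResult | None
    pathway_graph: nx.Graph | None
    modules: dict[str, nx.DiGraph]
    warning: str | None = None


def run_three_way(partition: GenePartition, collection: GeneSetCollection,
                  interactions: dict[str, InteractionTable], universe,
                  config: EnrichmentConfig | None = None
                  ) -> dict[str, ThreeWayResult]:
    """Run enrichment + networks independently for the core, unique_a, and
    unique_b gene lists of a :class:`GenePartition`.

    An empty gene list yields an empty result with a warning rather than
    an error.  *interactions* maps kind -> table for the kinds available.
    """
    config = config or EnrichmentConfig()
    out: dict[str, ThreeWayResult] = {}
    for name, genes in (("core", partition.core),
                        ("unique_a", partition.unique_a),
                        ("unique_b", partition.unique_b)):
        genes = sorted(genes)
        if not genes:
            out[name] = ThreeWayResult(name, [], None, None, {},
                                       warning="empty gene list")
            continue
        enr = overrepresentation(genes, collection, universe,
                                 min_overlap=config.min_overlap,
                                 p_cutoff=config.p_cutoff)
        graph = pathway_overlap_network(enr, collection,
                                        edge_min=config.edge_min,
                                        overlap_basis=config.overlap_basis)
        modules = {
            kind: induce_module(genes, table, kind,
                                confidence_min=config.confidence_min)
            for kind, table in interactions.items()
        }
        out[name] = ThreeWayResult(name, genes, enr, graph, modules)
    return out
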