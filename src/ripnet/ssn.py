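"""Sequence similarity network construction and community detection.

Nodes are TE copies; an edge connects two copies whose merged identity and
coverage both exceed their thresholds (strictly, by default, matching the
"> 80% identity over > 80% coverage" convention).  Subfamily candidates are
the communities found by unweighted greedy modularity maximization; small
communities are set aside as unclassified and each kept community is
summarized by its degree centroid, the exemplar used for downstream masking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from networkx.algorithms import community as nx_community

from .pairscore import PairScore

__all__ = [
    "Partition",
    "build_network",
    "modularity",
    "greedy_modularity_communities",
    "filter_small_communities",
    "centroid",
    "write_edge_list",
    "write_partition",
]


@dataclass(frozen=True)
class Partition:
    """A partition of the network's nodes into communities.

    Communities are sorted by decreasing size (ties by smallest member id)
    and labeled "1", "2", ... in that order, mirroring the community
    numbering style used for subfamily networks.
    """

    communities: tuple[frozenset, ...]
    q: float

    def __post_init__(self) -> None:
        nodes = [n for c in self.communities for n in c]
        if len(nodes) != len(set(nodes)):
            raise ValueError("communities are not disjoint")
        if any(len(c) == 0 for c in self.communities):
            raise ValueError("empty community in partition")

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self):
        return iter(self.communities)

    @property
    def labels(self) -> dict:
        """Map node -> community label ("1", "2", ... by decreasing size)."""
        out = {}
        for i, comm in enumerate(self.communities, start=1):
            for node in comm:
                out[node] = str(i)
        return out

    def node_set(self) -> frozenset:
        return frozenset(n for c in self.communities for n in c)


def _sorted_communities(comms: Iterable[Iterable]) -> tuple[frozenset, ...]:
    return tuple(
        sorted((frozenset(c) for c in comms), key=lambda c: (-len(c), min(c)))
    )


def build_network(
    pairs: Sequence[PairScore],
    nodes: Iterable[str],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    strict: bool = True,
) -> nx.Graph:
    """Build the thresholded similarity network.

    An edge is added iff merged_identity and merged_coverage both exceed
    their thresholds — strictly by default (``strict=False`` switches to
    >=).  Isolated nodes are retained, so the graph's node set is the full
    copy set, not just the connected copies.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for p in pairs:
        if p.a not in g or p.b not in g:
            missing = p.a if p.a not in g else p.b
            raise KeyError(f"pair references unknown node {missing!r}")
        if p.a == p.b:
            continue
        if strict:
            ok = p.merged_identity > min_identity and p.merged_coverage > min_coverage
        else:
            ok = p.merged_identity >= min_identity and p.merged_coverage >= min_coverage
        if ok:
            g.add_edge(
                p.a, p.b,
                merged_identity=p.merged_identity,
                merged_coverage=p.merged_coverage,
                n_hsps=p.n_hsps,
                covered_bp=p.covered_bp,
            )
    return g


def modularity(graph: nx.Graph, partition: Partition | Iterable[Iterable]) -> float:
    """Unweighted Newman modularity Q of a partition.

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]  over communities c, where m is
    the number of edges, e_c the number of intra-community edges and d_c the
    total degree of community c.  Undefined for edgeless graphs.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on a graph with no edges")
    comms = list(partition)
    covered = set()
    for c in comms:
        covered.update(c)
    if covered != set(graph.nodes):
        raise ValueError("partition does not cover the graph's node set")
    q = 0.0
    for c in comms:
        cset = set(c)
        e_c = sum(1 for u, v in graph.edges(cset) if u in cset and v in cset)
        d_c = sum(graph.degree(n) for n in cset)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def greedy_modularity_communities(graph: nx.Graph) -> Partition:
    """Detect communities by unweighted greedy (CNM) modularity maximization.

    Starts from singletons and repeatedly merges the community pair with the
    largest modularity gain until no merge increases Q.  Delegates to
    NetworkX's Clauset–Newman–Moore implementation on a node-sorted copy of
    the graph so results are reproducible; an edgeless graph yields all
    singletons (its modularity is undefined, so there is nothing to merge).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_edges() == 0:
        comms = [{n} for n in graph.nodes]
        return Partition(_sorted_communities(comms), q=float("nan"))
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges))
    comms = nx_community.greedy_modularity_communities(g, weight=None)
    comms = _sorted_communities(comms)
    return Partition(comms, q=modularity(graph, comms))


def filter_small_communities(
    partition: Partition, min_size: int = 5, keep_rule: str = "ge"
) -> tuple[Partition, frozenset]:
    """Split a partition into kept communities and unclassified members.

    ``keep_rule="ge"`` keeps communities with at least ``min_size`` members
    (i.e. drops those with fewer — "less than five left unclassified");
    ``keep_rule="gt"`` requires strictly more than ``min_size`` members.
    Members of dropped communities are returned as the unclassified set.
    """
    if keep_rule == "ge":
        keep = lambda c: len(c) >= min_size
    elif keep_rule == "gt":
        keep = lambda c: len(c) > min_size
    else:
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    kept = [c for c in partition if keep(c)]
    dropped = frozenset(n for c in partition if not keep(c) for n in c)
    return Partition(_sorted_communities(kept), q=partition.q), dropped


def centroid(graph: nx.Graph, community: Iterable) -> object:
    """The community member with the most connections inside the community.

    Degree is counted within the induced subgraph so that edges to other
    (interconnected) communities do not distort the exemplar choice.  Ties
    are broken by the largest summed merged identity of incident edges,
    then by lexicographically smallest id.
    """
    members = set(community)
    if not members:
        raise ValueError("community is empty")
    sub = graph.subgraph(members)

    def key(n):
        weight = sum(
            d.get("merged_identity", 0.0) for _, _, d in sub.edges(n, data=True)
        )
        return (-sub.degree(n), -weight, n)

    return min(sub.nodes, key=key)


# ---------------------------------------------------------------------------
# Exports


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list with merged identity/coverage attributes."""
    with open(path, "w") as fh:
        fh.write("a\tb\tmerged_identity\tmerged_coverage\n")
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((u, v))
            fh.write(
                f"{a}\t{b}\t{d.get('merged_identity', float('nan')):.4f}\t"
                f"{d.get('merged_coverage', float('nan')):.4f}\n"
            )


def write_partition(
    graph: nx.Graph,
    partition: Partition,
    path: str | Path,
    unclassified: Iterable = (),
) -> None:
    """TSV of (id, community, degree, is_centroid); unclassified rows last."""
    with open(path, "w") as fh:
        fh.write("id\tcommunity\tdegree\tis_centroid\n")
        for i, comm in enumerate(partition, start=1):
            cen = centroid(graph, comm)
            for node in sorted(comm):
                fh.write(
                    f"{node}\t{i}\t{graph.degree(node)}\t{int(node == cen)}\n"
                )
        for node in sorted(unclassified):
            fh.write(f"{node}\tUnclassified\t{graph.degree(node)}\t0\n")
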