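"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by exhaustive or per-base computation,
sharing no code path with the implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from ripnet.core_io import HitRecord


def sweep_merge(hsps: list[HitRecord], ref_len: int) -> tuple[float, float, int]:
    """Per-base sweep: walk every query position, apply the assignment rule.

    Each covered position is assigned to the HSP with the highest identity
    (ties: higher bitscore, then lower query start).  Returns
    (merged_identity, merged_coverage, covered_bp).
    """
    per_base: dict[int, float] = {}
    for pos in range(ref_len):
        covering = [h for h in hsps if h.qstart <= pos < h.qend]
        if not covering:
            continue
        best = min(covering, key=lambda h: (-h.pident, -h.bitscore, h.qstart))
        per_base[pos] = best.pident
    covered = len(per_base)
    if covered == 0:
        return 0.0, 0.0, 0
    identity = sum(per_base.values()) / covered
    coverage = 100.0 * covered / ref_len
    return identity, min(coverage, 100.0), covered


def _set_partitions(items: list):
    """All set partitions of ``items`` (standard recursive enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def _q(graph: nx.Graph, partition: list[list]) -> float:
    m = graph.number_of_edges()
    q = 0.0
    for comm in partition:
        cset = set(comm)
        e_c = sum(1 for u, v in graph.edges if u in cset and v in cset)
        d_c = sum(graph.degree(n) for n in cset)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def exhaustive_best_q(graph: nx.Graph) -> tuple[float, list[frozenset]]:
    """Globally optimal modularity by enumerating all set partitions.

    Enumerates per connected component and concatenates the per-component
    optima: merging communities from different components contributes no
    intra-community edges but adds a positive degree-product penalty, so a
    cross-component merge always lowers Q and the optimum respects
    components.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("modularity undefined without edges")
    best_parts: list[frozenset] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        rest = set(graph.nodes) - comp
        best = None
        for partition in _set_partitions(nodes):
            # the rest of the graph enters as one constant block, so the
            # argmax over this component's partitions is unaffected by it
            full = [list(c) for c in partition] + ([list(rest)] if rest else [])
            q = _q(graph, full)
            if best is None or q > best[0]:
                best = (q, [frozenset(c) for c in partition])
        best_parts.extend(best[1])
    return _q(graph, [list(c) for c in best_parts]), best_parts
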