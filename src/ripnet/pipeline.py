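"""End-to-end convenience wrapper: hits -> network -> subfamilies."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from . import classify as _classify
from . import pairscore as _pairscore
from . import ssn as _ssn
from .core_io import HitRecord

__all__ = ["PipelineResult", "classify_copies"]


@dataclass
class PipelineResult:
    graph: nx.Graph
    partition: _ssn.Partition
    kept: _ssn.Partition
    unclassified: frozenset
    classification: dict
    centroids: dict  # community label -> centroid id


def classify_copies(
    hits: Sequence[HitRecord],
    lengths: Mapping[str, int],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    min_community: int = 5,
    keep_rule: str = "ge",
    merge_map: _classify.MergeMap | None = None,
    prefix: str = "LTR",
    coverage_ref: str = "query",
) -> PipelineResult:
    """Run the full classification on raw all-vs-all hits.

    Cleans the hits, merges HSPs into per-pair scores, builds the
    thresholded network over *all* sequences in ``lengths``, detects
    communities by unweighted greedy modularity, drops small communities,
    and names the rest as subfamilies.
    """
    pairs = _pairscore.score_pairs(hits, lengths, coverage_ref=coverage_ref)
    graph = _ssn.build_network(pairs, lengths.keys(), min_identity, min_coverage)
    partition = _ssn.greedy_modularity_communities(graph)
    kept, dropped = _ssn.filter_small_communities(partition, min_community, keep_rule)
    classification = _classify.assign_labels(
        kept, merge_map, prefix=prefix, unclassified=dropped
    )
    centroids = {
        str(i): _ssn.centroid(graph, comm) for i, comm in enumerate(kept, start=1)
    }
    return PipelineResult(
        graph=graph,
        partition=partition,
        kept=kept,
        unclassified=dropped,
        classification=classification,
        centroids=centroids,
    )
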