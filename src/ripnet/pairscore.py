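"""Merged per-pair identity and coverage from all-vs-all local-alignment hits.

RIP-degraded TE copies rarely align to each other in one clean hit: the
all-vs-all search returns stacks of fragmented and partially overlapping
HSPs per pair.  Taking only the top hit under-reports both identity and
coverage, so the similarity used to build the network is recalculated over
the *non-overlapping union* of all HSPs of a pair: every covered query base
is counted exactly once, assigned to the best HSP covering it, and the
merged identity is the coverage-weighted mean of the contributing HSP
identities.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .core_io import HitRecord

__all__ = [
    "PairScore",
    "remove_self_and_reciprocal",
    "merge_hsps",
    "score_pairs",
    "write_pair_scores",
    "read_pair_scores",
]

CoverageRef = Literal["query", "shorter", "longer"]


@dataclass(frozen=True)
class PairScore:
    """Merged similarity for one unordered sequence pair.

    ``merged_identity`` is a convex combination of the HSP identities
    (bounded by their min and max); ``merged_coverage`` is the fraction of
    the reference length covered by the union of the HSPs, in percent.
    """

    a: str
    b: str
    merged_identity: float
    merged_coverage: float
    n_hsps: int
    covered_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.merged_identity <= 100.0):
            raise ValueError("merged_identity outside [0, 100]")
        if self.merged_coverage > 100.0 + 1e-9:
            raise ValueError("merged_coverage above 100%")


def remove_self_and_reciprocal(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """Drop self hits and keep one direction per unordered pair.

    For each pair {a, b} hit in both directions, the direction with the
    larger total bitscore is retained with all of its HSPs; the other
    direction is dropped entirely.  Ties keep the lexicographically smaller
    (qid, sid) direction, so the result is deterministic.
    """
    by_direction: dict[tuple[str, str], list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.qid == h.sid:
            continue
        by_direction[(h.qid, h.sid)].append(h)

    kept: list[HitRecord] = []
    for (qid, sid), fwd in sorted(by_direction.items()):
        if (sid, qid) in by_direction:
            rev = by_direction[(sid, qid)]
            fwd_score = sum(h.bitscore for h in fwd)
            rev_score = sum(h.bitscore for h in rev)
            if fwd_score < rev_score:
                continue
            if fwd_score == rev_score and (sid, qid) < (qid, sid):
                continue
        kept.extend(fwd)
    return kept


def merge_hsps(hsps: Sequence[HitRecord], ref_len: int) -> PairScore:
    """Merge the HSPs of one directed pair into a single identity/coverage.

    Overlapping query bases are assigned to the HSP with the higher percent
    identity (ties: higher bitscore, then lower query start), so that every
    covered base contributes exactly once.  The merged identity is
    sum(pident_i * assigned_len_i) / covered_bp and the coverage is
    100 * covered_bp / ref_len.
    """
    if not hsps:
        raise ValueError("merge_hsps requires at least one HSP")
    pair = (hsps[0].qid, hsps[0].sid)
    if any((h.qid, h.sid) != pair for h in hsps):
        raise ValueError("merge_hsps received HSPs from multiple pairs")
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")

    # Priority sweep: walking HSPs best-first and granting each one the part
    # of its query interval not yet claimed implements the per-base rule.
    order = sorted(
        range(len(hsps)),
        key=lambda i: (-hsps[i].pident, -hsps[i].bitscore, hsps[i].qstart),
    )
    claimed: list[tuple[int, int]] = []  # disjoint, sorted intervals
    weighted = 0.0
    covered = 0
    for i in order:
        h = hsps[i]
        assigned = _subtract(h.qstart, h.qend, claimed)
        got = sum(e - s for s, e in assigned)
        if got:
            weighted += h.pident * got
            covered += got
            claimed = _merge_sorted(claimed, assigned)

    merged_identity = weighted / covered
    merged_coverage = 100.0 * covered / ref_len
    return PairScore(
        a=pair[0], b=pair[1],
        merged_identity=merged_identity,
        merged_coverage=min(merged_coverage, 100.0),
        n_hsps=len(hsps), covered_bp=covered,
    )


def _subtract(start: int, end: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by the disjoint sorted intervals."""
    out: list[tuple[int, int]] = []
    cur = start
    for s, e in claimed:
        if e <= cur:
            continue
        if s >= end:
            break
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
        if cur >= end:
            break
    if cur < end:
        out.append((cur, end))
    return out


def _merge_sorted(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of two disjoint interval lists, coalescing adjacency."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(a + b):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def score_pairs(
    hits: Sequence[HitRecord],
    lengths: Mapping[str, int],
    coverage_ref: CoverageRef = "query",
    clean: bool = True,
) -> list[PairScore]:
    """Compute one :class:`PairScore` per surviving directed pair.

    ``coverage_ref`` selects the coverage denominator: the query of the
    retained direction (default), or the shorter/longer of the two
    sequences.  Output is sorted by (a, b) for reproducibility.
    """
    if clean:
        hits = remove_self_and_reciprocal(hits)
    by_pair: dict[tuple[str, str], list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_pair[(h.qid, h.sid)].append(h)

    scores: list[PairScore] = []
    for (qid, sid), group in sorted(by_pair.items()):
        for sid_ in (qid, sid):
            if sid_ not in lengths:
                raise KeyError(f"sequence id {sid_!r} missing from lengths")
        if coverage_ref == "query":
            ref_len = lengths[qid]
        elif coverage_ref == "shorter":
            ref_len = min(lengths[qid], lengths[sid])
        elif coverage_ref == "longer":
            ref_len = max(lengths[qid], lengths[sid])
        else:
            raise ValueError(f"unknown coverage_ref {coverage_ref!r}")
        scores.append(merge_hsps(group, ref_len))
    return scores


_PAIR_COLS = ["a", "b", "merged_identity", "merged_coverage", "n_hsps", "covered_bp"]


def write_pair_scores(scores: Iterable[PairScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLS) + "\n")
        for s in scores:
            fh.write(
                f"{s.a}\t{s.b}\t{s.merged_identity:.4f}\t"
                f"{s.merged_coverage:.4f}\t{s.n_hsps}\t{s.covered_bp}\n"
            )


def read_pair_scores(path: str | Path) -> list[PairScore]:
    scores: list[PairScore] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PAIR_COLS:
            raise ValueError(f"{path}: unexpected pair-score header {header}")
        for line in fh:
            a, b, mi, mc, n, cov = line.rstrip("\n").split("\t")
            scores.append(
                PairScore(a, b, float(mi), float(mc), int(n), int(cov))
            )
    return scores
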