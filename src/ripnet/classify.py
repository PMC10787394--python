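"""Turning communities into named subfamilies and auditing the result.

Covers three post-network steps: naming kept communities as subfamilies
(with user-directed merges of near-duplicate communities), comparing two
classifications of the same copies (e.g. the network's labels versus a
RepeatMasker assignment), and flagging "rogue" copies — classified copies
that fall outside their subfamily's main clade in a phylogeny, typically
because RIP degradation, indels or recombination pulled them away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .ssn import Partition

__all__ = [
    "UNCLASSIFIED",
    "Classification",
    "MergeMap",
    "DisagreementReport",
    "assign_labels",
    "compare_classifications",
    "detect_rogues",
    "read_merge_map",
    "write_classification",
    "read_classification",
]

UNCLASSIFIED = "Unclassified"

Classification = dict  # sequence id -> subfamily label (or UNCLASSIFIED)


@dataclass(frozen=True)
class MergeMap:
    """User-directed merges of communities into joint subfamilies.

    Each rule maps a set of community labels (as assigned by the partition,
    "1", "2", ...) to one subfamily name.  A community may appear in at most
    one rule.
    """

    rules: tuple[tuple[frozenset, str], ...] = ()

    def __post_init__(self) -> None:
        seen: set = set()
        for comms, _name in self.rules:
            dup = seen & comms
            if dup:
                raise ValueError(
                    f"community {sorted(dup)[0]!r} appears in more than one merge rule"
                )
            seen |= comms

    def name_for(self, community_label: str) -> str | None:
        for comms, name in self.rules:
            if community_label in comms:
                return name
        return None

    def all_communities(self) -> frozenset:
        return frozenset(c for comms, _ in self.rules for c in comms)


@dataclass(frozen=True)
class DisagreementReport:
    """Comparison of two classifications over the copies classified in A."""

    n_compared: int
    n_disagree: int
    n_missing: int
    confusion: tuple = field(default=(), compare=False)

    @property
    def rate(self) -> float:
        """Disagreement rate in percent."""
        return 100.0 * self.n_disagree / self.n_compared


def assign_labels(
    partition: Partition,
    merge_map: MergeMap | None = None,
    prefix: str = "LTR",
    unclassified: Iterable = (),
) -> Classification:
    """Name the kept communities, applying user-directed merges.

    Merged communities share the rule's subfamily name; the remaining
    communities receive ``prefix`` + rank, ranked by member count (joint
    subfamilies count their pooled members).  Members of dropped communities
    are labeled "Unclassified".
    """
    merge_map = merge_map or MergeMap()
    comm_labels = {str(i): comm for i, comm in enumerate(partition, start=1)}
    unknown = merge_map.all_communities() - set(comm_labels)
    if unknown:
        raise KeyError(f"merge rule names unknown community {sorted(unknown)[0]!r}")

    # Group communities into subfamilies: one group per merge rule plus one
    # per unmerged community, then rank groups by pooled size.
    groups: list[tuple[str | None, frozenset]] = []
    for comms, name in merge_map.rules:
        members = frozenset(n for c in comms for n in comm_labels[c])
        groups.append((name, members))
    merged = merge_map.all_communities()
    for label, comm in comm_labels.items():
        if label not in merged:
            groups.append((None, frozenset(comm)))
    groups.sort(key=lambda g: (-len(g[1]), min(g[1])))

    used = {name for name, _ in groups if name is not None}
    classification: Classification = {}
    counter = 1
    for name, members in groups:
        if name is None:
            while f"{prefix}{counter}" in used:
                counter += 1
            name = f"{prefix}{counter}"
            used.add(name)
            counter += 1
        for node in members:
            classification[node] = name
    for node in unclassified:
        classification[node] = UNCLASSIFIED
    return classification


def compare_classifications(a: Classification, b: Classification) -> DisagreementReport:
    """Count label disagreements over the copies classified in ``a``.

    Copies labeled Unclassified in ``a`` are excluded.  Copies absent from
    ``b`` count as disagreements and are also reported separately as
    ``n_missing``.  The rate is undefined (raises) if nothing is compared.
    """
    ids = [i for i, lab in a.items() if lab != UNCLASSIFIED]
    if not ids:
        raise ValueError("no classified copies to compare")
    n_disagree = 0
    n_missing = 0
    confusion: dict[tuple[str, str], int] = {}
    for i in ids:
        if i not in b:
            n_disagree += 1
            n_missing += 1
            continue
        if a[i] != b[i]:
            n_disagree += 1
            key = (a[i], b[i])
            confusion[key] = confusion.get(key, 0) + 1
    return DisagreementReport(
        n_compared=len(ids),
        n_disagree=n_disagree,
        n_missing=n_missing,
        confusion=tuple(sorted(confusion.items())),
    )


def detect_rogues(
    tree: dendropy.Tree,
    classification: Classification,
    purity: float = 0.5,
) -> dict:
    """Find copies placed outside their subfamily's main clade.

    For each subfamily S, the main clade is the internal node maximizing the
    number of S members among clades whose leaves are more than ``purity``
    S members (ties: more leaves, then closer to the root).  Rogues are the
    S members outside that clade.  A subfamily with no clade passing the
    purity bar reports all its members as rogue.  Unclassified copies are
    ignored.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    by_subfamily: dict[str, set] = {}
    for cid, label in classification.items():
        if label == UNCLASSIFIED:
            continue
        if cid not in leaf_labels:
            raise KeyError(f"classified copy {cid!r} is not a leaf of the tree")
        by_subfamily.setdefault(label, set()).add(cid)

    # Leaf sets and root distance (in edges) for every internal node.
    clades: list[tuple[frozenset, int]] = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        depth = sum(1 for _ in node.ancestor_iter())
        clades.append((leaves, depth))

    rogues: dict[str, frozenset] = {}
    for subfam, members in sorted(by_subfamily.items()):
        best: tuple | None = None
        for leaves, depth in clades:
            n_s = len(leaves & members)
            if n_s == 0 or n_s / len(leaves) <= purity:
                continue
            key = (n_s, len(leaves), -depth)
            if best is None or key > best[0]:
                best = (key, leaves)
        if best is None:
            rogues[subfam] = frozenset(members)
        else:
            rogues[subfam] = frozenset(members - best[1])
    return rogues


# ---------------------------------------------------------------------------
# Small text formats


def read_merge_map(path: str | Path) -> MergeMap:
    """Parse merge rules, one per line: ``1.1,1.2 -> LTR1``."""
    rules: list[tuple[frozenset, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'comms -> name'")
            left, name = (s.strip() for s in line.split("->", 1))
            comms = frozenset(c.strip() for c in left.split(",") if c.strip())
            if not comms or not name:
                raise ValueError(f"{path}:{lineno}: empty rule")
            rules.append((comms, name))
    return MergeMap(tuple(rules))


def write_classification(classification: Classification, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for cid in sorted(classification):
            fh.write(f"{cid}\t{classification[cid]}\n")


def read_classification(path: str | Path) -> Classification:
    out: Classification = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "label"]:
            raise ValueError(f"{path}: unexpected classification header")
        for line in fh:
            cid, label = line.rstrip("\n").split("\t")[:2]
            out[cid] = label
    return out
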