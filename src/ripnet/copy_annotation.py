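"""Copy retrieval and RepeatMasker post-processing logic.

Reconstructs the copy-context side of the workflow: merging genome hits
into haplotypes (with a minimum size and flank extension), deciding whether
a terminal-repeat occurrence sits at the end of a full element (a full-copy
LTR), inside one (a nested insertion) or on its own (solo/fragment), and
turning a RepeatMasker scan against subfamily exemplars into per-species,
per-subfamily counts of full versus solo/fragment copies.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_io import GenomicInterval, HitRecord, RMHit, interval_to_copy_id

__all__ = [
    "CopyContext",
    "FullCopyAnnotation",
    "AmbiguousContextError",
    "merge_hits_to_haplotypes",
    "classify_copy_context",
    "postprocess_repeatmasker",
    "flag_disparate_ltrs",
    "select_5prime_ltr",
]


class CopyContext(enum.Enum):
    """Genomic context of a terminal-repeat occurrence."""

    FULL_5P = "full_5p"
    FULL_3P = "full_3p"
    NESTED = "nested"
    SOLO_FRAGMENT = "solo_fragment"


class AmbiguousContextError(ValueError):
    """An LTR hit overlaps both ends of one element (spans the whole copy)."""


@dataclass(frozen=True)
class FullCopyAnnotation:
    """A full element: two terminal repeats flanking an internal region.

    ``ltr5``/``ltr3`` are strand-aware: on a minus-strand element the 5'
    LTR is the right-hand interval genomically.  All parts must lie on the
    same contig and strand, the LTRs must abut the element's ends, and the
    internal region must sit strictly between them.
    """

    element: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    internal: GenomicInterval
    ltr5_label: str | None = None
    ltr3_label: str | None = None

    def __post_init__(self) -> None:
        parts = (self.ltr5, self.ltr3, self.internal)
        if any(p.contig != self.element.contig or p.strand != self.element.strand
               for p in parts):
            raise ValueError("element parts on different contig/strand")
        left, right = (self.ltr5, self.ltr3) if self.element.strand == "+" else (self.ltr3, self.ltr5)
        ok = (
            left.start == self.element.start
            and left.end == self.internal.start
            and self.internal.end == right.start
            and right.end == self.element.end
        )
        if not ok:
            raise ValueError(
                f"element {self.id} is not LTR|internal|LTR "
                f"({left.start},{left.end},{self.internal.start},"
                f"{self.internal.end},{right.start},{right.end})"
            )

    @property
    def id(self) -> str:
        return self.element.name or interval_to_copy_id(self.element)


def merge_hits_to_haplotypes(
    hits: Sequence[HitRecord],
    min_size: int = 4000,
    flank: int = 2000,
    merge_gap: int = 1000,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Merge query-vs-genome hits into extended haplotype intervals.

    Hits on the same contig and strand separated by at most ``merge_gap``
    bp are merged into one haplotype; haplotypes shorter than ``min_size``
    are dropped; survivors are extended by ``flank`` bp on each side,
    clipped to the contig.  The defaults (4 kb minimum, 2 kb flanks) are the
    settings used for internal-region retrieval of full copies.
    """
    if min_size < 0 or flank < 0 or merge_gap < 0:
        raise ValueError("min_size, flank and merge_gap must be non-negative")
    contig_lengths = contig_lengths or {}

    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        groups.setdefault((h.sid, h.strand), []).append((h.sstart, h.send))

    out: list[GenomicInterval] = []
    for (contig, strand), spans in sorted(groups.items()):
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if contig_lengths and contig not in contig_lengths:
            raise KeyError(f"contig {contig!r} missing from contig_lengths")
        limit = contig_lengths.get(contig)
        extended: list[list[int]] = []
        for s, e in merged:
            if e - s < min_size:
                continue
            s2 = max(0, s - flank)
            e2 = e + flank if limit is None else min(limit, e + flank)
            # flank extension can close a previously unmergeable gap, so
            # coalesce again — this makes the operation idempotent
            if extended and s2 - extended[-1][1] <= merge_gap:
                extended[-1][1] = max(extended[-1][1], e2)
            else:
                extended.append([s2, e2])
        out.extend(GenomicInterval(contig, s, e, strand) for s, e in extended)
    return sorted(out)


def classify_copy_context(
    ltr: GenomicInterval,
    full_copies: Sequence[FullCopyAnnotation],
    end_tolerance: int = 10,
) -> CopyContext:
    """Place one terminal-repeat occurrence relative to the full copies.

    FULL_5P/FULL_3P if it overlaps the corresponding terminal repeat of a
    full element (the LTR intervals are padded by ``end_tolerance`` bp to
    absorb imprecise hit ends); NESTED if it overlaps only an internal
    region; SOLO_FRAGMENT if it overlaps no full copy at all.  A hit
    touching both ends of one element spans the whole copy and is rejected
    for manual curation.
    """
    nested = False
    for fc in full_copies:
        if fc.element.contig != ltr.contig:
            continue
        hit5 = _padded_overlap(ltr, fc.ltr5, end_tolerance)
        hit3 = _padded_overlap(ltr, fc.ltr3, end_tolerance)
        if hit5 and hit3:
            raise AmbiguousContextError(
                f"hit {ltr.contig}:{ltr.start}-{ltr.end} overlaps both ends "
                f"of element {fc.id}"
            )
        if hit5:
            return CopyContext.FULL_5P
        if hit3:
            return CopyContext.FULL_3P
        if ltr.overlaps(fc.internal):
            nested = True
    return CopyContext.NESTED if nested else CopyContext.SOLO_FRAGMENT


def _padded_overlap(ltr: GenomicInterval, part: GenomicInterval, pad: int) -> bool:
    return ltr.start < part.end + pad and part.start - pad < ltr.end


def postprocess_repeatmasker(
    rm_hits: Sequence[RMHit],
    full_copies: Sequence[FullCopyAnnotation],
    curated_ltrs: Sequence[GenomicInterval] = (),
    min_len: int = 250,
    end_tolerance: int = 10,
    species: str = "unknown",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four post-processing rules to a RepeatMasker scan.

    (1) drop hits whose genomic span is not longer than ``min_len`` (short
    hits never reach the variable U3 region that separates subfamilies);
    (2) assign each survivor a :class:`CopyContext` against the annotated
    full copies; (3) drop putative solo-LTRs that overlap a curated
    full-copy terminal repeat (any overlap counts); (4) tally per-species,
    per-subfamily counts of full versus solo/fragment copies — nested hits
    are tallied with solo/fragment, as in the copy-number analysis, but
    keep their context in the per-hit table.

    Returns ``(counts, detail)``: a counts table indexed by (species,
    subfamily) with columns full/solo_fragment, and a per-hit table with
    the context or the rule that dropped each hit.
    """
    annotated_contigs = {fc.element.contig for fc in full_copies} | {
        c.contig for c in curated_ltrs
    }
    rows: list[dict] = []
    for h in rm_hits:
        row = {
            "species": species,
            "subfamily": h.repeat_name,
            "contig": h.contig,
            "begin": h.begin,
            "end": h.end,
            "length": h.length,
            "context": None,
            "dropped_by": None,
        }
        if h.length <= min_len:
            row["dropped_by"] = "min_length"
            rows.append(row)
            continue
        if annotated_contigs and h.contig not in annotated_contigs:
            warnings.warn(
                f"RepeatMasker hit contig {h.contig!r} has no annotated full copies",
                stacklevel=2,
            )
        try:
            ctx = classify_copy_context(h.interval, full_copies, end_tolerance)
        except AmbiguousContextError:
            row["dropped_by"] = "spans_element"
            rows.append(row)
            continue
        if ctx is CopyContext.SOLO_FRAGMENT and any(
            h.interval.overlaps(c) for c in curated_ltrs
        ):
            row["dropped_by"] = "full_copy_boundary"
            rows.append(row)
            continue
        row["context"] = ctx.value
        rows.append(row)

    detail = pd.DataFrame(
        rows,
        columns=[
            "species", "subfamily", "contig", "begin", "end",
            "length", "context", "dropped_by",
        ],
    )
    counted = detail[detail["context"].notna()].copy()
    counted["category"] = counted["context"].map(
        lambda c: "full" if c in ("full_5p", "full_3p") else "solo_fragment"
    )
    counts = (
        counted.groupby(["species", "subfamily", "category"])
        .size()
        .unstack("category", fill_value=0)
        .reindex(columns=["full", "solo_fragment"], fill_value=0)
    )
    counts.columns.name = None
    return counts, detail


def flag_disparate_ltrs(full_copies: Sequence[FullCopyAnnotation]) -> list[str]:
    """Ids of full copies whose 5' and 3' terminal repeats disagree.

    Disparate LTR subfamilies on one element point to inter-element
    recombination or template switching.  Elements missing a label are
    skipped with a warning.
    """
    flagged: list[str] = []
    for fc in full_copies:
        if fc.ltr5_label is None or fc.ltr3_label is None:
            warnings.warn(f"element {fc.id} missing an LTR label; skipped", stacklevel=2)
            continue
        if fc.ltr5_label != fc.ltr3_label:
            flagged.append(fc.id)
    return flagged


def select_5prime_ltr(full_copies: Sequence[FullCopyAnnotation]) -> list[str]:
    """One terminal-repeat id per full copy: its strand-aware 5' LTR.

    Keeping a single LTR per element avoids double-weighting full copies
    when their terminal repeats enter the network.  On minus-strand
    elements the 5' LTR is the right-hand interval genomically.
    """
    return [fc.ltr5.name or interval_to_copy_id(fc.ltr5) for fc in full_copies]
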