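"""Readers, writers and canonical data types.

All genomic coordinates are held internally as 0-based, half-open intervals
with an explicit strand.  The two external tabular formats consumed here
(BLAST outfmt 6 and RepeatMasker ``.out``) are 1-based inclusive; they are
converted at the parsing boundary and converted back on output, so that all
interval arithmetic elsewhere in the package uses a single convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "HitRecord",
    "RMHit",
    "UndefinedGCError",
    "read_fasta",
    "write_fasta",
    "parse_copy_id",
    "copy_id_to_interval",
    "interval_to_copy_id",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_repeatmasker_out",
    "read_bed",
    "write_bed",
    "read_tree",
    "gc_content",
]

_COPY_ID_RE = re.compile(r"^(?P<contig>.+)_(?P<start>\d+)-(?P<end>\d+)$")


class UndefinedGCError(ValueError):
    """Raised when GC content is requested for a sequence with no A/C/G/T."""


@dataclass(frozen=True)
class SequenceRecord:
    """One TE copy (or any nucleotide sequence) with its identifier.

    The identifier conventionally encodes the genomic provenance of the copy
    as ``contig_start-end`` (1-based inclusive); see :func:`parse_copy_id`.
    """

    id: str
    seq: str
    species: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        rc = str(Seq(self.seq).reverse_complement())
        return SequenceRecord(id=self.id, seq=rc, species=self.species)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based, half-open interval on a contig with explicit strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap of at least one base on the same contig."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.contig, self.start + offset, self.end + offset, self.strand, self.name
        )


@dataclass
class HitRecord:
    """One local-alignment hit (HSP) between a query and a subject sequence.

    Coordinates are stored 0-based half-open on the plus strand of each
    sequence; ``strand`` is '-' when the subject was hit in reverse
    orientation (input ``sstart > send``).
    """

    qid: str
    sid: str
    pident: float
    alen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    bitscore: float
    evalue: float = 0.0
    mismatch: int = 0
    gapopen: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValueError("hit coordinates not canonicalized (start > end)")


@dataclass
class RMHit:
    """One row of a RepeatMasker ``.out`` annotation table."""

    score: int
    divergence: float
    deletion: float
    insertion: float
    contig: str
    begin: int  # 0-based half-open internally
    end: int
    strand: str  # '+' or '-' ('C' on input)
    repeat_name: str
    repeat_class: str
    rep_begin: int
    rep_end: int
    rep_left: int
    hit_id: int

    @property
    def length(self) -> int:
        return self.end - self.begin

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.begin, self.end, self.strand, name=self.repeat_name
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and line wraps removed.  Duplicate identifiers
    raise an error, since copy ids must be unique within a dataset.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        # distinguish empty/garbage files from a valid empty parse
        text = Path(path).read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise ValueError(f"{path} is not FASTA (no '>' header found)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Copy identifiers ("contig_start-end")


def parse_copy_id(copy_id: str) -> tuple[str, int, int]:
    """Split a ``contig_start-end`` identifier into its parts.

    The contig is everything left of the *rightmost* underscore, because
    contig names themselves routinely contain underscores.  Positions are
    returned exactly as written (1-based inclusive); ``start == end`` is
    rejected as a degenerate interval.
    """
    m = _COPY_ID_RE.match(copy_id)
    if m is None:
        raise ValueError(f"copy id {copy_id!r} does not end with '_<start>-<end>'")
    start, end = int(m.group("start")), int(m.group("end"))
    if start == end:
        raise ValueError(f"copy id {copy_id!r} has degenerate interval {start}-{end}")
    return m.group("contig"), start, end


def copy_id_to_interval(copy_id: str) -> GenomicInterval:
    """Convert a copy id to an internal interval.

    Reversed coordinates (start > end) mark a minus-orientation copy and are
    normalized, e.g. ``scaf_2_300-250`` becomes 249..300 on '-'.
    """
    contig, start, end = parse_copy_id(copy_id)
    strand = "+"
    if start > end:
        start, end = end, start
        strand = "-"
    return GenomicInterval(contig, start - 1, end, strand, name=copy_id)


def interval_to_copy_id(iv: GenomicInterval) -> str:
    """Inverse of :func:`copy_id_to_interval` (1-based inclusive on output)."""
    if iv.strand == "-":
        return f"{iv.contig}_{iv.end}-{iv.start + 1}"
    return f"{iv.contig}_{iv.start + 1}-{iv.end}"


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_OUTFMT6_COLS = (
    "qid sid pident alen mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | Path) -> list[HitRecord]:
    """Read 12-column BLAST tabular hits (outfmt 6).

    The subject strand is inferred from the order of ``sstart``/``send``;
    minus-strand subject coordinates are swapped so that all stored
    coordinates ascend.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                (qid, sid, pident, alen, mism, gapo, qs, qe, ss, se, ev, bs) = parts
                pident = float(pident)
                qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
                hit = _make_hit(
                    qid, sid, pident, int(alen), int(mism), int(gapo),
                    qs, qe, ss, se, float(ev), float(bs),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def _make_hit(qid, sid, pident, alen, mism, gapo, qs, qe, ss, se, ev, bs) -> HitRecord:
    strand = "+"
    if ss > se:
        ss, se = se, ss
        strand = "-"
    if qs > qe:
        raise ValueError(f"query coordinates reversed ({qs} > {qe})")
    return HitRecord(
        qid=qid, sid=sid, pident=pident, alen=alen,
        qstart=qs - 1, qend=qe, sstart=ss - 1, send=se,
        bitscore=bs, evalue=ev, mismatch=mism, gapopen=gapo, strand=strand,
    )


def write_tabular_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits back out as outfmt 6 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.sstart + 1, h.send
            if h.strand == "-":
                ss, se = se, ss
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.qid, h.sid, f"{h.pident:.2f}", h.alen, h.mismatch,
                        h.gapopen, h.qstart + 1, h.qend, ss, se,
                        f"{h.evalue:.2g}", f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: str | Path) -> list[RMHit]:
    """Parse a RepeatMasker ``.out`` file.

    The standard format carries a 3-line header, which is skipped when
    present (a missing header is tolerated with a warning).  'C' strands map
    to '-'; a trailing '*' higher-scoring-overlap flag is tolerated.
    """
    lines = Path(path).read_text().splitlines()
    start = 0
    first = lines[0].split() if lines else []
    if first and not first[0].isdigit():
        start = 3  # header block: two label lines + one blank
    else:
        warnings.warn(f"{path}: no RepeatMasker header detected", stacklevel=2)
    hits: list[RMHit] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if parts and parts[-1] == "*":
            parts = parts[:-1]
        if len(parts) < 15:
            raise ValueError(f"{path}:{lineno}: truncated row ({len(parts)} fields)")
        try:
            score = int(parts[0])
            div, dele, ins = (float(x) for x in parts[1:4])
            contig = parts[4]
            begin, end = int(parts[5]), int(parts[6])
            strand = parts[8]
            name, rclass = parts[9], parts[10]
            rep = [int(x.strip("()")) for x in parts[11:14]]
            hit_id = int(parts[14])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if strand == "C":
            strand = "-"
            rep_left, rep_end, rep_begin = rep
        else:
            rep_begin, rep_end, rep_left = rep
        hits.append(
            RMHit(
                score=score, divergence=div, deletion=dele, insertion=ins,
                contig=contig, begin=begin - 1, end=end, strand=strand,
                repeat_name=name, repeat_class=rclass,
                rep_begin=rep_begin, rep_end=rep_end, rep_left=rep_left,
                hit_id=hit_id,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# BED (0-based half-open, as the format itself)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 else "+"
            ivs.append(GenomicInterval(contig, start, end, strand, name=name))
    return ivs


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Trees


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree; leaf labels are sequence ids."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Sequence statistics

_GC = frozenset("GCgc")
_ACGT = frozenset("ACGTacgt")


def gc_content(seq: str) -> float:
    """GC content in percent over unambiguous bases.

    Ambiguity codes and N are excluded from the denominator so that the RIP
    statistics of degraded copies are not diluted by masked positions.
    Raises :class:`UndefinedGCError` if the sequence has no A/C/G/T at all.
    """
    acgt = sum(1 for c in seq if c in _ACGT)
    if acgt == 0:
        raise UndefinedGCError("sequence contains no unambiguous A/C/G/T bases")
    gc = sum(1 for c in seq if c in _GC)
    return 100.0 * gc / acgt
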