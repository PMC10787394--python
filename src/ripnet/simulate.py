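"""Forward simulator of an LTR-retrotransposon family under RIP.

Simulates a burst of insertions from a small set of subfamily founders that
share a conserved 3'-half of the terminal repeat (R + U5, carrying the
TATA-box) and an internal coding region, but differ in the regulatory U3
half of the LTR.  Each insertion carries two *identical* LTRs flanked by a
target-site duplication.  Copies then evolve through cycles of neutral
mutation, solo-LTR formation (LTR-LTR recombination), fragmentation, nested
insertion, and repeat-induced point mutation (RIP): C->T hypermutation of
repeats, preferring CpA (and TpG on the other strand), gated on a minimum
repeat length and a minimum pairwise identity.

Because every surviving base is tracked back to founder coordinates, the
simulator can emit *exact* pairwise homology hits (``truth_hits``) in BLAST
tabular form, so the whole classification pipeline can be exercised without
an external aligner; ``local_align`` offers a Smith-Waterman path for
cross-checking.
"""

from __future__ import annotations

import copy as _copymod
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .copy_annotation import FullCopyAnnotation
from .core_io import (
    GenomicInterval,
    HitRecord,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_tabular_hits,
)
from .pairscore import merge_hsps

__all__ = [
    "SimConfig",
    "SimCopy",
    "SimResult",
    "simulate_family",
    "apply_rip",
    "rip_mutate_seq",
    "make_solo_ltr",
    "truth_hits",
    "local_align",
]

# base codes
_A, _C, _G, _T = 0, 1, 2, 3
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i

TATA_BOX = "TATAAA"
CONTIG = "contig_1"


def _to_codes(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr.copy()


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class SimConfig:
    """Study conditions for one simulated LTR-retrotransposon family.

    Defaults describe a family whose ~400 bp terminal repeats diverge
    between subfamilies only in the ~200 bp U3 half, sitting on a ~6.6 kb
    internal region, with RIP requiring repeats of at least 400 bp sharing
    at least 80% identity and strongly preferring CpA/TpG dinucleotides.
    """

    n_subfamilies: int = 3
    copies_per_subfamily: int = 20
    ltr_len: int = 400
    u3_len: int = 200
    internal_len: int = 6600
    u3_divergence: float = 0.5
    neutral_mut_rate: float = 1e-4
    n_cycles: int = 3
    p_solo: float = 0.02
    p_frag: float = 0.01
    p_nest: float = 0.0
    rip_p_cpa: float = 0.05
    rip_p_other: float = 0.01
    rip_min_len: int = 400
    rip_min_id: float = 80.0
    tsd_len: int = 5
    genome_len: int = 0  # 0 = sized automatically from the copy count
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("u3_divergence", "neutral_mut_rate", "p_solo", "p_frag",
                     "p_nest", "rip_p_cpa", "rip_p_other"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0 < self.u3_len < self.ltr_len):
            raise ValueError("need 0 < u3_len < ltr_len")
        if self.rip_p_other > self.rip_p_cpa:
            raise ValueError("rip_p_other must not exceed rip_p_cpa")
        if self.n_subfamilies < 1 or self.copies_per_subfamily < 1:
            raise ValueError("need at least one subfamily and one copy")

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len

    @property
    def n_copies(self) -> int:
        return self.n_subfamilies * self.copies_per_subfamily


# ---------------------------------------------------------------------------
# Internal representation: units made of blocks in founder coordinates.
#
# Regions: "u3" (variable LTR half), "ru5" (conserved R+U5 half), "int"
# (internal).  A block holds a founder-coordinate interval of one region
# plus its current sequence, so exact homology between any two units is the
# intersection of their same-region intervals.


@dataclass
class _Block:
    region: str
    start: int
    end: int
    seq: np.ndarray

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class _NestBlock:
    child: "_Unit"
    tsd: np.ndarray


@dataclass
class _Unit:
    uid: int
    subfamily: int
    cls: str  # "full" | "solo" | "fragment"
    blocks: list
    nested: bool = False
    rip_exposures: int = 0

    def seq_blocks(self) -> list[_Block]:
        return [b for b in self.blocks if isinstance(b, _Block)]

    def own_len(self) -> int:
        return sum(len(b) for b in self.seq_blocks())

    def concat(self) -> tuple[np.ndarray, list[tuple[_Block, int]]]:
        """Own sequence (nested children excluded) plus block offsets."""
        offsets = []
        parts = []
        off = 0
        for b in self.seq_blocks():
            offsets.append((b, off))
            parts.append(b.seq)
            off += len(b)
        seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        return seq, offsets

    def set_seq(self, seq: np.ndarray) -> None:
        off = 0
        for b in self.seq_blocks():
            b.seq = seq[off : off + len(b)].copy()
            off += len(b)

    def has_nest(self) -> bool:
        return any(isinstance(b, _NestBlock) for b in self.blocks)


def _full_blocks(ltr: np.ndarray, internal: np.ndarray, u3_len: int) -> list[_Block]:
    return [
        _Block("u3", 0, u3_len, ltr[:u3_len].copy()),
        _Block("ru5", 0, len(ltr) - u3_len, ltr[u3_len:].copy()),
        _Block("int", 0, len(internal), internal.copy()),
        _Block("u3", 0, u3_len, ltr[:u3_len].copy()),
        _Block("ru5", 0, len(ltr) - u3_len, ltr[u3_len:].copy()),
    ]


# ---------------------------------------------------------------------------
# RIP


def rip_mutate_seq(
    seq: str | np.ndarray,
    p_cpa: float,
    p_other: float,
    rng: np.random.Generator,
) -> str | np.ndarray:
    """One RIP pass over a sequence: C->T and G->A, context-dependent.

    A cytosine followed by A mutates with ``p_cpa`` (the CpA preference); a
    guanine preceded by T mutates with ``p_cpa`` (TpG is CpA read from the
    other strand); any other C or G mutates with ``p_other``.  Context is
    evaluated on the input, so simultaneous mutations cannot create or
    destroy each other's context.
    """
    as_str = isinstance(seq, str)
    arr = _to_codes(seq) if as_str else seq.copy()
    n = len(arr)
    if n == 0:
        return seq
    nxt = np.full(n, 255, dtype=np.uint8)
    nxt[:-1] = arr[1:]
    prv = np.full(n, 255, dtype=np.uint8)
    prv[1:] = arr[:-1]
    cpa = (arr == _C) & (nxt == _A)
    tpg = (arr == _G) & (prv == _T)
    other_c = (arr == _C) & ~cpa
    other_g = (arr == _G) & ~tpg
    r = rng.random(n)
    arr[cpa & (r < p_cpa)] = _T
    arr[tpg & (r < p_cpa)] = _A
    arr[other_c & (r < p_other)] = _T
    arr[other_g & (r < p_other)] = _A
    return _to_str(arr) if as_str else arr


def _unit_pair_hsps(
    u: _Unit, v: _Unit, min_pident: float = 50.0, min_len: int = 30
) -> list[HitRecord]:
    """Exact homology HSPs between two units, query coordinates on ``u``."""
    hsps: list[HitRecord] = []
    _, uoffs = u.concat()
    _, voffs = v.concat()
    for ub, uoff in uoffs:
        for vb, voff in voffs:
            if ub.region != vb.region:
                continue
            s = max(ub.start, vb.start)
            e = min(ub.end, vb.end)
            if e - s < min_len:
                continue
            ua = ub.seq[s - ub.start : e - ub.start]
            va = vb.seq[s - vb.start : e - vb.start]
            matches = int((ua == va).sum())
            pident = 100.0 * matches / (e - s)
            if pident < min_pident:
                continue
            qs = uoff + (s - ub.start)
            ss = voff + (s - vb.start)
            hsps.append(
                HitRecord(
                    qid=str(u.uid), sid=str(v.uid), pident=pident,
                    alen=e - s, qstart=qs, qend=qs + (e - s),
                    sstart=ss, send=ss + (e - s),
                    bitscore=float(2 * matches - 3 * ((e - s) - matches)),
                    mismatch=(e - s) - matches,
                )
            )
    return hsps


def apply_rip(
    units: Sequence[_Unit], config: SimConfig, rng: np.random.Generator
) -> list[int]:
    """One RIP cycle over simulated copies; returns exposed unit ids.

    A copy is exposed iff it is at least ``rip_min_len`` long and shares at
    least ``rip_min_id`` merged identity with some other copy — computed
    with the same HSP-merging machinery the classifier uses, so the
    simulator and the classifier agree on what "similar" means.  Both
    members of a qualifying pair are mutable.
    """
    eligible = [u for u in units if u.own_len() >= config.rip_min_len]
    exposed: set[int] = set()
    for i, u in enumerate(eligible):
        for v in eligible[i + 1 :]:
            if u.uid in exposed and v.uid in exposed:
                continue
            hsps = _unit_pair_hsps(u, v)
            if not hsps:
                continue
            score = merge_hsps(hsps, ref_len=u.own_len())
            if score.merged_identity >= config.rip_min_id:
                exposed.add(u.uid)
                exposed.add(v.uid)
    for u in units:
        if u.uid in exposed:
            seq, _ = u.concat()
            u.set_seq(rip_mutate_seq(seq, config.rip_p_cpa, config.rip_p_other, rng))
            u.rip_exposures += 1
    return sorted(exposed)


# ---------------------------------------------------------------------------
# Structural events


def make_solo_ltr(unit: _Unit, rng: np.random.Generator) -> int:
    """Recombine a full copy's two LTRs, leaving a solo-LTR.

    The solo is the crossover product: positions before a uniform breakpoint
    come from the 5' LTR, the rest from the 3' LTR.  The internal region and
    one LTR's worth of sequence are lost; the flanking TSD (outside the
    unit) is untouched.  Returns the breakpoint.
    """
    if unit.cls != "full" or unit.has_nest():
        raise ValueError("solo-LTR formation requires an intact full copy")
    blocks = unit.seq_blocks()
    u3a, ru5a, _, u3b, ru5b = blocks
    ltr5 = np.concatenate([u3a.seq, ru5a.seq])
    ltr3 = np.concatenate([u3b.seq, ru5b.seq])
    bp = int(rng.integers(0, len(ltr5) + 1))
    solo = np.concatenate([ltr5[:bp], ltr3[bp:]])
    u3_len = len(u3a)
    unit.blocks = [
        _Block("u3", 0, u3_len, solo[:u3_len].copy()),
        _Block("ru5", 0, len(solo) - u3_len, solo[u3_len:].copy()),
    ]
    unit.cls = "solo"
    return bp


def _fragment(unit: _Unit, rng: np.random.Generator) -> None:
    """Truncate a copy from one end by a uniform 20-80% of its length."""
    total = unit.own_len()
    cut = int(total * rng.uniform(0.2, 0.8))
    if cut == 0 or cut >= total:
        return
    from_left = bool(rng.integers(0, 2))
    blocks = unit.seq_blocks()
    if not from_left:
        blocks = blocks[::-1]
    remaining = cut
    new_blocks: list[_Block] = []
    for b in blocks:
        if remaining >= len(b):
            remaining -= len(b)
            continue
        if remaining > 0:
            if from_left:
                b = _Block(b.region, b.start + remaining, b.end, b.seq[remaining:].copy())
            else:
                b = _Block(b.region, b.start, b.end - remaining, b.seq[:-remaining].copy())
            remaining = 0
        new_blocks.append(b)
    if not from_left:
        new_blocks = new_blocks[::-1]
    unit.blocks = new_blocks
    unit.cls = "fragment"


def _neutral_mutate(unit: _Unit, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    seq, _ = unit.concat()
    hit = rng.random(len(seq)) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        seq[hit] = (seq[hit] + shift) % 4
        unit.set_seq(seq)


# ---------------------------------------------------------------------------
# Simulation result


@dataclass(frozen=True)
class SimCopy:
    """One terminal-repeat occurrence with its ground truth."""

    id: str
    subfamily: str
    copy_class: str  # full | solo | fragment | nested
    interval: GenomicInterval
    rip_exposures: int
    ltr_start: int  # founder LTR coordinates covered by this copy
    ltr_end: int
    codes: np.ndarray = field(compare=False, repr=False)

    @property
    def sequence(self) -> str:
        return _to_str(self.codes)

    @property
    def length(self) -> int:
        return self.ltr_end - self.ltr_start


@dataclass
class SimResult:
    """Simulated genome with full ground truth for pipeline testing."""

    config: SimConfig
    genome: SequenceRecord
    copies: list[SimCopy]
    full_copies: list[FullCopyAnnotation]

    def copy_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(id=c.id, seq=c.sequence) for c in self.copies]

    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.copies}

    def truth_labels(self) -> dict[str, str]:
        return {c.id: c.subfamily for c in self.copies}

    def truth_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": c.id,
                    "subfamily": c.subfamily,
                    "copy_class": c.copy_class,
                    "contig": c.interval.contig,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "strand": c.interval.strand,
                    "rip_exposures": c.rip_exposures,
                }
                for c in self.copies
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], outdir / "genome.fa")
        write_fasta(self.copy_records(), outdir / "copies.fa")
        self.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_tabular_hits(truth_hits(self), outdir / "hits.tsv")
        write_bed(
            [fc.element for fc in self.full_copies] +
            [fc.ltr5 for fc in self.full_copies] +
            [fc.ltr3 for fc in self.full_copies],
            outdir / "full_copies.bed",
        )


# ---------------------------------------------------------------------------
# Main simulation


def simulate_family(config: SimConfig) -> SimResult:
    """Run the forward simulation described in the module docstring."""
    rng = np.random.default_rng(config.seed)
    n = config.n_copies
    genome_len = config.genome_len or (2000 + 120 * n)
    min_gap = config.tsd_len + 20
    n_slots = len(range(100, genome_len - 100 - config.tsd_len, min_gap))
    if n_slots < n:
        raise ValueError(f"genome_len={genome_len} too small for {n} insertions")

    # Founders: one ancestral LTR (with a TATA-box opening the conserved
    # R+U5 half) and internal region; subfamilies differ by U3 resampling.
    anc_ltr = rng.integers(0, 4, config.ltr_len).astype(np.uint8)
    tata = _to_codes(TATA_BOX)
    anc_ltr[config.u3_len : config.u3_len + len(tata)] = tata
    internal = rng.integers(0, 4, config.internal_len).astype(np.uint8)
    founder_ltrs = []
    for _ in range(config.n_subfamilies):
        ltr = anc_ltr.copy()
        hit = rng.random(config.u3_len) < config.u3_divergence
        shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        ltr[:config.u3_len][hit] = (ltr[:config.u3_len][hit] + shift) % 4
        founder_ltrs.append(ltr)

    units: list[_Unit] = []
    uid = 0
    for k in range(config.n_subfamilies):
        for _ in range(config.copies_per_subfamily):
            units.append(
                _Unit(uid, k, "full", _full_blocks(founder_ltrs[k], internal, config.u3_len))
            )
            uid += 1

    background = rng.integers(0, 4, genome_len).astype(np.uint8)
    positions = np.sort(
        rng.choice(
            np.arange(100, genome_len - 100 - config.tsd_len, min_gap),
            size=n,
            replace=False,
        )
    )

    # Evolution: per cycle, neutral mutation, then structural events, then RIP.
    for _ in range(config.n_cycles):
        for u in units:
            _neutral_mutate(u, config.neutral_mut_rate, rng)
        for u in list(units):
            r = rng.random()
            if u.cls == "full" and not u.has_nest():
                if r < config.p_solo:
                    make_solo_ltr(u, rng)
                elif r < config.p_solo + config.p_frag:
                    _fragment(u, rng)
                elif r < config.p_solo + config.p_frag + config.p_nest:
                    _insert_nested(u, units, config, rng)
            elif not u.has_nest() and r < config.p_frag:
                _fragment(u, rng)
        apply_rip(units, config, rng)

    top = [u for u in units if not u.nested]
    return _materialize(config, background, positions, top, units)


def _insert_nested(host: _Unit, units: list[_Unit], config: SimConfig,
                   rng: np.random.Generator) -> None:
    """Transpose a fresh copy of a random full element into ``host``."""
    donors = [u for u in units if u.cls == "full" and not u.nested and u is not host]
    if not donors:
        return
    donor = donors[int(rng.integers(0, len(donors)))]
    child = _Unit(
        uid=max(u.uid for u in units) + 1,
        subfamily=donor.subfamily,
        cls="full",
        blocks=_copymod.deepcopy(donor.seq_blocks()),
        nested=True,
    )
    # a new insertion carries two identical LTRs copied from one template
    blocks = child.blocks
    blocks[3].seq = blocks[0].seq.copy()
    blocks[4].seq = blocks[1].seq.copy()
    # insert at a uniform position of the host's internal region, so the
    # displaced terminal repeat context is the classic nested-copy case
    targets = [
        (i, b) for i, b in enumerate(host.blocks)
        if isinstance(b, _Block) and b.region == "int"
        and len(b) > 2 * config.tsd_len + 2
    ]
    if not targets:
        return
    units.append(child)
    idx, b = targets[int(rng.integers(0, len(targets)))]
    cut = int(rng.integers(config.tsd_len + 1, len(b) - config.tsd_len))
    left = _Block(b.region, b.start, b.start + cut, b.seq[:cut].copy())
    right = _Block(b.region, b.start + cut, b.end, b.seq[cut:].copy())
    tsd = right.seq[: config.tsd_len].copy()
    host.blocks = (
        host.blocks[:idx] + [left, _NestBlock(child, tsd), right] + host.blocks[idx + 1 :]
    )


def _materialize(
    config: SimConfig,
    background: np.ndarray,
    positions: np.ndarray,
    top_units: list[_Unit],
    all_units: list[_Unit],
) -> SimResult:
    parts: list[np.ndarray] = []
    cursor = 0
    prev = 0
    block_pos: dict[int, list[tuple[_Block, int]]] = {u.uid: [] for u in all_units}

    def emit_unit(u: _Unit) -> None:
        nonlocal cursor
        for b in u.blocks:
            if isinstance(b, _NestBlock):
                parts.append(b.tsd)
                cursor += len(b.tsd)
                emit_unit(b.child)
            else:
                block_pos[u.uid].append((b, cursor))
                parts.append(b.seq)
                cursor += len(b)

    for u, p in zip(top_units, positions[: len(top_units)]):
        p = int(p)
        parts.append(background[prev:p])
        cursor += p - prev
        site = background[p : p + config.tsd_len].copy()
        parts.append(site)
        cursor += len(site)
        emit_unit(u)
        prev = p
    parts.append(background[prev:])
    genome_seq = np.concatenate(parts)
    genome = SequenceRecord(id=CONTIG, seq=_to_str(genome_seq))

    subfam_name = lambda k: f"SF{k + 1}"
    copies: list[SimCopy] = []
    full_annotations: list[FullCopyAnnotation] = []
    for u in all_units:
        placed = block_pos[u.uid]
        if not placed:
            continue
        if u.cls == "full":
            cls = "nested" if u.nested else "full"
        elif u.cls == "solo":
            cls = "nested" if u.nested else "solo"
        else:
            cls = "fragment"
        # maximal runs of LTR-space blocks become terminal-repeat copies
        run: list[tuple[_Block, int]] = []
        runs: list[list[tuple[_Block, int]]] = []
        for b, g in placed:
            contiguous = bool(run) and run[-1][1] + len(run[-1][0]) == g
            if b.region in ("u3", "ru5") and (not run or contiguous):
                run.append((b, g))
            else:
                if run:
                    runs.append(run)
                run = [(b, g)] if b.region in ("u3", "ru5") else []
        if run:
            runs.append(run)
        for run in runs:
            codes = np.concatenate([b.seq for b, _ in run])
            if len(codes) < 30:
                continue
            gstart = run[0][1]
            gend = run[-1][1] + len(run[-1][0])
            first, last = run[0][0], run[-1][0]
            ls = first.start if first.region == "u3" else config.u3_len + first.start
            le = last.end if last.region == "u3" else config.u3_len + last.end
            iv = GenomicInterval(CONTIG, gstart, gend, "+")
            copies.append(
                SimCopy(
                    id=f"{CONTIG}_{gstart + 1}-{gend}",
                    subfamily=subfam_name(u.subfamily),
                    copy_class=cls,
                    interval=iv,
                    rip_exposures=u.rip_exposures,
                    ltr_start=ls,
                    ltr_end=le,
                    codes=codes,
                )
            )
        if u.cls == "full":
            blocks = [b for b, _ in placed]
            if [b.region for b in blocks] == ["u3", "ru5", "int", "u3", "ru5"]:
                estart = placed[0][1]
                eend = placed[-1][1] + len(placed[-1][0])
                l5s, l5e = placed[0][1], placed[1][1] + len(blocks[1])
                ins, ine = placed[2][1], placed[2][1] + len(blocks[2])
                l3s, l3e = placed[3][1], placed[4][1] + len(blocks[4])
                if (l5e, ine, l3e) == (ins, l3s, eend):  # contiguous (no nest split)
                    label = subfam_name(u.subfamily)
                    full_annotations.append(
                        FullCopyAnnotation(
                            element=GenomicInterval(CONTIG, estart, eend, "+",
                                                    name=f"{CONTIG}_{estart + 1}-{eend}"),
                            ltr5=GenomicInterval(CONTIG, l5s, l5e, "+",
                                                 name=f"{CONTIG}_{l5s + 1}-{l5e}"),
                            ltr3=GenomicInterval(CONTIG, l3s, l3e, "+",
                                                 name=f"{CONTIG}_{l3s + 1}-{l3e}"),
                            internal=GenomicInterval(CONTIG, ins, ine, "+"),
                            ltr5_label=label,
                            ltr3_label=label,
                        )
                    )

    copies.sort(key=lambda c: (c.interval.start, c.interval.end))
    return SimResult(config=config, genome=genome, copies=copies,
                     full_copies=full_annotations)


# ---------------------------------------------------------------------------
# Exact hits


def truth_hits(
    sim: SimResult,
    min_pident: float = 50.0,
    min_len: int = 30,
    coalesce_gap: float = 15.0,
) -> list[HitRecord]:
    """Exact all-vs-all hits between the simulated terminal-repeat copies.

    For every pair, the shared founder-coordinate span is split at the
    U3/conserved boundary, identity is the exact per-site identity, and
    adjacent segments whose identities differ by at most ``coalesce_gap``
    points are reported as one HSP — so identical copies yield one
    full-length hit, while a diverged U3 breaks off into its own HSP, as a
    local aligner would report it.  Segments below ``min_pident`` or
    shorter than ``min_len`` are then suppressed, emulating the
    sensitivity floor of a real search.  Self hits and both directions are
    emitted, as an all-vs-all search would.
    """
    u3_len = sim.config.u3_len
    boundaries = (0, u3_len, sim.config.ltr_len)
    hits: list[HitRecord] = []

    def segments(a: SimCopy, b: SimCopy) -> list[list]:
        lo = max(a.ltr_start, b.ltr_start)
        hi = min(a.ltr_end, b.ltr_end)
        segs = []
        for i in range(len(boundaries) - 1):
            s = max(lo, boundaries[i])
            e = min(hi, boundaries[i + 1])
            if e <= s:
                continue
            qa = a.codes[s - a.ltr_start : e - a.ltr_start]
            qb = b.codes[s - b.ltr_start : e - b.ltr_start]
            segs.append([s, e, int((qa == qb).sum())])
        merged: list[list] = []
        for seg in segs:
            if merged and merged[-1][1] == seg[0]:
                prev = merged[-1]
                p_prev = 100.0 * prev[2] / (prev[1] - prev[0])
                p_seg = 100.0 * seg[2] / (seg[1] - seg[0])
                if abs(p_prev - p_seg) <= coalesce_gap:
                    prev[1] = seg[1]
                    prev[2] += seg[2]
                    continue
            merged.append(seg)
        return merged

    cps = sim.copies
    for i, a in enumerate(cps):
        hits.append(
            HitRecord(qid=a.id, sid=a.id, pident=100.0, alen=a.length,
                      qstart=0, qend=a.length, sstart=0, send=a.length,
                      bitscore=float(2 * a.length))
        )
        for b in cps[i + 1 :]:
            for s, e, matches in segments(a, b):
                if e - s < min_len:
                    continue
                pident = 100.0 * matches / (e - s)
                if pident < min_pident:
                    continue
                qs, ss = s - a.ltr_start, s - b.ltr_start
                h = HitRecord(
                    qid=a.id, sid=b.id, pident=pident, alen=e - s,
                    qstart=qs, qend=qs + (e - s), sstart=ss, send=ss + (e - s),
                    bitscore=float(2 * matches - 3 * ((e - s) - matches)),
                    mismatch=(e - s) - matches,
                )
                hits.append(h)
                hits.append(
                    replace(h, qid=h.sid, sid=h.qid, qstart=h.sstart,
                            qend=h.send, sstart=h.qstart, send=h.qend)
                )
    return hits


# ---------------------------------------------------------------------------
# Smith-Waterman path (no external aligner)

_MASK = "X"


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    alphabet = "ACGTN" + _MASK
    matrix = np.full((len(alphabet), len(alphabet)), mismatch)
    for i, c in enumerate("ACGT"):
        matrix[i, i] = match
    mi = alphabet.index(_MASK)
    matrix[mi, :] = -1e6
    matrix[:, mi] = -1e6
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.Array(
        alphabet=alphabet, dims=2, data=matrix
    )
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
    min_score: float = 20.0,
    max_hsps: int = 25,
) -> list[HitRecord]:
    """Iterated Smith-Waterman HSP extraction between two sequences.

    The optimal local alignment is taken as an HSP, its query span masked,
    and the alignment repeated until the score drops below ``min_score``
    (or ``max_hsps`` HSPs were found).  Identity is computed over aligned
    columns, gaps included, like BLAST's pident.
    """
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    query = list(a.seq.upper())
    target = b.seq.upper()
    hits: list[HitRecord] = []
    for _ in range(max_hsps):
        alignments = aligner.align("".join(query), target)
        if len(alignments) == 0 or alignments.score < min_score:
            break
        aln = alignments[0]
        qsegs, ssegs = aln.aligned
        qs, qe = int(qsegs[0][0]), int(qsegs[-1][1])
        ss, se = int(ssegs[0][0]), int(ssegs[-1][1])
        identities = 0
        columns = 0
        gaps = 0
        for (q0, q1), (s0, s1) in zip(qsegs, ssegs):
            for qi, si in zip(range(q0, q1), range(s0, s1)):
                columns += 1
                if query[qi] == target[si]:
                    identities += 1
        for k in range(1, len(qsegs)):
            gaps += (qsegs[k][0] - qsegs[k - 1][1]) + (ssegs[k][0] - ssegs[k - 1][1])
        columns += gaps
        hits.append(
            HitRecord(
                qid=a.id, sid=b.id,
                pident=100.0 * identities / columns,
                alen=columns, qstart=qs, qend=qe, sstart=ss, send=se,
                bitscore=float(aln.score), mismatch=columns - gaps - identities,
                gapopen=sum(1 for k in range(1, len(qsegs))
                            if qsegs[k][0] > qsegs[k - 1][1] or ssegs[k][0] > ssegs[k - 1][1]),
            )
        )
        for i in range(qs, qe):
            query[i] = _MASK
    return sorted(hits, key=lambda h: -h.bitscore)
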