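"""Shared fixtures: tiny hand-built RepeatMasker scans and annotations."""

from __future__ import annotations

import pytest

from ripnet.core_io import GenomicInterval
from ripnet.copy_annotation import FullCopyAnnotation

RM_HEADER = (
    "   SW   perc perc perc  query     position in query              matching"
    "  repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin  end          (left)   repeat"
    "        class/family  begin  end  (left)   ID\n"
    "\n"
)


def rm_row(score, contig, begin, end, name, strand="+", rm_id=1, star=False):
    """One RepeatMasker .out row (1-based inclusive coordinates)."""
    fields = [
        str(score), "10.1", "0.5", "0.3", contig, str(begin), str(end),
        "(0)", strand, name, "LTR/Gypsy", "1", str(end - begin + 1), "(0)",
        str(rm_id),
    ]
    if star:
        fields.append("*")
    return " ".join(fields) + "\n"


def make_full_copy(contig, start, ltr_len=400, internal_len=6600, strand="+",
                   label5=None, label3=None):
    end = start + 2 * ltr_len + internal_len
    left = GenomicInterval(contig, start, start + ltr_len, strand)
    right = GenomicInterval(contig, end - ltr_len, end, strand)
    ltr5, ltr3 = (left, right) if strand == "+" else (right, left)
    return FullCopyAnnotation(
        element=GenomicInterval(contig, start, end, strand),
        ltr5=ltr5, ltr3=ltr3,
        internal=GenomicInterval(contig, start + ltr_len, end - ltr_len, strand),
        ltr5_label=label5, ltr3_label=label3,
    )


@pytest.fixture
def rm_fixture(tmp_path):
    """The 12-row RepeatMasker scan exercising all post-processing rules.

    Hand-derived outcome: 2 hits dropped by the length filter, 1 dropped as
    a solo overlapping a curated full-copy boundary, 1 dropped for spanning
    a whole element; 3 counted full (two 5', one 3'), 2 nested, 3
    solo/fragment.
    """
    rows = [
        rm_row(300, "ctg1", 30001, 30200, "LTR1", rm_id=1),   # len 200: dropped
        rm_row(300, "ctg1", 31001, 31250, "LTR1", rm_id=2),   # len 250: dropped (strict)
        rm_row(900, "ctg1", 991, 1380, "LTR1", rm_id=3),      # FULL_5P on e1
        rm_row(900, "ctg1", 8101, 8500, "LTR1", rm_id=4),     # FULL_3P on e1
        rm_row(700, "ctg1", 4001, 4400, "LTR2", rm_id=5),     # NESTED in e1
        rm_row(700, "ctg1", 15001, 15400, "LTR2", rm_id=6),   # SOLO_FRAGMENT
        rm_row(700, "ctg1", 20101, 20500, "LTR1", rm_id=7),   # solo on curated boundary: dropped
        rm_row(700, "ctg3", 101, 500, "LTR3", rm_id=8),       # SOLO (unannotated contig)
        rm_row(900, "ctg2", 5001, 5400, "LTR2", rm_id=9, strand="C"),  # FULL_5P on e2
        rm_row(700, "ctg2", 6001, 6500, "LTR1", rm_id=10),    # NESTED in e2
        rm_row(950, "ctg1", 901, 8500, "LTR1", rm_id=11),     # spans e1: dropped
        rm_row(700, "ctg2", 201, 600, "LTR3", rm_id=12, star=True),  # SOLO
    ]
    out_path = tmp_path / "scan.out"
    out_path.write_text(RM_HEADER + "".join(rows))

    full_copies = [
        make_full_copy("ctg1", 1000),
        make_full_copy("ctg2", 5000),
    ]
    curated = [GenomicInterval("ctg1", 20000, 20400, "+", name="LTR1")]
    expected = {
        "full": 3,
        "solo_fragment": 5,  # includes the 2 nested hits
        "nested_detail": 2,
        "dropped_min_length": 2,
        "dropped_boundary": 1,
        "dropped_spans": 1,
    }
    return out_path, full_copies, curated, expected
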