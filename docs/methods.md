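# Methods

This note documents the models, parameter choices and numerical
conventions behind `ripnet`, and what the simulation-based tests do and
do not demonstrate about real data.

## Coordinates and formats

All intervals are held internally as 0-based, half-open with an explicit
strand. BLAST tabular (outfmt 6) and RepeatMasker `.out` files are
1-based inclusive and are converted at the parsing boundary; minus-strand
subject hits (sstart > send) are stored with ascending coordinates and
strand `-`. Copy identifiers follow the `contig_start-end` convention
(1-based inclusive); since contig names routinely contain underscores,
the identifier is split at the *rightmost* underscore. A reversed
coordinate pair in an identifier (`..._300-250`) marks a minus-oriented
copy and is normalized. `start == end` is rejected as degenerate. GC
content excludes N and ambiguity codes from the denominator so that RIP
statistics of partially masked copies are not diluted.

## Merged pair similarity

The unit of similarity is the unordered sequence pair, not the HSP.
After removing self hits, the direction (query, subject) with the larger
total bitscore is retained with all of its HSPs (ties keep the
lexicographically smaller direction, for reproducibility). HSPs are
projected onto query coordinates and every covered base is assigned to
exactly one HSP — the one with the highest identity, then highest
bitscore, then smallest query start. Merged identity is the
assigned-length-weighted mean of HSP identities (hence always bounded by
the min and max HSP identity); coverage is the union length over a
reference length.

Choices left open by the underlying pipeline description and fixed here:

- **Coverage denominator**: the query length of the retained direction,
  configurable to the shorter or longer sequence (`coverage_ref`). The
  query default matches a one-direction-per-pair cleaning step.
- **Overlap resolution**: per-base best-identity assignment. Any fixed
  tie-break chain would do; the one above makes output deterministic.
- HSPs are never chained or gap-penalized — only union arithmetic.
- Mixed-strand HSP sets for one pair are allowed (inversions occur in
  real dotplots); strand does not enter the merge.

## Network and communities

Edges require merged identity **and** coverage strictly above their
thresholds (80/80 by default; 80/70 is the internal-region preset); the
strictness follows the "> 80%" convention and can be relaxed to ≥.
Isolated nodes are kept, so unconnected copies surface as unclassified
rather than silently vanishing.

Community detection is unweighted greedy modularity maximization
(Clauset–Newman–Moore), delegated to NetworkX on a node-sorted copy of
the graph so repeated runs are identical. The modularity implementation
used for reporting and testing is the direct formula
Q = Σ_c [e_c/m − (d_c/2m)²] and is cross-checked against NetworkX's in
the tests; the greedy result is checked against an exhaustive
set-partition oracle on small graphs. An edgeless graph has undefined
modularity; community detection then returns singletons.

Both community-size filter readings are supported — keep size ≥ 5
(default; "fewer than five are unclassified") and keep size > 5 — via
`keep_rule`. The centroid of a community is the member with the highest
degree *within the community's induced subgraph*, so edges between
interconnected communities do not distort exemplar choice; ties fall to
the largest summed merged identity, then the smallest id.

## Subfamily naming, comparison, rogues

Merge rules (`"1.1,1.2 -> LTR1"`) pool communities into joint
subfamilies; remaining communities are named by pooled-size rank with a
configurable prefix, skipping user-taken names. Classification
comparison counts label disagreements over the copies classified in the
reference classification; ids missing from the other classification
count as disagreements and are also reported separately.

Rogue detection operationalizes "grouping outside the main subfamily
clade": for subfamily S the main clade is the internal node with the
most S members among clades whose leaves are *strictly* more than 50% S
(the strictness matters: at exactly half, the root of a balanced
two-subfamily tree would swallow everything); ties prefer larger clades,
then clades closer to the root. S members outside the main clade are
rogues; a subfamily with no qualifying clade is reported entirely rogue.
The purity threshold is configurable. This is a reproducible rule, not a
reconstruction of any manual inspection, and it is deliberately simple:
it knows nothing about branch lengths or support values.

## Copy-context annotation and RepeatMasker post-processing

Haplotype merging joins same-contig, same-strand hits with gaps ≤
`merge_gap` (default 1000 bp — the upstream script's value is not
published, so this is an explicit parameter), drops merged haplotypes
shorter than `min_size` and extends survivors by `flank`, clipping at
contig ends and re-coalescing intervals that the extension brought
within `merge_gap` of each other (this makes the operation idempotent).
The 4 kb / 2 kb defaults are the internal-region retrieval settings.

A terminal-repeat occurrence is FULL_5P/FULL_3P if it overlaps the
corresponding LTR of an annotated full element (LTR intervals padded by
`end_tolerance`, default 10 bp — "overlaps the end" is not quantified
upstream), NESTED if it overlaps only an internal region, SOLO_FRAGMENT
otherwise; a hit overlapping both ends of one element spans the whole
copy and is flagged for curation. On minus-strand elements the 5' LTR is
the right-hand interval.

RepeatMasker post-processing applies, in order: (1) drop hits with
genomic span ≤ 250 bp (strictly greater survives; short hits cannot
reach the subfamily-diagnostic U3 region), (2) context classification as
above, (3) removal of putative solo-LTRs overlapping a curated full-copy
terminal repeat — any overlap of at least 1 bp counts, as no overlap
fraction is published — and (4) per-species × per-subfamily counts with
nested hits tallied in the solo/fragment column (their context is kept
in the per-hit table). Every input hit is either counted once or dropped
by exactly one rule.

## The simulator

The simulator emulates the curated data the classifier was designed for:
one LTR-retrotransposon family whose subfamilies share a conserved
3'-half of the terminal repeat (R+U5, opening with a fixed TATA-box
motif) and an internal region, but differ in the U3 half.

- **Founders.** One ancestral LTR (default 400 bp, U3 = 200 bp) and
  internal region (6600 bp) are drawn uniformly; each subfamily
  resamples U3 sites independently with probability `u3_divergence` to a
  random different base. At the default 0.5, two subfamily LTRs share
  ≈ 67% identity (per site: (1−d)² + d²/3 in U3), below the 80%
  threshold, while copies within a subfamily start identical.
- **Insertion.** All copies insert at cycle 0 ("burst") with two
  *identical* LTRs and a duplicated 5 bp target site, at uniformly
  spaced positions in a random background contig.
- **Per cycle**: neutral substitution (default 10⁻⁴/site), solo-LTR
  formation (LTR-LTR recombination at a uniform breakpoint: the solo is
  5'-LTR prefix + 3'-LTR suffix; default 0.02/copy/cycle), fragmentation
  (uniform 20–80% truncation from a random end; 0.01), nested insertion
  (a fresh element, copied from a random intact donor with its LTR pair
  re-identicalized, into a uniform position of a host's internal region;
  default rate 0), and RIP.
- **RIP.** A copy is exposed in a cycle iff it is ≥ `rip_min_len`
  (400 bp) long and shares ≥ `rip_min_id` (80%) merged identity with at
  least one other copy — evaluated with the *same* HSP-merging machinery
  the classifier uses, so simulator and classifier agree on what
  "similar" means. Exposed copies mutate C→T with `rip_p_cpa` when
  followed by A, G→A with `rip_p_cpa` when preceded by T (the same
  dinucleotide on the other strand) and with `rip_p_other` at other C/G
  sites; the context is read from the pre-mutation sequence. RIP never
  creates C or G, so per-copy GC is non-increasing. Per-site RIP rates
  in any real species are not measured quantities here; the defaults
  (0.05 / 0.01) are chosen to produce visible but not saturating
  degradation over a handful of cycles.

Every surviving base is tracked in founder coordinates, so `truth_hits`
emits *exact* pairwise HSPs: shared spans are split at the U3 boundary,
adjacent segments within 15 identity points are reported as one HSP (an
aligner would not split a homogeneous alignment), and segments below 50%
identity or 30 bp are suppressed, emulating search sensitivity. A
Smith-Waterman path (`local_align`, Biopython's PairwiseAligner with
match +1, mismatch −2, gap open 5, extend 2, iterated query masking)
provides an independent alignment route; on ungapped, lightly diverged
pairs the two agree to within ~2 identity points, while on strongly
diverged blocks Smith-Waterman legitimately trims to high-scoring cores.

**What the simulation does not model**: indels (outside whole-segment
loss), selection, transposition after the initial burst, recombination
hotspots, inter-element template switching, and RIP's occasional
targeting of short interspersed repeats. Passing the recovery tests
therefore shows the pipeline is correct under clean burst-and-degrade
dynamics, not that real curated datasets — with alignment ambiguity and
manual boundary calls — will classify with the same accuracy.

## Problem sizes and test design

The test suite and the acceptance script run the recovery experiments at
3 and 5 subfamilies × 20 copies (≈ 115–200 terminal-repeat copies, three
RIP cycles) and the GC-signature experiment at 120 elements with
`rip_min_len` = 450 > `ltr_len` = 400, so solos escape RIP while full
elements remain targets; both finish in seconds and are stable across
seeds. Oracles are independent re-derivations: a per-base sweep for HSP
merging (exact agreement demanded to 10⁻⁹), exhaustive set-partition
enumeration per connected component for modularity (cross-component
merges only add a degree-product penalty, so the optimum respects
components), and hand-derived tables for the RepeatMasker fixture.
Determinism is asserted byte-for-byte on all TSV/FASTA outputs for fixed
seeds; all randomness flows from one `numpy` generator per simulation.
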