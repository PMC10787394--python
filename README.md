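# ripnet

Consensus-free, RIP-aware classification of transposable-element (TE)
copies into subfamilies using sequence similarity networks — with
companion tools for LTR copy-context annotation, RepeatMasker output
post-processing, and a forward simulator of LTR-retrotransposon families
under repeat-induced point mutation (RIP).

## Who this is for

Curators of repeat libraries in fungal (and other RIP-affected) genomes.
RIP stochastically hypermutates C→T (preferring CpA/TpG dinucleotides) in
any repeat longer than roughly 400 bp sharing roughly 80% identity with
another copy. Under that regime a consensus sequence is a poor summary of
a TE family: copies are degraded to different degrees, fragmented, nested
and recombined, and similarity-threshold clustering (the classic
80-80-80 rule as implemented by greedy sequence clusterers) shatters a
single family into hundreds of clusters. `ripnet` instead classifies the
copies themselves, with no consensus, from the structure of their
pairwise-similarity network.

## The method

1. **Merged pair similarity.** From an all-vs-all BLASTn search (outfmt
   6), self hits are removed and, for each pair, only the direction with
   the higher total bitscore is kept. All HSPs of a pair are then merged
   over the non-overlapping union of their query intervals: each covered
   base is assigned to the best HSP covering it (highest identity, then
   highest bitscore, then leftmost), giving

   *merged identity* = Σᵢ pᵢ·ℓᵢ / Σᵢ ℓᵢ,  *coverage* = 100·Σᵢ ℓᵢ / L,

   where pᵢ and ℓᵢ are the identity and assigned length of HSP *i* and L
   the reference length. This recovers the similarity of fragmented,
   RIP-degraded pairs that a top-hit-only score underestimates.
2. **Sequence similarity network (SSN).** Nodes are copies; an edge
   connects pairs with merged identity > 80% **and** coverage > 80%
   (70% coverage is the preset for internal-region networks).
3. **Communities.** Unweighted greedy modularity maximization
   (Clauset–Newman–Moore) partitions the network; communities with fewer
   than five members are set aside as unclassified. Near-duplicate
   communities can be merged into joint subfamilies via an explicit merge
   map; each kept community is summarized by its **degree centroid** (the
   member with the most within-community edges), the exemplar used for
   downstream masking.
4. **Audit.** Classifications can be compared (disagreement rate), and
   copies falling outside their subfamily's main clade in an ML phylogeny
   are flagged as **rogues** (main clade = the clade with the most
   subfamily members among clades that are majority that subfamily).
5. **Copy context.** Genome hits are merged into haplotypes (minimum
   size, flank extension); terminal repeats are annotated as full-copy
   5'/3' LTRs, nested insertions, or solo/fragment copies; RepeatMasker
   scans against subfamily exemplars are filtered (>250 bp), context-
   classified and tallied per species and subfamily.
6. **Simulator.** A forward simulator of an LTR-retrotransposon family —
   subfamily founders diverged in the U3 half of the LTR, identical LTR
   pairs and target-site duplications at insertion, then cycles of
   neutral mutation, solo-LTR formation, fragmentation, nesting and RIP —
   emits a genome, copy FASTA, truth tables and *exact* hit tables, so
   the whole pipeline is testable end to end without external tools.

## Worked example

Simulate a three-subfamily family and classify it back:

```bash
$ ripnet simulate --seed 11 --out sim/
115 terminal-repeat copies (110 on full elements) in a 418500 bp genome -> sim/

$ ripnet score --hits sim/hits.tsv --fasta sim/copies.fa --out pairs.tsv
scored 6555 pairs -> pairs.tsv

$ ripnet network --pairs pairs.tsv --fasta sim/copies.fa --out net/
115 nodes, 2149 edges; 3 communities (Q=0.6652), 3 kept, 0 copies unclassified -> net/

$ ripnet classify --hits sim/hits.tsv --fasta sim/copies.fa --out classes.tsv
3 communities -> 3 subfamilies; 0 copies unclassified -> classes.tsv
```

The simulator planted three subfamilies of 20 elements each (their
terminal repeats appear as ~115 copies: two LTRs per intact full element,
plus solo-LTRs and fragments created during the mutation cycles). The
network at the 80/80 thresholds splits cleanly into 3 communities —
modularity Q = 0.67 — and every copy is assigned to the subfamily it was
simulated from (`classes.tsv`, columns `id`, `label`). `net/partition.tsv`
additionally reports each copy's degree and flags the community
centroids.

The same commands run on real data: `--hits` takes any 12-column BLASTn
tabular file and `--fasta` the copy sequences. `ripnet rogues`,
`ripnet compare`, `ripnet rm-post`, `ripnet haplotypes` and
`ripnet annotate` cover the audit and annotation steps.

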