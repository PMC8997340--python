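# Methods

`taxodelim` implements a polyphasic genus-delimitation workflow for
prokaryotes (its defaults are tuned to filamentous cyanobacteria of the
family Leptolyngbyaceae): marker-gene identity, 16S-23S ITS architecture
and helix structure, genome-wide divergence indices, single-copy-ortholog
phylogenomics, a best-hit-taxonomy HGT screen, and a rank decision that
applies published thresholds. This note records the models, the parameters
that matter, the numerical conventions, and what the synthetic fixtures do
and do not demonstrate.

## Pairwise alignment and search

All protein-level metrics are built on optimal pairwise alignment
(Needleman-Wunsch global, Smith-Waterman local) under affine gaps, where a
gap of length L costs `gap_open + gap_extend * L`. Defaults are the
conventional search settings: nucleotide match +5 / mismatch −4, gaps
10/0.5; protein BLOSUM62, gaps 11/1. The DP itself is delegated to
Biopython's `PairwiseAligner`; this package owns the scoring conventions
and the statistics. Traceback is deterministic (Biopython's fixed
alignment order); alignment *scores* are the tested contract and are
verified against an independent Gotoh DP in the test suite.

The built-in database search is seed-and-extend: exact k-mer seeding (k=4
protein, k=11 nucleotide), a two-seed-occurrence candidate filter, then a
full local alignment of query against each candidate. E-values follow
Karlin-Altschul, `E = K·m·n·exp(−λS)`, with fixed documented constants
(λ=0.267, K=0.041 for gapped BLOSUM62; λ=1.28, K=0.46 for the nucleotide
scheme) and n = summed subject lengths; since no score statistics are
fitted, e-values are reproducible but approximate. Hits are totally
ordered by (evalue asc, bitscore desc, subject id). `percent_similarity`
counts positive-scoring columns (substitution score > 0), matching the
"similarity" wording of the HGT rule; an identity-based reading is
available as a switch. Query coverage is aligned query residues over query
length, gaps excluded. Searches with seeding disabled are exhaustive and
exactly reproduce the all-vs-all hit set; an exhaustive fallback also
covers queries shorter than the word size.

## ITS extraction and dissection

An rrn operon's ITS is the span strictly between a 3'-terminal 16S anchor
match and the next 5'-terminal 23S anchor match; both strands are
searched, anchors are located exactly with an approximate (edit-distance ≤
10% of anchor length) fallback, and each operon is dissected independently
(real genomes often carry several operons; the reference organism carries
two).

Dissection assigns the canonical regions in the order
D1-D1′, D2, D3, tRNA-Ile, boxA, D4, V2, tRNA-Ala, boxB, V3. The conserved
domains D2 (12 bp), D3 (5 bp), boxA (12 bp) and D4 (7 bp) are located as
ungapped motif matches with a per-motif mismatch tolerance of 1; the motif
strings live in an editable config (`data/motifs.yaml`) because the
convention — not any specific string — is what published dissections
share. The bundled motifs, anchors and tRNA references are synthetic
stand-ins (files named `synthetic_*`); real-organism dissection requires
supplying organism-specific definitions. tRNA-Ile (74 nt) and tRNA-Ala
(73 nt) are located by alignment against the bundled references (edit
distance ≤ 10%); absent tRNAs are flagged, not reported as zero-length.
D1-D1′ runs from the ITS start to the D2 motif; V2 fills the interval
between D4 and the next landmark (tRNA-Ala, else boxB); boxB spans its
basal helix motifs AGCA…UGCU; V3 runs from the basal GUC after boxB to the
ITS end (closing GAC). Unnamed gaps between landmarks are kept as explicit
`spacer` regions so region lengths always sum to the ITS length, and the
tRNA-removed total is the ITS length minus the located tRNA lengths.
Zero-length variable regions are permitted and flagged. The summary table
mirrors the standard per-strain layout (ITS length with tRNAs removed,
then the ten regions).

## Helix secondary structure

Helices are folded by weighted maximum pairing (Nussinov-style dynamic
programming): maximise the summed weight of nested pairs, GC=3, AU=2,
GU=1, with a minimum hairpin loop of 3 unpaired residues and no
pseudoknots. Ties are broken deterministically (pair the leftmost residue
with its smallest admissible partner; pairing options are scanned before
leaving a residue unpaired), so outputs are bit-stable. This is a
combinatorial stand-in for thermodynamic nearest-neighbour folding, chosen
because it is self-contained and exactly testable: the DP optimum is
verified against exhaustive enumeration of all nested structures for every
sequence up to length 10 and sampled sequences to length 18. The
consequence is that element counts on real helices are model-dependent and
are treated as a soft comparison surface; basal-stem closures (boxB's
AGCA-UGCU, V3's GUC-GAC) are the robust, asserted property. Structures are
annotated purely from the pair set into stems (maximal stacks), hairpin
loops, left/right bulges (one-sided unpaired runs), symmetric/asymmetric
internal loops, multiloops and exterior residues; the annotation
partitions all residues. The structure distance is the symmetric
difference of pair sets (sequences compared left-aligned) plus per-kind
signed element-count deltas.

## Genome and proteome divergence indices

**ANI** follows the classical fragment-based convention: the query genome
is cut into consecutive 1,020-bp fragments (a final partial fragment is
kept if ≥ 700 bp; circularity is ignored, which is negligible at genome
scale), each fragment is placed at its best location in the subject by
exact semi-global (infix) alignment (edlib), and a fragment is retained
when its best alignment has ≥ 30% identity over ≥ 70% of the fragment.
The one-way value is the mean retained-fragment identity; the reported
two-way value is the mean of the two one-way values, so any genome against
itself is exactly 100.00. No retained fragments is an *undefined* result,
distinct from zero. Note that forced infix placement always aligns the
full fragment, so with the default filters even unrelated genomes can
produce (low) values; raise `min_identity` to make unrelated comparisons
undefined.

**AAI** is the mean identity over reciprocal best hits between two
proteomes. RBH selection uses the local search with filters identity ≥
30%, query coverage ≥ 0.7, alignment ≥ 50 aa; the reported identity of
each pair is then recomputed over a global alignment (identical columns
over alignment columns). **POCP** is `100·(C1+C2)/(T1+T2)`, a protein
counting as conserved when it has a hit in the other proteome with
e-value < 1e-5, identity > 40% and an alignable region > 50% of the query
protein's length; it is symmetric by construction. Whether a published
matrix reports one-way or two-way ANI is often unstated; both one-way
values are emitted in the JSON detail. Genome statistics are length and
GC% with ambiguous bases excluded from the GC denominator, reported to one
decimal.

## Ortholog phylogenomics

Orthology is approximated by reciprocal best hits under the AAI filters;
single-copy clusters are connected components of the pooled RBH graph with
exactly one member per strain and all strains present. Per-cluster
alignments use center-star progressive alignment (center = member with the
best summed pairwise score; pairwise alignments to the center are merged
column-wise, once-a-gap-always-a-gap) — deterministic and adequate at the
scale the package targets; pre-computed alignments can be substituted.
Clusters are concatenated in sorted cluster-id order with a partition map.
Distances are p-distances over shared non-gap columns (Poisson correction
−ln(1−p) optional, undefined at p ≥ 1). Trees are built by neighbor
joining with lexicographic tie-breaking, exact on additive matrices
(verified to 1e-9 on random additive fixtures), optionally rooted on the
outgroup's terminal edge at its midpoint. Supports are classical
bootstrap: column resampling with replacement, percentage of replicate
trees containing each internal bipartition; fully degenerate (all-zero
distance) matrices are flagged and carry no supports. This distance
pipeline deliberately replaces maximum-likelihood inference and is
labelled as such in outputs.

## HGT screen

Per protein: drop hits to the strain's own database records (matched by a
case-insensitive strain token in the subject id), keep hits with query
coverage ≥ 0.90 and similarity ≥ 40% (both inclusive), order by the search
total order, and call *candidate* when all of the top five retained hits
lie outside the focal family (exact, case-insensitive match against any
lineage rank; lineages are ordered domain→species). Proteins with fewer
than five retained hits form an explicit `insufficient_hits` class so
counts stay auditable. Filter-then-rank is the default; a
rank-before-filter switch covers the other reading of "top five". The
summary reports the candidate fraction over all screened proteins and a
donor-family tally.

## Delineation thresholds

16S rRNA identity: < 94.5% → new genus; 94.5–95% → genus boundary zone;
(95, 98)% → same genus, new species; 98–99% → species boundary zone;
> 99% → same species. The published ranges are preserved as explicit
boundary-zone calls rather than forced to one side. Genomic indices vote
independently: ANI < 83% and POCP < 50% (strict), AAI ≤ 70% (inclusive,
mirroring the printed operators) each support a distinct genus; a metric
at or above its threshold votes "within genus" without claiming species
resolution. Ties in the vote break toward the deeper split and are
flagged. The combined verdict is the most conservative (deepest-split)
call when all non-abstaining evidence agrees within one rank on the scale
species(0) – species-boundary(0.5) – new-species(1) – genus-boundary(1.5)
– new-genus(2); otherwise the verdict is an explicit conflict listing the
disagreeing sources — no precedence between 16S and genomic evidence is
invented. Every applied threshold is echoed in the rationale.

## Synthetic data

The generators produce every fixture with machine-checkable ground truth:
i.i.d. genomes at a target GC; substitution-only mutants with logged
sites (so `100·(1−realized rate)` is an exact ANI oracle — no indels, by
design); ITS sequences assembled from the bundled templates in canonical
order with known boundaries (including tRNA-less variants and an analog of
the longest observed configuration, 380 bp tRNA-removed with
D1-D1′/V2/boxB/V3 = 121/76/45/98); proteome pairs with a controlled shared
fraction and exact per-pair identities (substitutions at interior sites
only, so global-alignment identity equals the log); HGT hit tables with
planted foreign proteins and border hits at coverage 0.89/0.90 and
similarity 39.9/40.0 that pin the filter thresholds; random additive tree
matrices with the generating tree. The study bundle assembles four strains
whose evidence deliberately straddles the genus thresholds (nearest 16S
≈ 96%, ANI ≈ 82, AAI ≈ 65, POCP ≈ 46).

What the fixtures do **not** emulate: indels and rearrangements, base
composition structure, repeat content, real rRNA/tRNA sequence (all
bundled references are synthetic stand-ins), and realistic helix sequence
(variable-region interiors use reduced alphabets — A/C for V2, poly-A for
boxB/V3 — so landmark motifs can never be shadowed and basal stems are
the unique fold optimum). Passing tests therefore demonstrate correctness
of the algorithms and thresholds under the stated models, not dissection
or folding accuracy on arbitrary real genomes, which additionally needs
organism-specific motif/anchor definitions.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen as the package's own
defaults: 100–200-kb genomes for ANI properties, 8–12-protein proteomes
(120–150 aa) for AAI/POCP, 12 universal families across 4 strains for the
phylogenomic chain, 4–8-taxon additive matrices for NJ, and exhaustive
folding verification to length 10 (plus sampled length ≤ 18). Headline
comparative values that depend on external genome sets and the full NCBI
nr database (complete divergence matrices against all published
neighbors, the 845-gene supermatrix, the genome-wide 24.6% HGT fraction)
are out of desk scale by construction; the pipeline reproduces the
*procedures* and verifies them on generated data. All randomness flows
from explicit integer seeds; reruns are byte-identical. Floating-point
conventions: ANI/AAI to two decimals and POCP/GC to one in reports;
undefined metrics raise a dedicated error and render as NA in tables.
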