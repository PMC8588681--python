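# Methods

This note documents the models, decision rules and numerical choices behind
`mitoscreen`, and what the synthetic-data generator does and does not
emulate.

## Local similarity search

The aligner is seed-and-extend: exact `word_size`-mer matches (default 11)
are grouped into diagonal clusters (single-linkage with a 32-diagonal /
500 bp tolerance), and each cluster is extended by a banded affine-gap
Smith–Waterman (numba kernel) over the cluster's diagonal neighbourhood
plus a pad. Because every reported alignment is a legal local alignment,
scores are bounded above by the unrestricted Smith–Waterman optimum; the
band and pad are generous enough that on mutated-copy pairs (10%
substitutions, a few indels) the optimum is reached in ≥ 95% of cases.

Scoring is +2/−3 with gap cost 5 + 2·L. Identity is computed over alignment
columns, gap columns counting as non-matches. There is no E-value: the
report threshold is a raw score (default 60). With these scores the
Karlin–Altschul λ is ≈ 0.63, so score 60 corresponds to E ≈ 1e-10 at the
10 kb × 10 kb scale this package works at; seeded random-pair searches at
that scale return nothing. Near-duplicate alignments from adjacent clusters
are collapsed to the best-scoring (same-diagonal containment, or mutual
≥ 80% overlap).

Hit filters are strict thresholds (a hit is dropped iff *shorter than* the
length cutoff or *below* the identity cutoff). The near-top display filter
groups hits by single-linkage overlap on the assembly; within a group the
top hit is the maximum-identity hit (ties: longer, then earlier start), and
a hit is dropped iff its length is within 50 bp of (or shorter than) the
top hit's and its identity is more than 2 points lower. The tie rule is a
package decision; display filtering of this kind is usually described only
operationally.

## Repeats and the recombination proxy

Dispersed repeats come from a self-search at 50 bp / 90% identity with the
trivial self-hit removed, mirror duplicates collapsed, and self-overlapping
(tandem-like) pairs excluded. Circular genomes are searched on a doubled
sequence and hits canonicalized back; content percentages are per-base
unions. Long repeats use strict > 500 bp and > 90% identity with
overlapping qualifying pairs reduced to a non-overlapping set by descending
length.

Tandem arrays are proposed per candidate period p ≤ 500 from runs where
`seq[i] == seq[i+p]` at a rate near the squared match probability, merged
across small gaps, scored against a per-phase majority consensus with
(+2, −7) and trimmed to the best-scoring subsegment (Kadane). Indels are
not modelled in the scoring; the full `2 7 7 80 10 50 500` parameter vector
is kept for interface familiarity. Arrays need ≥ 2.5 copies (a two-copy
"array" is just a duplication, and few-copy consensus overfits long
periods); among overlapping candidates the smallest period whose score is
≥ 0.6 of the group's best is reported, which collapses period multiples
without ever inventing a small period (an unrelated small period scores
below the cutoff).

Recombinational activity: a long read spans a repeat if it covers the whole
repeat plus ≥ 100 bp (anchor) on both sides. Each side of a spanning read
is assigned to the repeat copy whose corresponding flank it matches with
higher identity; a difference under 2 percentage points is ambiguous.
Incongruence is discordant flank phasing (left flank from one copy, right
flank from the other); activity is the percentage of incongruent reads
among classified (non-ambiguous) reads, over a seeded random sample of up
to 50 spanning reads. The 2-point ambiguity margin and the flank-phasing
operationalization are package decisions. On simulations the estimator is
unbiased to well under 2 percentage points at 200 spanning reads.

## Transfer screens

Plastid-derived regions: each reference plastome is searched against the
mitogenome; hits overlapping annotated rRNA genes or *atp1* are excluded
(their plastid homology is ancient and uninformative), and surviving hits
are merged into regions separated by < 100 bp (the merge gap is a package
decision). Each region receives one of four origin calls, in cascade:

1. **mitogenome** — ≥ 98% identical (over ≥ 90% of its length) to related
   reference mitogenomes: ordinary mitochondrial sequence that happens to
   resemble the plastome;
2. **homology** — overlaps a mitochondrial gene with a known plastid
   homolog (*nad* genes vs *ndh* genes, *atp1* vs *atpA*, rRNAs);
3. **HGT candidate** — the matched plastid gene is absent or pseudogenized
   in the organism's own plastome, or phylogenetic placement groups the
   region with a foreign lineage;
4. **intracellular** — placement groups the region with the own-lineage
   plastome. Unresolved placements fall back to this lowest-commitment
   category with an explicit "unresolved" evidence code; absent placements
   are withheld.

Placement itself aligns the region with the best-matching segment of each
candidate source genome and applies the grouping test to a bootstrapped
distance tree.

The order-level intergenic screen searches reference mitogenomes (grouped
by order) against the assembly, filters at 250 bp / 80% identity, and
flags as HGT candidates contiguous stretches of ≥ 500 bp that a foreign
order hits but the focal order's coverage mask leaves uncovered. The
per-base mask with a contiguous-run requirement formalizes what is
otherwise a visual judgement on coverage plots.

Nuclear copies of missing genes are the best ≥ 50% identity locus per
gene; reading-frame intactness is assessed on the aligned locus in the
frame implied by the hit, and a missing start codon is reported separately
from internal stops.

## Phylogenetics

Protein-guided alignment translates each CDS (terminal stop trimmed,
internal-stop sequences dropped with a warning), aligns the proteins
(mafft when lengths differ; the identity alignment when they do not), and
back-translates so gaps come in codon triplets. Columns with more than 50%
gap/ambiguous characters are masked, with an old→new coordinate map.

Distances are Kimura two-parameter with pairwise deletion:
d = −½ ln((1 − 2P − Q)√(1 − 2Q)) with P and Q the transition and
transversion proportions; a non-positive logarithm argument flags the pair
as saturated and sets it to a ceiling of 5.0 substitutions/site. Trees are
neighbour joining over canonically sorted taxa (deterministic tie-breaking,
so the unrooted topology is invariant to input order); negative branch
lengths are clamped to zero with the deficit moved to the sibling.
Bootstrap resamples alignment columns with replacement; supports are the
percentage of replicate trees containing each original bipartition,
computed through vectorized per-pair site-type counts so 1000 replicates on
a dozen taxa take about a second. Distance trees deliberately replace
maximum-likelihood inference here; `phylo.load_tree` accepts externally
computed Newick trees (supports as internal labels), so an ML program's
trees can be slotted into the grouping test unchanged for full-scale work.

The grouping test roots on a designated outgroup and is decided by clade
membership at a bootstrap threshold (default 80): **vertical** when the
focal taxa are monophyletic and either the (focal + expected sister) clade
is supported, or the smallest supported clade above the focal taxa confines
them to the expected group; **hgt_candidate** when that clade instead
confines them inside a single different labelled group; **unresolved**
otherwise. The alternative-clade granularity is whatever labelling the
caller supplies (orders, in the pipeline).

The conversion scan restricts the alignment to polymorphic columns; each
taxon pair's statistic is its longest run of identity across those columns,
with a null distribution from seeded column permutations (equivalently,
uniform rearrangements of the pair's fixed match/mismatch multiset — the
Monte Carlo null is cached by (sites, mismatches)). P-values are
Bonferroni-corrected over pairs tested; pairs identical across all
polymorphic sites carry no contrast and are skipped. On clock-like
no-conversion panels the scan's family-wise false-positive rate stays at or
below the nominal 5%.

## Annotation, split genes, editing

Gene models chain query-colinear hits of reference CDS; a single locus (or
cis-intron chain) covering ≥ 95% of the reference is intact, subject to a
pseudogene check (net frameshift, i.e. spliced length ≢ 0 mod 3, or an
internal stop in the conceptual translation — standard genetic code, which
plant mitochondria use). Multi-locus models are fragmented and reported
with the `_frag` suffix convention.

Split-gene layouts order pieces by reference coordinate: adjacent pieces on
the same strand, in genomic order, within `min_separation_bp` (default
5000) are cis; farther, strand-changed, or contig-break-separated pieces
are trans. Pieces abutting on the reference (gap ≤ 10 bp, absorbing the
few bases local alignments trim off diverged edges) additionally flag a
within-exon split. The 5 kb default stands in for "remotely located" on
realistically sized genomes; the pipeline's synthetic runs pass 1.5 kb
because the toy genomes are only ~15 kb.

Junction support maps reads to the spliced model with the package aligner
(≥ 90% identity); a split read crosses a junction with ≥ 20 aligned bp on
each side, and a read pair supports a junction when its mates anchor
(≥ 30 bp) in pieces on opposite sides.

Editing prediction is an explicit surrogate for dedicated predictors,
sharing only the ≥ 0.5 decision threshold: for each genomic C whose C→U
edit changes the encoded residue, the score is the fraction of non-gap
homolog residues matching the *edited* residue. Observation requires a
genomic C on the coding strand with ≥ 5× transcript coverage and ≥ 50% T;
predicted and observed sites merge into predicted-only / observed-only /
both classes.

## The synthetic-data generator

The generator defines the study conditions. Defaults: 4 orders × 2 taxa
plus an outgroup; 0.05 expected substitutions/site per branch (sister taxa
are ~9% divergent, orders ~17%, comfortably inside the screens' identity
windows); 10 protein genes of 100–250 codons plus two rRNA genes; 12–16 kb
recipients. Evolution is Jukes–Cantor substitution only; inside genes,
substitutions creating internal stops are re-drawn, keeping every panel
sequence translatable. Each order carries its own random intergenic
scaffold (homologous within an order, unrelated between orders), which is
exactly the contrast the order-level screen relies on. The focal (recipient)
lineage grafts as sister to `Order_1|taxon_1` through a recorded midpoint,
so donor divergence for a planted transfer (~4 branch lengths) is at least
twice the recipient–sister divergence.

Planted tracts replace intergenic scaffold so the configured genome length
is exact. Repeat copies are substituted to the target identity by exact
count, and three flanking bases on each copy edge are forced to mismatch
between copies (orientation-aware), so copy boundaries are recoverable to
the base — a single mismatched base is cheaper for the aligner to jump than
the chance matches beyond it. Crossover long reads join one copy's left
context to the other's right context at a uniform point inside the repeat;
read base errors are substitutions (default 3%). Transcript reads are
100 bp pairs from mature spliced transcripts with planted C→T edits; the
trans-spliced gene's mature transcript joins the 3′ piece of exon 1 to
exon 2, while the orphan 5′ piece is transcribed separately, so no fragment
ever bridges the exon-1 halves. Edit sites are planted where editing
restores a panel-conserved residue, mirroring the restorative character of
real C-to-U editing.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: indels inside genes, realistic long-read
error profiles (no homopolymer or indel errors), base-composition bias
(GC ≈ 50% rather than the ~44% of real mitogenomes), rate heterogeneity
across sites or lineages, within-panel transfers, structural heteroplasmy
beyond pairwise repeat crossovers, and genome-scale repeat families. The
screens' thresholds are exercised, not stress-tested, by these conditions;
real assemblies add alignment ambiguity and annotation noise the truth set
cannot represent.

## Pipeline

Stages run in dependency order (simulate → annotate → repeats → recomb →
transfer → phylo → report); each writes plain-text artifacts plus a stamp
carrying a hash of the scientific configuration (the output directory is
excluded from the hash), so unchanged reruns are cache hits and full reruns
are byte-identical. All randomness flows from one root seed. Pipeline
defaults scale the analysis to desk-size problems (200 bootstrap
replicates, 2000 conversion permutations, ~15 kb genomes); the library
functions accept the full-scale values (1000 replicates, 10000
permutations) directly.

## Known limitations

* The aligner is heuristic: alignments whose optimal path leaves the
  seeded diagonal band, or that contain no exact word match, can be missed
  or undershoot the optimal score.
* The tandem detector does not model indels within arrays and claims no
  numeric parity with dedicated tandem-repeat software.
* The grouping test depends on the caller's clade labelling; with a single
  focal taxon, monophyly is trivially satisfied and the verdict rests
  entirely on clade support.
* Editing prediction scores each C against homolog conservation
  independently; compound edits within one codon are scored one site at a
  time.
* `classify_transfer` formalizes what is, in practice, a manual judgement;
  on real data its calls should be read as structured evidence summaries,
  not final answers.
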