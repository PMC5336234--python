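# Methods

This note documents the models, conventions and design choices behind the
`rptp` package: a desk-scale comparative pipeline for the R3 subtype of
receptor protein tyrosine phosphatases (RPTPs) — single-pass membrane
proteins with extracellular fibronectin type III (FN3) repeats and one
cytoplasmic catalytic PTP domain.

## Coordinates and core containers

All coordinates are 0-based half-open internally.  GFF-style 1-based
closed coordinates exist only at file boundaries, with the exact bijection
`(s, e)_gff = (s - 1, e)_internal`.  Minus-strand gene models are flipped
to transcript orientation on read, so all downstream phase arithmetic is
strand-free.  CDS lengths include the stop codon by default (GenBank CDS
dialect): a protein of length L has a CDS of 3L + 3 nt; a flag disables
this for CDS fragments.  FN3 repeats are numbered with ordinal 1 closest
to the transmembrane segment, increasing toward the N terminus.

## PTP-domain similarity

The all-vs-all domain comparison uses exact Smith–Waterman local alignment
(Gotoh affine-gap DP) with BLOSUM62, gap open 11, gap extend 1, and
Karlin–Altschul expectations `E = K·m·n·exp(-λS)` with the standard gapped
constants for that scoring system (K = 0.041, λ = 0.267).  A database
search engine is deliberately not called: the analysis uses E-values
ordinally (which cells of the matrix fall below a threshold, default
1e-80), and exact local alignment preserves that ordering.  K and λ are
fixed constants, not re-estimated; no composition-based statistics are
applied, so E-values are comparable within one run only.  Unknown residues
(X) score 0 against everything.

## Alignment sweep and elision

Proteins are aligned by a plain progressive aligner: guide tree by
neighbor joining on `d = 1 − identity` from exact global alignments
(identity = matches over aligned residue columns), then profile–profile
global alignment with affine gaps up the guide tree.  Column–column
profile scores are mean pairwise substitution scores over non-gap
residues.  Determinism is guaranteed end to end: distances are exact, NJ
ties break lexicographically by label, and all DP tie-breaks are fixed
(match preferred, then gap-in-second, then gap-in-first).

The sweep aligns the same sequences at gap-open costs 1, 2, 4, 6, 8 and
16.  Gap-extend is tied to gap-open (ratio 0.1, floor 0.5) so the sweep
stays one-dimensional.  Elision concatenates the six alignments
column-wise into one supermatrix whose partition table records each
cost's half-open column range; every partition must degap to the original
sequences, which is checked.  Only concatenation + partitioning is
implemented; down-weighting of parameter-sensitive columns is not.

Codon alignments are produced by back-translation: each amino-acid column
of the protein alignment becomes one codon triple from the in-frame CDS,
gaps become `---`.  Every CDS must translate exactly to its protein row
(silent differences are invisible and therefore fine; any nonsynonymous
mismatch aborts with the label and residue).

## Phylogenetics

Parsimony uses the classic Fitch two-pass state-set computation,
vectorized over sites with bitmasks, on the tree rooted along the edge
next to the first leaf (the length is invariant to that choice, which is
tested).  Gaps are treated as missing data (`?` semantics) by default; a
flag makes the gap a 21st state.  The heuristic search is random stepwise
addition (greedy insertion over all edges) followed by best-improvement
NNI hill climbing, with a configurable number of independent addition
orders (default 10) and per-seed determinism.  Equally parsimonious
distinct topologies can all be retained for consensus reporting.  This is
a desk-scale search: NNI rather than TBR, suitable for the tens of taxa
this analysis handles.

Neighbor joining is implemented with deterministic tie-breaks (minimum Q,
then lexicographically smallest pair).  On an exactly additive matrix it
reconstructs the generating topology and path-length metric, which is the
oracle test.  Branch lengths are not clamped.

The bootstrap resamples alignment columns with replacement (implemented
as per-site weights), re-infers a tree per replicate (parsimony with one
addition order by default, or NJ on weighted p-distances), and summarizes
with majority-rule consensus; supports are split frequencies on a 0–100
scale.  Monophyly of a named group is an unrooted-tree property: some
edge bipartition must isolate exactly the group; the smallest bipartition
side containing the group is also reported.

Likelihood and Bayesian inference are out of scope by design: the clade
statements this pipeline targets (group monophyly, sister relations) are
testable with parsimony/NJ + bootstrap, and duplicating off-the-shelf
ML/MCMC engines adds no method-specific logic.

## Structural character systems

**Landmark anchoring.**  Characters are read off positions, not motifs
searched by regex: a domain sequence is globally aligned to a reference
scaffold with declared landmark columns, and the residues aligned to
those columns are the landmarks.  A single-residue landmark must carry
its expected residue (the strand-B W must be W) or it is reported absent;
the WPD triplet columns are exempt from the identity check because the
triplet's variation *is* the character.  The shipped FN3 and PTP
scaffolds are synthetic constructions with known landmark columns (see
`data/*_synthetic.fasta`); any scaffold can be substituted, e.g. a real
FN3 consensus with annotated strand-B/strand-C columns.

**B-C loop codes.**  `W{n}G{m}Y` with n residues strictly between the
strand-B W and the loop G, m between G and the strand-C Y; hence
n + m + 1 equals the W–Y span, an identity asserted across all tests.
When several glycines lie in the loop, the one aligned to the scaffold's
loop-G column wins; otherwise the leftmost.  Codes map to the eight
standard colour classes (red = W4G4Y … pink = W9G4Y); everything else,
including missing anchors, overlong loops (cap 30 residues, a misanchor
guard) and G-less loops (coded `W{L}Y`), is white.

**Intron phases and FN3 intron codes.**  For the intron after c coding
nucleotides: phase = c mod 3, protein position = c div 3.  A domain's
code is upstream-flank : internal phases… : downstream-flank, colon
joined.  Introns exactly on a domain boundary count as flanking, never
internal (the figure-style classes treat "flanked by" and "inside" as
disjoint, and boundary assignment must be deterministic).  Absent flanks
are recorded as open sides, never as phase 0.  Flank search is bounded by
the neighbouring domain's edge when provided.  Colour classes: 1:1
yellow, 1:0:1 orange, 1:1:1 blue, 1:2:1 black; the enlarged
juxtamembrane repeat with two or more internal introns is grey regardless
of its exact code — the grey class is structural ("long juxtamembrane
multi-intron"), not a string match.

**WPD calls.**  The motif-8 triplet read at the scaffold's WPD columns;
class WPD, WPE, or other.  If overall identity to the PTP scaffold falls
below 20% the anchor is unreliable and the call is `other`/`???` with a
warning.

**YxN motifs.**  Every tyrosine C-terminal to the PTP domain is reported;
it is a YxN motif iff position +2 carries asparagine.  The per-protein
summary pattern is YxN > otherY > none.  Neural-network phosphorylation
scores are not reimplemented; an external prediction table can be joined
by position.

## Character mapping and ancestral states

Characters join to tree leaves as a long-format (leaf, character, value)
table plus an NHX-annotated Newick; missing leaves get `?` with a
warning and topology is never modified.  Ancestral reconstruction is
set-valued Fitch: bottom-up state sets, then a top-down pass that
intersects with the parent's final set where possible.  States are
reported as sets rather than forced singletons — where several states are
equally parsimonious, choosing one would overstate the data.  The implied
change count equals the parsimony length of the same single-column
matrix (tested) and is invariant under re-rooting; note that the *root
set* of the default output tree depends on where the unrooted tree was
arbitrarily rooted for display.

## Synteny comparison

Each neighbor of the anchor locus in genome A is classified against
genome B: conserved (present on the same chromosome/scaffold as B's
anchor), elsewhere (present on another scaffold), absent (no ortholog) —
an exhaustive, disjoint partition.  Orthology is by name with an optional
renaming table; "near" means same scaffold as the anchor.  The packaged
worked example encodes the vertebrate PTPRB neighborhood (CCT2, LRCC10,
BEST3, MYRFL, CNOT2, KCNMB4, PTPRR, LGR5) against the Ciona intestinalis
gene complement; the vertebrate-side coordinates in the fixture are
approximate and only the presence and scaffold assignments drive the
classification.

## Synthetic families

The generator exists so that every stage is testable without downloads.
A family evolves along a given tree (branch lengths in expected
substitutions/site) from an ancestor assembled out of the reference
scaffolds: signal peptide (18 aa), FN3 repeats (default 3) with linkers
(8 aa), transmembrane helix, PTP domain, 25-aa tail.  Per-site
substitution is i.i.d. with probability `1 − exp(−rate·t)` per branch,
replacement uniform over a per-segment alphabet.  Clade plans apply on
the stem branch of each group's MRCA and rewrite the planted characters
(loop composition, WPD triplet, tail motif, juxtamembrane enlargement).

What makes the truth recoverable by construction: landmark sites, whole
loops and two flanking residues are masked from substitution; FN3
segments never substitute to W/G/Y (no decoy landmarks); tails never
substitute to Y/N; indels occur only in linkers.  Gene models place the
planned introns at domain boundaries (flanks) and evenly spaced inside
domains (internal phases), with fixed 120-nt introns; CDSs use one fixed
codon per residue plus TAA.  Everything is driven by one
`numpy.random.default_rng` seed, and identical seeds give byte-identical
output files.

The default configuration mirrors the study design: five vertebrate
clades of three species (PTPRB, PTPRJ, PTPRH, PTPRO, PTPRQ) with their
characteristic characters (PTPRQ: WPE, no tail tyrosine, W7G4Y loops,
multi-intron juxtamembrane repeat; PTPRO: 1:0:1 intron patterns; etc.),
two tunicate singletons splitting between the PTPRB-like and PTPRQ-like
sides, a protostome and a sponge outgroup — 19 taxa, stems of 0.15–0.3
substitutions/site, tips of 0.08–0.12.

What the generator does **not** emulate: realistic substitution processes
(no WAG/GTR, no rate heterogeneity), codon usage and silent variation
(CDSs are deterministic back-translations), domain gain/loss,
alternative splicing, alignment-hostile low-complexity regions, or any
database/curation noise.  Passing tests therefore demonstrate that the
annotators, aligners and tree methods are correct and internally
consistent — not that they are robust to every pathology of real curated
sequences.  Real-data reruns need user-supplied proteins, domain tables
and exon tables in the documented formats.

## Problem sizes and numerical choices

Default desk-scale sizes: 19 taxa, PTP domains of ~165 aa, elided
supermatrices of ~1,500 columns, 10 addition orders for the final search,
100 bootstrap replicates with 1 addition order each.  These run in
seconds to a couple of minutes on one CPU and are the package's default
study conditions; all are configurable upward.  Floating-point DP scores
are compared with exact arithmetic on integer-valued matrices; NNI
acceptance requires strict improvement, so searches terminate.  Seeds
derived from the master seed use SHA-256 of the stage name, truncated
below 2^31.

## Known limitations

* E-values are a calibrated stand-in, not database-search expectations;
  only their ordering is meaningful.
* The progressive aligner has no iterative refinement or consistency
  scoring; at very low gap costs alignments are gappy (by design the
  elision protocol wants exactly this parameter sensitivity).
* NNI can in principle stop in local optima that TBR would escape;
  multiple random addition orders mitigate this at the sizes used here.
* The fixture coordinates of the synteny worked example are approximate;
  classification depends only on presence and scaffold identity.
* Intron-position homology within strands (the region-level summary of
  internal intron placement) is not computed; it would require a curated
  per-strand segmentation of each FN3 alignment.
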