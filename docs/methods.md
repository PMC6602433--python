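# Methods

This note records the models, conventions and design choices behind each
pipeline stage, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Genome intake

One FASTA file per genome; the genome id is the file basename minus its
extension (`.fa`/`.fasta`/`.fna`). Genomes are ordered lexicographically
by id at intake and that order is used everywhere downstream, so tables,
phyletic strings and trees are reproducible regardless of archive
layout. Sequences are uppercased and U→T; IUPAC ambiguity codes other
than N are mapped to N with a warning by default (`ambiguous="strict"`
rejects them instead) — draft assemblies routinely contain them, and a
hard failure by default would be hostile. A file in which more than 20%
of characters are not A/C/G/T/N is rejected as non-nucleotide, naming
the file. Malformed input fails fast; there is no partial intake.

## ORF extraction

Coordinates everywhere are **0-based, half-open, on the forward strand
of the contig**, spanning start codon through stop codon inclusive;
`nt_seq`/`aa_seq` exclude the stop codon. Excluding the stop makes
back-translation a pure 1-residue : 1-codon map with no special cases.

The built-in finder is a six-frame scanner: within each frame, stop
codons partition the sequence, and each inter-stop segment contributes
at most one ORF, from the most upstream start codon (ATG/GTG/TTG) to the
terminating stop. ORFs shorter than 90 nt (stop excluded) or truncated
by a contig end are discarded. Translation uses the bacterial code
(table 11); the initiator codon is rendered M whatever its table-11
amino acid. Codons containing N translate to X.

A raw six-frame scan also reports *shadow ORFs* — stop-free stretches on
the other frames and strand of real genes. Trained gene callers suppress
them with a coding model; the built-in stage instead applies the
standard length heuristic (`resolve_overlaps`): calls are kept
longest-first, and a call is dropped when more than half of its genomic
span overlaps an already-kept call on the same contig. Real genes are
the longest ORFs at their locus and survive; genuine small overlaps
(operon boundaries) stay below the threshold. The heuristic can
occasionally sacrifice a real gene to a longer shadow that extends past
its boundary (about 2% of planted genes in the synthetic runs).

The Prodigal adapter runs the trained caller (`-p single`, i.e. normal
mode; the mode string is passed verbatim) and converts its 1-based
inclusive GFF coordinates to the package convention. Partial
(contig-edge) genes are dropped, matching the built-in discard rule. A
missing binary falls back to the built-in finder with a warning.

GC content is computed per genome over the concatenation of its ORF
coding sequences — (G+C)/(A+C+G+T), N excluded from both counts — so it
reflects coding GC, not whole-genome GC.

## Homology search

ORFs are extracted in frame, so the search scores their translations
directly with Smith–Waterman local alignment under BLOSUM62 and
BLAST-default affine gap costs (a length-k gap costs 11 + k); a
six-frame nucleotide search would duplicate work the ORF caller already
did. The scorer is `Bio.Align.PairwiseAligner` in score-only mode; the
test suite holds it to exact agreement with an independent exhaustive
Gotoh DP.

Raw scores are converted to bit scores with the published
Karlin–Altschul parameters for gapped BLOSUM62 11/1 (λ = 0.267,
K = 0.041); an empty alignment is 0 bits. Hits under the floor
(`min_score`, default 50 bits) are discarded before top-hit selection.
The floor replaces a search engine's significance threshold: true
ortholog pairs in the synthetic runs score hundreds of bits, while
chance local alignments between unrelated 100–300 aa proteins stay
around 20–30 bits. Because the raw→bit map is strictly monotonic, top
hits and tie-breaks are identical under either scale. Ties on score are
broken by lexicographically smallest target ORF id, making the whole
table deterministic and independent of genome input order. The external
adapter parses standard 12-column tabular output, whose 12th column is
already a bit score — both engines filter on the same scale.

The search is exhaustive: every cross-genome pair is scored once
(the scorer is symmetric). No k-mer prefilter is applied, so the
all-against-all stage dominates run time; the 10-genome synthetic study
(~2,700 ORFs) takes a few minutes on one CPU.

## Reciprocal best hits and Markov clustering

An edge {x, y} exists iff each is the other's recorded top hit in the
partner genome; edges carry the mean of the two directed bit scores,
but clustering is unweighted by default (`use_weights` turns it on),
mirroring the plain RBH construction. Only cross-genome edges exist —
no within-genome (in-paralog) edges are added. Isolated ORFs stay in
the graph and become singleton orthogroups, so every ORF is accounted
for in the output tables.

MCL is implemented from scratch with canonical defaults: self-loops on
(weight = the node's maximum incident weight), expansion power 2,
inflation 2.0, entries below 1e-5 pruned, convergence when no entry
moves more than 1e-6, at most 200 iterations (non-convergence clusters
the current matrix with a warning). A column emptied by pruning has its
diagonal restored — the node becomes its own attractor rather than
vanishing. Flow never crosses disconnected components, so clustering
runs per connected component; this is a pure speed-up with identical
results. Clusters are read off the limit matrix as attractor systems
(rows with nonzero diagonal, grouped when they exchange flow); each
remaining node joins the attractor receiving the most of its column
flow, ties to the smallest attractor — guaranteeing a partition, which
the downstream tables require, rather than the overlapping clusters the
raw nonzero pattern can imply.

## Orthogroup tables, phyletic patterns, core extraction

Orthogroups are numbered OG0000001… ordered by decreasing size, then
smallest member id. Cells with several members of one genome are
semicolon-joined in sorted order. Phyletic patterns are one 0/1 string
per genome over the fixed orthogroup order, written as FASTA (the
layout gain/loss-inference tools consume). The x%-core is occupancy
based: groups with ≥1 member in at least ⌈x/100·n⌉ genomes (so x = 100
means every genome); ceil is used because "at least x%" cannot round
down. Multi-copy core groups count as core here but are excluded later
from concatenation, which needs single-copy groups.

## Alignments and back-translation

The built-in protein aligner is center-star progressive: the center is
the sequence maximising its summed pairwise global-alignment score
(Needleman–Wunsch, BLOSUM62, gaps 11 + k as above; ties to smallest
id), and remaining sequences are merged against it under "once a gap,
always a gap". Input order is fixed by sorting on ORF id, and the
pairwise aligner's first-reported optimal path is used, so output is
deterministic. Center-star is a bounded-error heuristic, not an optimal
MSA; MAFFT `--auto` is the production adapter and satisfies the same
row contract (degapping recovers the input). Singleton groups pass
through unaligned so the per-group file inventory is uniform.

Codon alignments replace each aligned residue with its source codon and
each gap with `---`; inputs are validated (length must be 3× the
degapped row, translation must match) and violations abort with the
offending ORF named. Stop codons were stripped at ORF extraction, so no
stop handling is needed here.

Core concatenation takes the single-copy core groups in orthogroup-id
order; groups missing a genome or carrying paralogs are excluded with a
logged count. A partition table records each group's column interval
(1-based inclusive) in the supermatrix. No filtering of poorly aligned
groups is applied before concatenation — alignment trimming/masking is
out of scope and left to downstream tools.

## Species tree

Pairwise p-distances (mismatches over columns non-gap in both rows;
a pair with zero comparable columns is a fatal error) feed canonical
neighbor joining: Saitou–Nei Q-criterion, ties broken by the
lexicographically smallest pair of labels (internal nodes are labelled
by their smallest descendant leaf), negative branch estimates clamped
to zero. Two taxa split their distance evenly; three taxa get the
closed-form star. NJ is consistent on additive distances: the test
suite verifies exact tree-metric recovery (within 1e-9) on random
additive matrices of 4–12 taxa.

NJ on p-distances is the always-available engine so the pipeline always
yields a tree; it is a distance heuristic, and for publication-grade
phylogenies the external maximum-likelihood adapter (RAxML, LG
replacement matrix, discrete gamma with four categories plus an
invariant category) should be used when installed — a missing binary
falls back to NJ with a prominent warning. The adapter accepts an
optional partition file but does not write one by default. Trees are
unrooted (rooting, e.g. on an outgroup, is left to the user) and
serialised to Newick with children ordered by smallest descendant leaf
and 6-significant-digit branch lengths; parsing is delegated to
dendropy, whose errors carry line/column positions.

## Synthetic pan-genome generator

The generator emulates exactly the signal the pipeline measures:

- ancestral families: random codon sequences, a start codon followed by
  non-stop codons, length uniform in 300–900 nt (100–300 aa — compact
  but realistic bacterial proteins);
- presence/absence: each genome loses each family independently with
  probability 0.1;
- divergence: retained copies mutate per site at rate 0.02; a mutation
  that would create an in-frame stop or destroy the start codon is
  reverted, so every planted gene remains a structurally valid ORF;
- gain: genome-private random genes, Poisson with mean
  `gain_rate × n_families` per genome (default 0.1 → ~10);
- layout: genes are shuffled onto one contig per genome, random strand,
  separated by 50–500 nt random spacers, with an in-frame stop codon
  planted directly upstream of each gene so the six-frame finder
  recovers exactly the planted start.

Defaults (10 genomes × 100 families, loss 0.1, substitution 0.02) are
the package's standard study conditions; everything is deterministic
given the seed. Ground truth maps every placed gene to its family, and
recovery is scored over gene pairs: precision and recall of
co-clustering, matched to predicted ORFs by shared stop codon (robust
to start-site disagreement). When no pairs are inferred, precision is
reported as 1.0 with an explicit `precision_defined=False` flag.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: indels and rearrangements, gene
duplication (paralogs), codon-usage and GC bias, intergenic regulatory
structure, sequencing or assembly error. Two practical consequences are
measured in the test suite: random spacers and other-frame shadows
yield spurious short ORF calls that end up as singleton orthogroups
(realistic in effect, if not in mechanism), and the absence of
codon-usage signal costs a trained gene caller part of its recall on
short planted genes (Prodigal recovers ~96% of planted genes ≥450 nt
on these genomes but only ~89% at ≥300 nt, whereas on real genomes its
short-gene recall is far higher).

## Problem sizes and run times

The default verification battery uses: 50 random pairs (≤30 aa) for the
alignment-score oracle, 20 random 2 kb sequences for the ORF oracle,
planted score matrices over 3–6 genomes for RBH, a 50-graph panel
(≤30 nodes) plus a 20-graph reference panel for MCL, 100 random
additive matrices (4–12 taxa) for NJ, the 10 × 100 synthetic
pan-genome for end-to-end recovery, and a 4 × 20 pan-genome run twice
for determinism. On one CPU the oracles take seconds; the end-to-end
run takes a few minutes, dominated by the exhaustive all-against-all
search.

## Known limitations

- The built-in ORF stage is a length-based scanner, not a trained gene
  model; on real genomes Prodigal should be preferred.
- No in-paralog rescue: within-genome duplicates are never linked, so
  recent paralogs land in separate orthogroups (or the same one only
  via shared cross-genome best hits).
- The exhaustive search scales quadratically in total ORF count;
  dozens of genomes are comfortable, hundreds call for the external
  search adapter.
- Center-star alignment and NJ on p-distances are heuristics standing
  in for MAFFT and maximum likelihood; both externals are first-class
  adapters.
- The x%-core counts occupancy (≥1 member), not single-copy presence;
  single-copy filtering happens only at concatenation.
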