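# Methods

`scramblekit` analyses pairwise whole-genome alignments of highly
rearranged ("scrambled") genomes — the motivating system is the tunicate
*Oikopleura dioica*, whose cryptic lineages share gene content but show
little conservation of gene order below the chromosome-arm scale.  The
package consumes one-to-one local alignments (as produced by an aligner
plus a one-to-one filtering step), gene annotations, chromosome layouts
and orthology tables; it never computes alignments or orthology itself.

## Coordinate conventions

All internal coordinates are 0-based, half-open, on the forward strand of
each genome.  Strand is a property of an alignment block (the relative
orientation of the two genomes across that block), never of an interval.
GFF3 (1-based inclusive) and MAF (minus-strand positions counted from the
sequence end) are converted at the I/O boundary; PAF and BED pass through
unchanged.  Alignment sets must be one-to-one — pairwise non-overlapping
on both genomes — and this is validated at construction, as is agreement
between observed chromosome lengths and any user-supplied layout (a
mismatch is an error because silent disagreement corrupts every
length-weighted statistic downstream).  Blocks of zero width on either
genome are rejected: they have no defined strand contribution.

## Collinearity segmentation

The strictest definition of collinearity is used.  Two blocks are chained
iff they are consecutive among aligned blocks on their target chromosome,
consecutive among aligned blocks on their query chromosome (ascending for
`+` chains, descending for `-`), and on the same strand.  Collinearity is
therefore interrupted by inversions (strand changes) and by translocations
(one extra aligned region in one genome only) of any length — but never by
the length of the unaligned gap between two members.  Adjacency counts
every aligned block on a chromosome, whatever its partner chromosome, so a
block translocated in from elsewhere breaks the chains it lands between.

The target genome is then partitioned exactly into four classes:
aligned blocks in chains (*collinear alignments*), aligned blocks in no
chain (*isolated alignments*), unaligned gaps between consecutive chain
members (*bridges*), and all remaining unaligned sequence (*breakpoint
regions*).  Where two non-collinear blocks abut, a zero-width breakpoint
is recorded at the shared boundary: real breakpoint-region widths are
strongly skewed with many near-zero regions, so counts must not depend on
how much unalignable sequence an event left behind.  Coverage reports give
breakpoint counts both with and without zero-width regions.  Unaligned
sequence before the first and after the last block of a chromosome is
breakpoint, never bridge, because bridges exist only strictly between
chain members; a chromosome with no alignment at all is one whole-length
breakpoint.  Chains never span chromosomes but may span the centromere.

One consequence worth noting: a clean deletion on one branch leaves the
flanking alignments mutually adjacent in both genomes, so the resulting
unaligned gap in the genome that retains the material is a **bridge**, not
a breakpoint.  Breakpoints require an actual interruption of collinearity.

## Scrambling index

For a grouping unit (chromosome or arm) with total same-strand aligned
length L_s and opposite-strand length L_o on the target genome,

    index = |L_s − L_o| / (L_s + L_o).

A value of 1 means all alignments agree in orientation (a whole-unit
inversion also scores 1 — that is a single event, not scrambling); 0 means
orientations are balanced, i.e. look random.  The genome-wide summary is
the mean over units weighted by **full unit sequence length** (not aligned
length); units with no aligned base are undefined and excluded from both
the numerator and the weight sum.  Lengths are measured on the target
genome, which makes per-unit weighted means direction-dependent; the
single-unit (whole-genome) index is direction-symmetric because L_s and
L_o are.  Arm grouping clips blocks at arm boundaries and weights by arm
length.

## Breakpoint accumulation rate

rate = n_breakpoints / (aligned Mbp) / (divergence time in My), with
aligned length the total of collinear plus isolated alignment bases on the
target.  Divergence time enters once, as time since the split, not twice
the branch length: split ages combined with observed counts are what yield
rates in the single-digit-to-tens range for rapidly scrambling genomes.
Whether zero-width breakpoints are counted is a flag (default: counted).

## Macrosynteny blocks

Single-copy ortholog pairs (orthogroups with exactly one member in each of
the two genomes) are ranked along each genome by (chromosome, start)
**among the pairs only**, so intervening non-ortholog genes never break a
run.  Synteny blocks are maximal runs with consecutive ranks in both
genomes, query rank ascending or descending — strand is ignored.  Every
pair belongs to exactly one block; singleton blocks are allowed.  The
run definition is a design choice (the field uses several); consecutive
ranks among single-copy orthologs is the simplest strand-independent one
and is what the size histograms and dot-plot exports are built from.

## Operons

An operon is a maximal run of ≥ 2 same-strand, same-chromosome genes with
each intergenic gap ≤ 500 bp (configurable), measured between gene spans;
overlapping same-strand genes count as gap 0 and merge.  Cross-genome
equivalence compares orthogroup **multisets** (order and strand ignored) at
either HOG granularity (hierarchical orthogroups, near one-to-one) or OG
granularity (gene-family level, more permissive).  *Exact* equivalence
requires identical multisets; *inexact* additionally accepts exactly one
substituted gene for operons of ≥ 3 genes (ABC matches ABC, XBC, AXC,
ABX; AB matches only AB).  Identical multisets are equivalent under both
criteria, so exact equivalence always implies inexact.  Genes without an
orthogroup assignment match nothing — conservative, so conservation is
never inflated.  Substitution-only matching (equal sizes, no gene
indels) mirrors the worked three-gene pattern family above.

The operonic-status association between two genomes classifies each
single-copy pair as operonic in both / A only / B only / neither and tests
the four observed counts against expectations from independent marginal
operonic rates — a goodness-of-fit with df = 3.  The plain 2×2
independence test (df = 1) is reported alongside as a cross-check; the
df = 3 construction is the one that matches a four-category report.

Breakpoint overlap uses half-open interval intersection; a zero-width
breakpoint at position p overlaps an element iff p is strictly inside the
element span (a point on the edge cuts nothing).

## Profiles

Boundary enrichment: for each segmentation class and boundary side, the
fraction of boundaries with a feature (exon, intron, operon, repeat, CNE)
at each offset in a ±W window (default W = 1000 bases, 10-base steps —
chosen to resolve exon-scale structure in a compact genome; no canonical
window exists).  Offsets falling off the chromosome count as uncovered.
Profiles are strand-agnostic (genome-forward).  Percent-length profiles
bin per-element values by floor(B·midpoint/length) with B = 50 bins by
default; multi-genome averages are means of per-genome bin means, not
pooled elements, so a gene-rich genome cannot dominate a bin.  Arm-class
comparisons use two-sided Wilcoxon rank-sum tests (exact null when both
samples are ≤ 25 and tie-free, asymptotic otherwise); classes with fewer
than two elements are skipped with a notice.  The gene×breakpoint×arm
table drops empty classes, reducing the degrees of freedom accordingly.
d_N/d_S values are inputs (per-gene TSV); no codon-model estimation is
performed.

## Rearrangement simulator

The simulator provides ground truth for every downstream stage.  Sequence
content is never simulated: every statistic in scope is coordinate-based,
so a descendant genome is a *painting* of ancestral segments, each with an
orientation and a copy number, and true one-to-one alignments between two
descendants are emitted directly from shared ancestry.

**Ancestor.**  Default study conditions, scaled to desk size: three
chromosomes (2.4, 2.0 and 1.6 Mb) with centromeres splitting them into
short and long arms, the third carrying an X-specific region (XSR) as its
short arm; 1,500 genes laid down left to right in runs — an operon run
(size 2 + Poisson, one strand, gaps 20–500 bp) with probability 0.25,
otherwise a singleton — with inter-run gaps of 501–5000 bp.  Because
inter-run gaps always exceed the 500-bp operon ceiling, the planted
operons are *exactly* the maximal 500-bp same-strand runs, closing the
loop with the operon caller.  The run probability 0.25 puts ~50% of genes
in operons, the share reported for compact operon-dense tunicate genomes.
Repeats cover a sparse 3% of the genome.  Gene density (~0.25 genes/kb)
matches a compact genome at one-tenth linear scale.

**Events.**  Each branch receives 40 events by default, mixed 70%
inversions / 25% translocations / 3% deletions / 2% duplications.  Events
are intra-chromosomal with probability 0.94 and, conditional on that,
confined to a single arm with probability 0.99 (the two observed scale
fractions; the arm fraction is conditional so that intra-arm events are
never claimed to exceed intra-chromosomal ones).  Event lengths are
uniform between 1% and 20% of the scope length.  Endpoints snap to the
nearest gene boundary, so genes move, flip, duplicate or die whole —
keeping operon and ortholog truth exact; an event that cannot fit its
scope is resampled and the count reported.  No empirical event-length
distribution exists for the motivating system; the bounds are exposed in
the config.  Event logs are complete: replaying a log from the ancestor
reproduces the descendant exactly.

**Alignments.**  Emitted blocks are maximal intervals of unbroken common
ancestry with consistent relative strand.  Deleted material is unaligned;
duplicated material aligns only through its primary copy (copy 0), which
preserves the one-to-one property; duplicates share an OG but get their
own HOG in the emitted ortholog table.  An optional `flank_loss` strips a
configurable number of bases (default 0, up to ~500 is sensible) from each
side of every internal segment junction, emulating the unalignable
sequence real breakpoint regions accumulate — the one cause of
unalignability representable without sequence.  With `flank_loss = 0`
breakpoints between abutting blocks are zero-width, which is why
zero-width breakpoints are first-class objects throughout.

**What the simulator does not model:** nucleotide substitution and
alignability decay with divergence, repeat-mediated breakage mechanisms,
gene birth/death apart from duplication/deletion of existing genes,
chromosome fission/fusion, and assembly artefacts.  Passing tests
therefore demonstrate correctness of the coordinate analysis under known
rearrangement histories, not robustness to alignment noise in real data.

## Numerical and degenerate-input choices

Ties in block sorting cannot occur (one-to-one, non-overlapping; equal
starts are rejected upstream).  Class-coverage fractions sum to 1 exactly
by construction (integer arithmetic on a partition).  Units/classes with
no data propagate as NaN/missing and are excluded from weighted means;
degenerate contingency tables (an empty expected cell, a single occupied
class) raise or return an explicit notice instead of a statistic.  Reports
serialise floats at 6 significant digits with sorted keys so identical
runs produce byte-identical files.

## Problem sizes

Defaults throughout are chosen for a ~6 Mb, 1,500-gene synthetic genome
pair; the test suite uses 0.4–1.2 Mb genomes with 250–500 genes, 1,000
random alignment sets for the partition property, an exhaustive
enumeration of >300,000 small block configurations against the
brute-force chaining oracle, and 200-replicate nulls for the calibration
checks.  These sizes are the package's own verification conditions; all
scale linearly if raised.
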