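# Methods

This note documents the models, conventions and numerical choices behind
each stage, the design decisions that were genuinely open, and what the
synthetic-data tests do and do not demonstrate about real genomes.

## Coordinates and genome representation

All coordinates are 1-based inclusive, following the GenBank convention.
A feature crossing the replication origin of a circular genome is stored
as a single span with `end < start` (at most one wrapping span per
feature); GFF3 export splits it into two part lines sharing an ID because
GFF3 has no origin-crossing notation. N bases are accepted in input but
excluded from both numerator and denominator of composition statistics,
and a codon containing N is treated as neither start nor stop during ORF
scanning. Reported percentages are rounded to one decimal at the
reporting layer only; all internal arithmetic is unrounded.

## ORF annotation

The annotation rule is the conventional one for baculovirus genomes:
ATG-initiated ORFs only (no alternative starts), one candidate per stop
codon — the most upstream in-frame ATG after the previous stop — and a
length floor of `min_aa = 50` codons, the community criterion for
"ORFs encoding proteins of more than 50 amino acids". Circular genomes
are scanned on the doubled sequence so frames wrap through the origin;
candidates are deduplicated per (strand, stop codon), keeping the longest
extension, and a candidate may never exceed one full circumference.

"Minimal overlapping" is unquantified in annotation practice, so overlap
resolution is explicit and configurable: candidates are taken greedily by
decreasing protein length (ties: smaller start, then forward strand) and
rejected when they overlap an accepted ORF by **more than**
`max_overlap_bp = 75` (≈ 25 codons) on the circle — a conventional
tolerance; the inequality is strict, so an overlap of exactly 75 bp is
allowed. Coding coverage is the length of the union of selected spans
divided by genome length, so overlapping bases are counted once.

ORF numbering follows tradition: the polyhedrin gene (or any caller-
chosen anchor) becomes ORF 1 and numbering proceeds around the circle in
the anchor's transcription direction; for a minus-strand anchor the
coordinates therefore descend.

## Homologous-region detection

hrs are modelled as tandem arrays of a unit of roughly 80 bp whose
consensus carries at least two imperfect palindromes. Detection is fully
deterministic (no stochastic alignment), so hr counts are reproducible
for fixed parameters.

*Tandem repeats.* Exact 12-mer matches at lags within
`period_min..period_max` (default 60–120 bp, bracketing the ~80 bp unit)
seed candidate arrays; seeds are clustered by lag (± 4) and positional
adjacency, the cluster is extended outward while positions agree with
their image one period away (match +1, mismatch −2, X-drop 15), and the
span is phased into unit copies scored against a majority-rule consensus.
Terminal copies below the identity floor are trimmed (they are extension
overshoot), loci overlapping by more than half the shorter are merged
keeping the higher copy number, and circular genomes are scanned on the
doubled string with deduplication. Floors: `min_copies = 2.5`,
`min_unit_identity = 0.6`. A single chance k-mer match extends to barely
more than one period and is removed by the copy-number floor, which is
why a 100 kb i.i.d. random sequence yields zero calls.

*Palindromes.* For every center and loop length (≤ 10), arms are grown
outward counting mismatches between the left arm and the reverse
complement of the right arm (≤ 2), arms never terminating on a
mismatched pair; hits contained in a longer hit's span are suppressed,
and the floor is `min_arm = 8`. Because the phase of a tandem unit is
arbitrary, palindromes are searched on the **circular** unit (doubled
string, offsets reduced modulo the period) — otherwise a palindrome
split across the reported unit boundary would be missed.

*hr calling.* A repeat locus is promoted when its consensus unit carries
at least two palindromes. The locus A+T fraction is computed over the
whole span; the summary reports both the pooled A+T over all hr bases
and the mean of per-hr values, since either convention appears in genome
papers. hr orientation is a reported-only heuristic (sign of the
consensus unit's GC skew) and plays no role in scoring.

## Protein homology

Pairwise alignment is optimal global Needleman–Wunsch/Gotoh under affine
gaps, BLOSUM62, gap open 11 and extend 1 (a run of length *g* costs
`11 + g`). Percent identity is identical columns divided by the columns
between the first and last column where both rows carry a residue:
terminal overhangs are excluded (so a perfect substring scores 1.0),
internal gaps are not. This convention changes identity tables by
several points and is pinned by a dedicated test. Coverage is the
fraction of each sequence inside that core window.

Orthologs are called by reciprocal best hit: each protein must be the
other's best score (ties resolved by higher identity, then
lexicographically smaller label), with permissive floors
`min_identity = 0.15` and `min_coverage = 0.3` — the published homolog
counts for these genomes come from unstated BLAST criteria, so RBH
counts are treated as approximate, not exact, reproductions.

Gene classes come from a packaged catalog: the 38 core genes and the 22
lepidopteran-conserved genes are transcribed from the study's gene-
content table; no authoritative enumeration of the Group I-specific set
ships with genome annotations, so a representative 11-gene list
(gp64, ie-2, ptp, pkip, odv-e26, ac5, ac16, ac30, ac72, ac73, ac124) is
included and easily overridden. Lookups normalise case and punctuation
and follow a synonym table (p74 = pif0, vp91 = p95 = pif8, ac110 = pif7,
ac108 = sf58, …). Per-class summaries are arithmetic means of pair
identities; empty classes are absent, never zero.

The multiple aligner is progressive: UPGMA guide tree on pairwise
identity distances, profiles merged in guide-tree order with a
profile-profile dynamic program (column score = mean pairwise
substitution score; linear per-column gap cost of half the affine
open+extend). It is deterministic for a fixed input order and adequate
for the substitution-only families the generator produces; it is not a
replacement for a production aligner on indel-rich data.

## Gene parity and collinearity

Parity points are **ordinal** positions (ORF numbers after anchor
normalisation), not nucleotide coordinates, one point per homolog pair,
with an orientation flag recording strand agreement. Genes matched in
only one genome are re-ranked away (matched genes are compressed to
consecutive ranks); the alternative — keeping skipped ordinals — changes
τ little but is not implemented.

Because the choice of ORF 1 is a convention on a circular genome, the
collinearity statistic is Kendall's τ (pair counting; equivalent to τ-a
on distinct ranks) maximised over all circular renumberings of the
second genome in both orientations; the maximising shift and the
orientation flip are reported. The longest collinear block is a
longest-increasing-subsequence with an ordinal-gap cap (default 5) on
both axes, searched over both orientations and all rotations.

## Phylogeny

The distance surrogate replaces full maximum-likelihood tree building:
p-distances with pairwise deletion (columns gapped in either member of a
pair are dropped for that pair) and the Poisson correction
d = −ln(1 − p), which is undefined at p ≥ 1 — such pairs are flagged
saturated and refuse tree building rather than being silently truncated.
Pairwise deletion (rather than complete deletion) preserves signal in a
concatenated supermatrix and is switchable.

Neighbor joining is canonical: minimise Q = (n−2)d − R_i − R_j, join,
update with Studier–Keppler distances; ties break on the smallest index
pair in the current active ordering, so results are deterministic, and
NJ is exact on additive matrices (tested on 50 random additive matrices).
Negative branch lengths, which NJ can produce on noisy data, are clamped
to zero with a warning. Bootstrap resamples columns with replacement —
indexed by column only, so supports are invariant to taxon input order —
rebuilds the tree per replicate, and labels each internal edge of the
full-data tree with the percentage of replicates containing its
bipartition. Newick serialisation writes branch lengths to six decimals
with supports as internal node labels and round-trips exactly.

Clade placement is judged on unrooted splits: the query is *outside* the
reference clade iff some split side contains every reference taxon but
not the query (the references are monophyletic without it); the trivial
side that merely excludes the query leaf does not count. This avoids the
complement-side artifact of rooted-clade definitions on unrooted trees.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: a circular genome of 113,971 bp at
G+C 0.311 carrying 124 ORFs (length drawn uniformly from 60–500 aa,
scaled down only if a draw cannot pack) and six interspersed hrs built
from a genome-wide 80 bp consensus unit (G+C 0.457, two planted
palindromes of arm 10 / loop 4, 3–8 copies per locus, 5% per-copy
substitution). Stop-codon rejection in ORF bodies and the hr composition
bias the genome away from the G+C target, so intergenic gaps are drawn
at a compensating composition; realized genome G+C lands within ±0.01 of
the target.

Three constructions make planted truth exactly recoverable, and they are
the generator's contract rather than incidental choices:

* every ORF cassette carries an in-frame stop immediately upstream of
  its ATG, so the scanner's most-upstream-ATG rule reports exactly the
  planted start;
* a 15 bp spacer with a stop codon in all six reading frames separates
  consecutive cassettes, so no reading frame can thread a cassette
  boundary, and the hr unit is redrawn until every frame of its tandem
  context holds ≥ 2 stops per period, so no ORF threads a repeat array;
* residual background candidates reaching 50 codons are disrupted by
  planting a stop outside all recorded features — or, for candidates
  nested antisense inside a planted ORF, by a synonymous edit of the
  host that creates a stop in the spurious frame without changing any
  planted protein (recorded DNA is refreshed afterwards).

Ortholog pairs enforce their target identity exactly (substituted
positions counted, not expected), so identity-recovery tolerances can be
tight; protein families evolve along a tree by a Poisson substitution
process. Deliberate idealisations, hence limits on what passing tests
show about real data: background bases are i.i.d. (no dinucleotide or
codon-usage structure, no promoter motifs), evolution is
substitution-only (no indels, so multiple alignment of simulated
families is trivial by construction), there are no nested or programmed
overlapping genes, and hrs are the only repeat family (no *bro*-like
repeated ORFs). Detector false-positive control on i.i.d. background is
therefore necessary but not sufficient evidence for low-complexity real
genomes.

## Problem sizes in the routine checks

The recovery batteries run at desk scale by choice: 8 kb genomes with 6
planted ORFs for annotation recall, 30 kb genomes with 1–8 planted hrs
for hr recovery, one 100 kb random sequence for false positives, 38-gene
proteome pairs (200–400 aa) for identity recovery, additive matrices of
up to 10 taxa for NJ exactness, and 10-taxon families of 300 aa for the
clade-placement rate. The full-scale simulated genome (113,971 bp) is
annotated end-to-end in the acceptance script. Validation against the
deposited GenBank record is wired into the suite but requires a one-time
download of the public accession; it is the only check that cannot run
from generated data alone.
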