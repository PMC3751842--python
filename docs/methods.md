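# Methods

`plastomics` re-implements, as one tested pipeline, the comparative analysis
stages commonly applied to chloroplast (plastid) genomes of closely related
plants: quadripartite structure and IR-junction analysis, four-category
repeat scanning, homologous-region divergence and hotspot scanning,
p-distances and variant tallies, and partitioned maximum-parsimony
phylogenetics. Because the deposited genomes such analyses run on are
external data, the package ships a plastome-evolution simulator whose ground
truth makes every stage verifiable end to end.

## The simulated study system

The simulator emulates a set of seven individuals from six closely related
plant species plus four more distant outgroup plastomes.

**Ancestor construction.** The ancestral genome is circular and laid out
LSC | IRb | SSC | IRa with default lengths 86,204 + 26,025 + 18,318 + 26,025
= 156,572 bp. IRa is the exact reverse complement of IRb. The gene
inventory follows the conserved dicot arrangement: 123 unique genes
(81 protein-coding, 38 tRNA, 4 rRNA), of which 23 lie in the IR and are
placed once in each copy (146 gene copies). Sixteen genes carry one intron
and `clpP`/`ycf3` carry two, for 20 introns total. Exon lengths approximate
published plastome annotations; the largest LSC proteins are padded so
protein-coding sequence reaches 52.9% of the genome (tRNA ~1.9%, rRNA
~5.8%, coding ~60.6%). Bases are drawn i.i.d. with an AT fraction of 0.627.
Intergenic spacers (>= 30 bp) fill each region, their sizes drawn from a
Dirichlet split of the slack so layouts differ between seeds. The generator
deliberately ignores codon structure, start/stop codons and compositional
heterogeneity: no downstream statistic in this pipeline reads codons.

The four bases adjacent to the IR junctions are chosen to mismatch their
reverse-complement partners and are held immutable during evolution, so the
planted IR is exactly the maximal inverted pair. Without this, a 1-in-4
chance flanking match would legitimately extend the true IR and no detector
could recover the nominal boundary "exactly".

**Planted repeats.** 45 repeats with motif lengths 30-61 bp are written into
single-copy spacers (two "gene-similarity" repeats into the interiors of two
long genes): 19 tandem (42%), 15 dispersed, 9 palindromic, 2 gene-similarity
(4%), a mixture shaped like the tandem-heavy repeat landscape reported for
real plastomes. Copies are exact or carry one planted mismatch.
Consecutive reservations leave 40 bp of random sequence between plants so
that two independent plants can never be spanned by one >= 90%-identity
window.

**Evolution.** Genomes evolve along a fixed 11-taxon tree (branch lengths in
expected substitutions/site at relative rate 1). Substitution counts per
branch and region are Poisson with mean `branch_length x rate_scale x
multiplier[class][region] x region_bp`; transitions occur with probability
kappa/(kappa+1) (default kappa = 2). Indels (5'-geometric length, mean 3 bp,
capped at 8) occur only in single-copy non-coding sequence at a default rate
of 0.03 events/site per unit branch length. IR mutations are mirrored into
the other copy (concerted evolution), so IRa remains the exact reverse
complement of IRb in every descendant. One designated species has two
individuals; their two terminal branches receive *exactly* 16 differing
sites (and nothing else), so within- vs between-species contrasts have a
planted truth.

Two bookkeeping rules make downstream statistics exactly checkable:

* **Site exclusivity.** Mutation sites are drawn without replacement
  genome-wide; a site is touched by at most one event in the whole
  simulation. Realized event counts therefore equal alignment-column counts
  (no multiple hits, no substitution-inside-deletion ambiguity). At the
  simulated rates (~2,700 events over 157 kb) the deviation from independent
  placement is negligible.
* **Indel margins.** Each indel excludes a 12 bp margin around itself, so
  two independent indels are never close enough for the aligner to stack
  them into shared columns; indel events and alignment gap runs then
  correspond one to one.

**Rate multipliers.** Real plastomes show the partition ordering
SSC > introns/spacers > LSC > coding > IR in variable-character percentages.
The defaults here (coding 0.30/0.70/0.10, intron 0.50/0.85/0.18, spacer
0.62/1.05/0.18 for LSC/SSC/IR) produce, at the default tree, about
0.76 / 0.54 / 0.43 / 0.34 / 0.13 % variable characters for
SSC / introns+spacers / LSC / coding / IR. The separations are chosen wide
enough that the ordering is a property of the configuration rather than a
sampling accident in a single ~157 kb genome set: with partitions of 18-86
kb, adjacent partitions must differ by several binomial standard deviations
for a replicated ordering check to be meaningful. Magnitudes remain in the
sub-1% regime typical of congeneric plastome comparisons.

**What the simulator does not model** (and hence what passing tests do not
show about real data): codon structure and selection, rate variation within
a region class, genome rearrangement, IR expansion/contraction, gene
loss, heterogeneous base composition, sequencing or assembly error, and
alignment ambiguity beyond simple indels.

## Structure detection

The IR pair is found from exact 25-mer seed matches between the genome and
its reverse complement (computed on the doubled sequence so the circle has
no blind spot), clustered by the circular anti-diagonal `p + q = C`. The
best cluster is extended base by base in both directions; a patch of up to
two consecutive mismatches is crossed only when at least 12 of the next 14
pairs match, and total mismatches must stay within `mismatch_tol` (default
0.5%). This confirmation rule stops extension from creeping into
single-copy sequence on chance matches (the probability of random sequence
passing is ~5e-6 per junction). The larger single-copy gap is the LSC.
Detection is rotation-invariant; intervals may wrap the origin (`end > n`)
for rotated inputs. An exhaustive anti-diagonal scan
(`brute_force_inverted_repeat`, <= 20 kb) serves as the oracle in tests.

Junction genes are reported with exonic base counts on each side of the four
junctions; a straddling feature that is a truncated duplicate of a longer
same-named gene is flagged pseudogene-like (the classic truncated second
`ycf1` copy).

## Repeat scanning

A hit is a pair of equal-length ungapped segments (direct or inverted) with
identity = matches/length >= 0.90 and length >= 30 bp, reported if no longer
valid window on the same diagonal contains it ("containment-maximal"; the
diagonal is the offset for direct hits and the anti-diagonal constant for
inverted hits). Ungapped identity follows the mismatch-based model of
classic plastome repeat scans; no gapped variant is defined.

The scanner finds candidate diagonals from exact 7-mer seeds: any valid
window up to ~75 bp contains two exact runs of >= 7 whose starts differ by
8-60 positions (pigeonhole on the mismatch budget), and longer windows
(tandem arrays, merged motifs) have runs recurring well within that span
unless mismatches are placed adversarially. Each candidate zone is then
enumerated exactly. The exhaustive oracle enumerates every window on every
diagonal up to a length cap (default `2 x min_len`); fixtures for
scanner-vs-oracle equivalence plant repeats within the cap. A conservative
density prefilter (any valid window of length <= ~800 contains a 30-window
with >= 26 matches) prunes empty diagonals in both implementations; motifs
are capped at 800 bp, far above anything outside the IRs, which are handled
by the structure module and masked here.

Overlapping hits merge when both copies overlap with the same orientation;
merged identity is recomputed ungapped when spans stay equal and by the
package's own pairwise aligner otherwise. Classification priority is
tandem (direct, gap <= 10 bp) > gene-similarity (copies inside two
different named genes) > palindromic (inverted, gap <= 3 kb) > dispersed;
only the tandem-over-dispersed priority is a field convention, the rest is
a repo convention. One caveat follows from containment-maximality: lowering
`min_identity` can merge two maximal windows into one longer valid window,
so hit counts are guaranteed monotone only in `min_len`.

## Alignment

Regions are aligned progressively: guide order by 6-mer-profile distance to
a centre sequence, then each sequence joins the growing profile
(closest first) via banded affine-gap alignment (match +1, mismatch -1, gap
open -4, gap extend -1; a gap of length g costs 4+g). The band is the
length-difference corridor +-60 for inputs over 200 bp and the full matrix
below that; at the sub-1% divergences this pipeline targets the optimal
path cannot leave the corridor. Pairwise scores are verified against
Biopython's global aligner in the tests. When all sequences of a region
have equal length and >= 98.5% ungapped identity to the first, the ungapped
stacking is returned directly; under this scoring a gap pair costs at least
10 and can only pay for itself above ~1.5% divergence or with real length
differences, neither of which applies on that fast path.

## Divergence statistics

Each genome decomposes into named regions (exons, introns, spacers; spacers
split at the four junctions; the IRb copy dropped so each locus appears
once), matched across genomes by name. A column is *variable* if it shows
>= 2 distinct bases among {A,C,G,T}; gaps and N are not states, and a
column of one base plus gaps is an indel column. Hotspots are regions whose
variable percentage strictly exceeds 1.0% (configurable), computed over the
ingroup only by default. The whole-genome alignment is the concatenation of
per-region alignments in genome order, valid because the simulated (and
real congeneric) genomes are collinear.

p-distance: differing sites / compared sites, where compared sites have a
base in both rows; means are taken over ingroup pairs, split within/between
species. Variant tallies classify each variable column once (transition if
the observed bases are exactly {A,G} or {C,T}, otherwise transversion,
mixed columns counting once as transversion) and count an indel event as a
maximal run of columns sharing the same non-empty set of gapped rows; both
axes (coding vs introns+spacers, LSC/SSC/IR) are tallied. These tallies
equal the simulator's realized event counts exactly under the bookkeeping
rules above — computed over all 11 individuals, since realized events
include outgroup branches.

## Maximum parsimony

Character matrices for six datasets (complete, coding exons, LSC, SSC, IR,
introns+spacers) are cut from the whole-genome alignment by column labels
inherited from the region table; columns within 5 positions of a gap
opening in any row are treated as ambiguously aligned and excluded from all
partitions (the window is configurable; no standard rule exists).

Fitch counting treats gaps and N as missing. Searches: exhaustive
enumeration (<= 9 taxa), branch-and-bound with the partial-tree length as
bound (provably complete for minimum-length trees), and a heuristic with
random-addition starts followed by tree-bisection-reconnection swapping
(every edge bisected, the detached part rerooted all ways and reattached
everywhere), keeping all equally best trees. Bootstrap resamples columns
with replacement (pattern-compressed; only parsimony-informative patterns
affect topology ranking, the rest contribute a tree-independent constant);
support is the percentage of replicates whose strict consensus of best
trees contains each clade of the best tree. Homoplasy indices per variable
column i: m_i = states - 1, s_i = Fitch steps, g_i = (taxa with a state) -
(count of the commonest state); CI = sum m / sum s, RI = (sum g - sum s) /
(sum g - sum m), RC = CI x RI; columns containing gaps are excluded, and RI
is reported as missing when sum g = sum m. dendropy's Fitch pass serves as
an independent cross-check in the tests, never as the implementation.

## Numerical and procedural choices

* All randomness flows from `numpy.random.SeedSequence` spawns of one seed;
  identical configuration and seed give byte-identical genomes and reports.
* Ties in alignment traceback prefer diagonal, then gap-in-B; ties in tree
  search are broken by deterministic insertion order under the seed.
* Pipeline TSVs are sorted on a primary key and begin with a comment header
  carrying the configuration hash and seed; Newick files carry the same in
  a bracket comment; a manifest records SHA-256 checksums of every output.
* Problem sizes used by the validation experiments: 100 genomes for
  boundary recovery; 50 random 10 kb fixtures for scanner/oracle
  equivalence; 100 full-scale replicates for the partition-ordering check;
  100 random 6-taxon matrices against the labeling-enumeration oracle and
  50 8-taxon matrices for branch-and-bound vs exhaustive; 1,000 bootstrap
  replicates on the 11-taxon dataset; the determinism check reruns the
  pipeline at scale 0.2 with 10 bootstrap replicates.

## Known limitations

* Real GenBank records with inconsistent annotation (missing `gene`
  qualifiers, trans-spliced `rps12`) will need curation before region
  extraction; duplicate gene names outside the IR context raise an error
  rather than being guessed at.
* The repeat scanner's exactness guarantee is stated for motifs <= ~75 bp
  under adversarial mismatch placement and for longer motifs with
  non-adversarial (e.g. random or planted) mismatch spacing.
* The aligner is a progressive method with a fixed scoring scheme; columns
  near indels in deep outgroups can be ambiguous, which is why partition
  building excludes a window around gap openings.
* The hotspot-recovery fixture plants exact variant counts; with free
  Poisson rates, regions near the 1% threshold would flip by sampling, which
  is a property of thresholded scans, not of the implementation.
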