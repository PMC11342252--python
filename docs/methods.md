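# Methods

This note documents the models, parameter choices and numerical
conventions behind `cifscape`, and what the synthetic-data regime does and
does not establish about real genomes.

## Coordinate and ordering model

External coordinates are GenBank-style (1-based, inclusive). All window
arithmetic — neighborhoods, scan windows — operates on 0-based gene
*indices* into the (contig, start)-sorted gene list, so windows are counted
in genes, never base pairs. Gene order is positional regardless of strand;
"upstream of CifB" in the curation sense is resolved strand-aware (the 5′
positional neighbor on the CifB coding strand). Pseudogenes keep their
slots in the gene order (they occupy neighborhood positions) but carry no
protein and never enter clustering. Neighborhoods do not cross contig
boundaries; circular wrapping exists but is off by default, because draft
genomes make origin-spanning windows unreliable.

## Homolog curation

A candidate is accepted iff its domain architecture contains ≥ 4 tandem
REase hits with no intervening non-REase hit, and is **not**
CR-effector-like (first hit CR-ATPase with a REase after it). A missing or
non-CifA upstream gene flags the homolog as an *orphan* but does not reject
it — orphan CifB copies occur in real genomes, so adjacency is evidence,
not a requirement. The upstream check defaults to immediate adjacency with
a configurable tolerated gap (`max_gap`), since operons occasionally carry
an inserted gene.

The provenance filter for eukaryote-annotated candidates removes a
candidate only when a *strict majority* of its genomic neighbors, or of its
closest homologs, is bacterial; ties retain. This is deliberately
conservative: a false removal silently discards a true horizontal-transfer
case, whereas a false retention is visible downstream.

## REase active-site classification

Activity is called from the ordered residue motif E … D … E-x-K … Q. The
literature gives the residue order but not spacing, so the classifier uses
configurable inter-anchor spacing windows, default 5–120 residues; "E-x-K"
is matched literally as E, any single residue, K. Sequences shorter than
the minimal motif span are inactive by definition. The call is invariant
to residues outside the motif positions (property-tested).

## Domain annotation

The native matcher assigns maximal non-overlapping hit sets from a profile
list, resolving overlaps greedily by score, then start, then label — which
makes the output independent of profile iteration order. The default
profile set is a *synthetic signature set*: literal 10-residue anchors,
one per domain family, matching what the simulator plants. It exists so
that architecture logic is exactly testable; real analyses import external
hmmscan per-domain tables (envelope coordinates, per-domain independent
score) or supply their own profiles in the YAML motif format.

## Gene-neighborhood clustering

Protein families are connected components under pairwise linkage:
local alignment (BLOSUM62, gap open −11 / extend −1), linked iff identity
≥ 0.30 over aligned columns *and* coverage ≥ 0.80 of the shorter sequence.
The thresholds are a permissive family-level grouping chosen because the
original similarity-clustering tool's parameter set is unstated; both are
configurable. Conserved CIF-associated families must additionally occur in
loci of ≥ 2 distinct CIF types and show within-cluster mean identity
≤ 0.90 — an operationalisation of "diversified, not recently duplicated";
the ceiling is likewise configurable rather than inferred.

For large inputs an optional shared-4-mer prefilter (default: ≥ 3 shared
4-mers) skips alignment of pairs that could not plausibly reach the
thresholds; unrelated random proteins share ~0.1 distinct 4-mers on
average, so the filter prunes essentially only true negatives. A test
verifies filter/no-filter equivalence on simulated data; `prefilter=None`
forces exhaustive alignment.

## Enrichment test

Genes are coded 0 (background), 1–6 (the six CIF-associated functional
categories) or 7 (the core dyad); categories are recorded but unweighted —
the statistic counts non-zero codes. The scan statistic is the maximum
count of flagged genes over all windows of L consecutive genes (L = 19 by
default, the longest observed CIF locus in genes). The null is a uniform
random permutation of gene order: "random rearrangements" is not otherwise
specified, and uniform permutation is the exchangeable null that the
P-value arithmetic implies. A block-shuffle variant was considered and
deliberately left out of scope: under a window statistic on unordered
categories, block moves only reduce the effective randomisation.

The Monte Carlo estimator is `n_exceed / n_reps` with no pseudo-count, so
a P-value of 10⁻⁶ is reportable at 10⁶ replicates; a conservative
`(n_exceed + 1)/(n_reps + 1)` option exists. Sampling draws a uniform
m-subset of positions per replicate (argpartition of random keys — exact,
not approximate), and a window holds ≥ t flags iff some run of t
consecutive sorted flag positions spans ≤ L − 1. Because the statistic
depends on the vector only through (n, m), results for different
thresholds share one permutation stream, making P-values exactly monotone
in t. Windows default to linear (n − L + 1 windows; circular mode has n)
and the dyad's own genes count toward the threshold, since they are coded
non-zero.

The exact oracle enumerates all C(n, m) flag placements (guarded to
n ≤ 25) and is the reference the Monte Carlo route is calibrated against.
The calibration grid spans n ∈ {6, 10, 14}, m = ⌊n/3⌋, L ∈ {1, 2, n/2, n},
all t, both topologies, at 10⁵ replicates with a 3-standard-error band.
The grid is kept at ~70 cells on purpose: each cell is an independent
3σ check, so a much denser grid would make a spurious excursion the
expected outcome of a correct implementation rather than a defect signal.

## Sequence evolution and the incongruence test

Simulated alignments evolve under a 20-state Poisson (Jukes–Cantor-type)
model: along a branch of length b substitutions/site a site changes with
probability (19/20)(1 − e^(−20b/19)) and takes a uniform different residue.
This composes exactly along paths, giving the closed-form expected
P-distance used to calibrate the simulator. No indels are simulated —
distances use complete columns, which is the regime where the P-distance /
NJ combination is best behaved.

Neighbor joining is the standard Saitou–Nei agglomeration with negative
branch lengths clamped to zero and Q-criterion ties broken by the
lexicographically smallest label pair (internal nodes inherit their
smallest descendant leaf label), making trees deterministic. Maximum
likelihood and Bayesian inference are intentionally not reimplemented; NJ
on uncorrected P-distances is the in-repo engine, with newick import for
externally computed trees. Robinson–Foulds distance is the symmetric
difference of non-trivial bipartitions (canonical side: the one not
containing the lexicographically smallest leaf).

The segment-incongruence test builds per-segment P-distance NJ trees from
user-supplied column ranges (segment boundaries come from domain
annotation, since they are alignment-specific) and reports RF plus the
conflicting bipartitions. Mosaic families are simulated with a random
topology (mean branch length divergence/3, jittered ±50%), the
deubiquitinase segment evolving on a tree with the swapped lineage pair
exchanged. Swaps must be non-sister pairs: exchanging a cherry merely
relabels the tree. At the default study conditions (8 lineages, divergence
0.3, 2000-column segments) detection power and specificity both exceed
95% over 100 seeded replicates.

## Synthetic-data regime

The generator emulates reduced endosymbiont genomes: 100–1300 genes, 0–9
planted cifA–cifB dyads (cifA directly upstream on the plus strand),
per-locus neighbor genes from the six functional categories placed
downstream of the dyad, CR-effector-like decoys at a 5% rate, pseudogenes
at 5%. Proteins are random background with embedded literal signature
blocks; within REase blocks the filler alphabet excludes E/D/K/Q so
activity calls depend only on planted anchors. Planted families descend
from per-category founder templates (keyed by a cohort-level
`family_seed`) with 15% per-residue divergence per member — inside the
0.30 identity floor and the 0.90 diversification ceiling by a wide margin.

One global seed expands into per-component streams via
`SeedSequence.spawn` in a fixed order, so generation is bit-reproducible
and sub-draws stay stable under config changes. Ground truth (dyads,
categories, locus types, decoys, pseudogenes, segment histories) is
complete: every planted feature is recoverable from it alone.

What passing tests on this regime show: the curation logic, window
arithmetic, clustering, statistics and tree machinery are correct on data
whose truth is known exactly. What they do not show: performance on real
annotations, where domain detection is probabilistic (HMM scores, partial
domains), families have indel-rich alignments, and locus type labels come
from phylogenetic classification rather than ground truth. The headline
counts of the motivating survey (homolog totals, phyletic spread, the
ten-type classification) depend on public-database snapshots and external
search tools and are out of scope; the endosymbiont-scale enrichment run
(1300 genes, 40 coded genes, L = 19, thresholds 6–8) is a synthetic
stand-in at 10⁵ replicates that reproduces the qualitative behaviour —
sharply decreasing, highly significant P-values — not the printed numbers.

## Problem sizes used by the default test run

Chosen as the package's own standard study conditions: 50-genome cohorts
of 120-gene genomes for recovery statistics; 10⁵ Monte Carlo replicates
for calibration and the endosymbiont-scale run; 100 + 100 replicates for
incongruence power; 2000-column segments for mosaic detection; the full
15-topology suite for NJ. The exhaustive oracle is used wherever C(n, m)
is enumerable.

## Known limitations

* The motif matcher is exact-literal; it is a harness for the logic, not a
  substitute for profile-HMM searches on real proteins.
* Coverage is measured relative to the shorter sequence, so a short
  fragment can cluster with full-length members — intended for
  family-level grouping, but worth remembering when interpreting clusters.
* The permutation null treats genes as exchangeable; real rearrangements
  preserve local structure, so the reported P-values are calibrated
  against the exchangeable null only.
* NJ consistency is guaranteed on additive distances; at low divergence or
  short segments, segment trees may disagree by chance — the swap-free
  control replicates quantify that false-positive rate.
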