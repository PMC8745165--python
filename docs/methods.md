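# Methods

## Problem and model

The package attributes uremic retention solutes to gut-microbiome versus
host metabolism by joining four snapshot tables: toxins (with compound
identifiers and optional plasma concentrations), an enzymatic-reaction
catalog, organism records with reaction repertoires (bacterial strains
plus one host), and a patient detection cohort. The analysis is purely
set-theoretic and statistical — there is no flux modeling, no
stoichiometry, and no thermodynamics. A bacterium "can synthesize" a
toxin when some reaction in its repertoire, with a usable direction,
produces a compound mapped to that toxin; everything downstream
(rankings, prevalence, clustering) is built on that relation.

## Strain collapsing

Strain-level organism records are merged to one record per
case-insensitive (genus, species) pair; the merged repertoire is the
union over strains and the merged identifier is the lexicographically
smallest member id, which makes the operation deterministic and
idempotent. `sp.` is treated as an ordinary species token so genus-level
taxa remain distinct units. Conflicting host flags inside one species
group are a fatal error.

## Link semantics

A toxin mapped to several compound identifiers (isomers, salt forms)
contributes a single link per (reaction, organism); the link's role
records on which side(s) the toxin sits. Reactions with a compound on
both sides must be flagged degenerate; they are kept (role `both`)
rather than dropped, to avoid silent data loss. The per-toxin host
enzyme count is over distinct EC tokens on host-linked reactions, with
partial (dash-wildcarded) ECs counted as distinct tokens.

## Direction resolution and capability

Two annotation sources are merged with strict precedence: the primary
(module-style) direction is used whenever known; the secondary
(curated-pathway-style) direction only fills primary silence. This makes
the resolved count monotone in secondary coverage and guarantees the
primary source is never overridden — both properties are asserted in
tests. Reactions neither source annotates stay `unresolved` and
contribute nothing in strict mode.

In strict mode a pair can synthesize if some linked reaction is resolved
forward with the toxin on the product side, reverse with it on the
substrate side, or reversible; decomposition is symmetric. Reversible
reactions granting both capabilities is a deliberate choice (the
alternative, ignoring them, is available as `reversible_counts="none"`):
treating a reversible reaction as usable in either direction matches how
pathway databases mean the annotation, at the cost of inflating the
`both` class. Topology mode instead uses upstream/downstream pathway
position tags and exists because direction coverage in module-style
sources is sparse; requesting it on a catalog with no tags at all is a
fatal error pointing back to strict mode.

Producer/consumer rankings use strict inequalities (`> min_synth`,
`> min_decomp`) with defaults (5, 4); both thresholds are config keys
because different analyses legitimately use different cutoffs. The host
is excluded from rankings — producers and consumers are by definition
bacteria. Ties are broken lexicographically by organism display name for
byte-stable reports.

## Host enzyme abundance

Whole-organism abundance is operationalized as the tissue-mass-weighted
sum of expression: A(g) = Σ_T E(g,T)·w_T with w_T in grams. This is a
transcript quantity, not enzymatic activity; the package makes no
stronger claim. The distribution view uses log10(x+1) with 50
equal-width bins; the pseudo-count handles unexpressed genes. Rank
flags (bottom-k/top-k, default k=5) identify the enzymes whose host
contribution is plausibly negligible or dominant. Toxin-to-gene mapping
is restricted to toxins with 1–3 host enzymes, where a handful of genes
actually determines the host's capacity. The bimodality check in the
test suite is a crude smoothed-histogram dip criterion (a second peak of
at least 20 % of the main peak separated by a valley below half the
smaller peak) — a generator-level sanity check, not a statistical test.

## Cohort prevalence

Detection is presence/absence: mRNA count > 0, with no abundance
threshold, because reported occurrence percentages carry no stated
cutoff. Within-patient abundance enters only through quartiles: the
nonzero counts of one patient are ranked (ties get the minimum rank) and
cut as Q = ceil(4·rank/n), so Q1 is the lowest-abundance quarter and
occupancies differ by at most one when counts are distinct. Quartiles
are per patient, not pooled across patients — a transcriptome is only
internally comparable — and the per-enzyme summary class is the modal
quartile over patients where the enzyme was detected, ties resolved
toward the lower quartile. Both the per-patient labels and the summary
class are emitted, since a single summary label can hide genuine
between-patient disagreement. EC joining between cohort enzymes and the
reaction catalog honors dash wildcards in either direction
(`4.1.1.-` matches `4.1.1.85`), as metatranscriptome annotations are
often partial.

## Association

The count–concentration relation uses Spearman rank correlation
(two-sided) by default: concentrations span orders of magnitude across
solutes, and a rank statistic is invariant to monotone transforms of
either variable (a property test asserts this). Pearson is available by
config. Fewer than three usable pairs, or a zero-variance vector,
produce an explicit no-result status instead of a number.

Toxin clustering defaults to Jaccard distance on binarized producer
profiles with average linkage — grouping is by shared producer *sets* —
with Euclidean distance on log1p counts plus Ward linkage as the
configurable alternative. All-zero profile rows are excluded with a
warning. Note that agglomerative linkage is only permutation-invariant
when pairwise distances are untied; Jaccard distances on few organisms
tie easily, so the invariance test uses a continuous profile where ties
have measure zero.

## Synthetic data generator

The generator emulates the study conditions end to end with planted,
recoverable structure:

* **Planted producers/consumers.** Selected species get dedicated
  forward reactions that produce (or consume) their planted toxins and
  nothing that does the opposite, with curated (always-annotated)
  directions. All *background* toxin reactions are reversible, so every
  background (organism, toxin) pair classifies as `both` and background
  noise can never masquerade as an exclusive producer or consumer —
  recovery precision and recall are structurally 1 under full direction
  coverage.
* **Host coverage.** Every toxin outside the planted host-enzyme-free
  set shares at least one reaction with the host repertoire, so the
  "no host enzyme" candidate set equals the planted set exactly.
* **Coverage masks** for the two direction sources are drawn from a
  dedicated substream keyed by reaction order, so for a fixed seed a
  higher coverage fraction only ever adds annotations (nested masks),
  which is what the monotonicity tests exercise.
* **Cohort sampling** is presence → detection → count → protein:
  organism presence is Bernoulli (per-organism probabilities uniform on
  [0.05, 0.95] by default, giving the broad occurrence spectrum seen in
  real cohorts), an enzyme's mRNA is detected iff a carrier is present
  and detection fires (default 0.7), counts are ceil-log-normal, and
  protein detection is conditional on mRNA (default 0.3). Detection
  rates are therefore analytically checkable:
  P(detect) = (1 − (1 − p)^k)·d for k carrier species.
* **Host expression** is a two-component log-normal mixture (weights
  0.45/0.55, log10 means 0.3/2.6), reproducing the bimodal
  whole-organism transcript distribution with a poorly-expressed mode.
* **Block mode** (`n_toxin_blocks=2`) splits background toxins and
  species into disjoint groups, with one core species per block carrying
  a reaction of every toxin in its block; cross-block Jaccard distances
  are exactly 1 and within-block distances strictly below 1, so cutting
  the dendrogram at two clusters recovers the blocks exactly.
* **Concentrations** are either independent of producer counts (null
  mode) or monotone in them up to multiplicative log-normal noise
  (linked mode); linked mode with all-equal counts is a fatal error
  since no signal is plantable.

Default problem sizes are desk-scale — 30 toxins, 90 compounds, 120
reactions, 50 species with up to 3 strains, 200 patients, 12 tissues,
800 host genes — chosen so that the full pipeline and every test run in
seconds while still exercising all code paths at realistic shape.
A single integer seed drives everything through deterministically
derived substreams (one per emitted artifact), so equal parameters give
byte-identical bundles.

What the generator does **not** emulate: real pathway topology,
taxonomy, EC frequency spectra, sequencing-depth effects, compositional
correlations between organisms, or strain-level repertoire variation
beyond random subsets. Passing tests therefore demonstrate the
correctness of the joins, classifications and statistics — not that any
particular real bacterium produces any particular toxin.

## Numerical and determinism choices

All report tables are sorted by explicit keys (stable sorts, documented
tie-breaks); TSV cells holding sets are pipe-delimited and sorted. The
run manifest records seed, config hash (over the analysis-relevant
config, excluding the output path) and per-file row counts. Repeated
runs with the same config and seed produce byte-identical output
directories; this is asserted in the acceptance suite.

## Known limitations

* Capability is possibility, not activity: repertoire membership says
  nothing about expression level, kinetics, or gut conditions.
* The weighted-sum abundance treats all tissues as equally accessible
  compartments and ignores protein-level regulation.
* Union prevalence treats enzymes as exchangeable; a toxin whose
  enzymes are all in one rare pathway is indistinguishable from one
  with several independent routes at equal marginals.
* Strict and topology modes can disagree; the package reports either
  but does not arbitrate between them.
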