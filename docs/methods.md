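# Methods

## Data model

A dataset is a cells × mutations table of genotype calls in
{WT, HET, HOM, MISSING} with one timepoint label per cell, mirroring how
single whole-genome-amplified (WGA) cells are genotyped by Sanger
sequencing for a small somatic panel and scored as per-cell "VAF" codes
0 / 0.5 / 1. Accepted input tokens are {WT, 0}, {HET, 0.5}, {HOM, 1},
{NA, ., MISSING}, case-insensitive; unknown tokens are an error unless a
permissive flag maps them to MISSING. Cells whose calls are all MISSING
carry no information and are dropped with a logged warning. Timepoints
are free strings ordered by a user-supplied order (default
lexicographic).

## Clone calling

A clone is a maximal set of cells with an identical signature, at
*presence* resolution ({HET, HOM} collapsed) or *zygosity* resolution.
Cells with MISSING calls are assigned only when exactly one clone formed
from fully-defined cells matches all of their defined positions;
otherwise they are reported as unassigned, never silently dropped or
guessed. Probabilistic (dropout-aware) assignment is deliberately out of
scope: exact matching keeps every downstream count auditable.

Clones smaller than `min_cells` are retained but flagged *minor*;
display-oriented steps (the clone tree of "most represented" clones, the
prevalence table) can operate on the major clones only. The default
`min_cells` is 1 — every distinct signature is a clone.

The **mutated fraction** of a variant at a timepoint is
(#HET + #HOM) / #non-MISSING among that timepoint's cells. Zygosity
distributions are reported both over all four states and renormalized
over defined calls. Clonal heterogeneity is summarized by the Shannon
entropy (natural log) of the clone-size distribution per timepoint, a
scale-free statistic reported alongside raw clone counts.

## Mutation acquisition order

Under no-back-mutation, an earlier mutation is carried by a (weak)
superset of cells, so mutations are ranked by pooled mutated fraction,
descending. Ties break by first-timepoint fraction, then catalog order,
making the ranking deterministic and invariant to cell order.

## Perfect-phylogeny checks, repair, and tree construction

*Conflict test.* For each mutation pair, count cells (both calls
defined) with presence patterns (1,1), (1,0), (0,1). All three positive
⇒ the pair cannot lie on a single mutation tree rooted at wild-type.

*Repair.* Conflicts are removed by flipping presence calls (a gained
call becomes HET, a removed call becomes WT):

- **Exact** (≤ 6 mutations × ≤ 30 cells): iterative-deepening
  branch-and-bound. Completeness rests on the observation that any
  conflict-free solution must differ from the current matrix at some
  defined position in the two columns of any currently conflicting pair,
  so branching over those positions at each node covers all optima; the
  deepening loop guarantees the returned flip count is minimal.
  Positions are explored in (cell, mutation-rank) order, so ties resolve
  deterministically.
- **Greedy** (larger instances): repeatedly take the first conflicting
  pair in rank order, pick the *smallest* of its three witness classes,
  and flip one call of its first cell so the cell merges into the
  dominant nested pattern ((0,1)→(1,1), (1,0)→(1,1), (1,1)→(1,0) by
  dropping the lower-ranked mutation). Each position is flipped at most
  once. A max-participation rule (flip the call appearing in the most
  witnesses) was considered and rejected: witness counts are dominated
  by the *correct* majority patterns, so that rule systematically flips
  healthy calls and inflates the repair; the minority class is where the
  errors live. The greedy may exceed the true minimum and is labelled
  accordingly.

*Tree.* For a conflict-free matrix the perfect phylogeny is unique and
is built by the containment construction: thread each clone's presence
signature, mutations sorted by rank, through a prefix trie from the
wild-type root; unobserved intermediate signatures are materialized as
inferred nodes. At zygosity resolution each presence node is expanded
along single HET→HOM escalation steps: clones sharing a presence
signature are ordered by their sets of homozygous mutations and chained
from the all-HET entry variant, with intermediates always materialized
so every edge is exactly one event (gain or escalation — never a
compound edge, never a reversion). Escalations are canonically placed
*after* the gains of a node (the data cannot distinguish the true
interleaving); within ties, mutation rank decides. Sibling order is
mutation rank order. An unobserved all-wild-type root with a single
child is pruned, so the root is the minimal observed signature when the
data contain no wild-type cells.

Trees serialize to Newick with event labels in `[&event=...]` comments
(round-trip parseable) and to JSON (nodes, edges, events).

## Temporal dynamics

Clones are matched across timepoints by exact signature — a clone that
changes zygosity is a different clone. `own_fraction` is the clone's
cell count over the timepoint's assigned cells; `nested_fraction` adds
all descendants, computed bottom-up (so parent ≥ child holds by
construction). A proportional-rescale helper handles externally supplied
nested values that violate nesting (children scaled by parent/sum,
logged) — the fishplot convention requires nesting, and violations
diagnose noise rather than being hidden. Both own and nested values are
emitted (tables and timescape/fishplot-convention JSON), since published
fishplots do not always state which convention they use.

## Allele dropout

With per-allele dropout rate *d* acting independently on both alleles:

| true | WT | HET | HOM | MISSING |
|------|-----|-----|-----|---------|
| WT   | 1−d² | 0 | 0 | d² |
| HET  | d(1−d) | (1−d)² | d(1−d) | d² |
| HOM  | 0 | 0 | 1−d² | d² |

Three estimators of *d* from one mutation's cell counts, with
amplification-free colony genotypes as reference:

- **moment** (default when the cells' MISSING count is supplied):
  d̂ = √(missing fraction). Because P(MISSING) = d² for every true
  genotype, this is the MLE under the package's standing assumption that
  colonies may be fitness-biased (their counts then carry no information
  about the cells' genotype mix). It is also well behaved at d = 0,
  where contrast-style estimators suffer a boundary effect (sampling
  noise in the heterozygote deficit is converted into spurious positive
  estimates about half the time). Caveat: it attributes *all*
  missingness to dropout, so it overestimates d when calls are missing
  for other reasons; use the conditioned estimators in that case.
- **contrast**: plug the colony distribution in as the true mix, push it
  through the dropout model conditioned on non-MISSING, and minimize the
  3-category multinomial negative log-likelihood by golden-section
  search on [0, 0.5] (tolerance 1e-6). Unbiased when colonies are
  representative, but its sampling error at a few hundred cells and ~100
  colonies is large (SD ≈ 0.06): the heterozygote-deficit signal is
  weak and colony sampling noise propagates directly.
- **joint**: full MLE of (mix, d) from the 4-category cell likelihood
  plus the colony multinomial (Nelder–Mead on logit-transformed
  parameters, three starts), assuming unbiased colonies.

Identifiability: with no heterozygous colonies the dropout-distorted
defined-genotype distribution is indistinguishable from the mix itself,
so contrast/joint report the estimate as unidentifiable rather than a
number. Confidence intervals are seeded percentile bootstraps (default
1000 resamples of both tables), widened if necessary to contain the
point estimate so the reported triple is always coherent.

*Exact tests.* The 2×2 Fisher test is two-sided by the
point-probability rule — sum hypergeometric probabilities ≤ the observed
table's, with a 1+1e-9 relative tolerance for float ties and
normalization by the full support sum so an all-inclusive p is exactly
1; a zero margin returns p = 1 with a warning. The 2×3 cells-vs-colonies
comparison uses the Freeman–Halton extension: full enumeration with
exact integer table weights when the grand total is ≤ 200, otherwise
seeded Monte Carlo (10⁵ draws from the margin-conditional distribution
via multivariate hypergeometric sampling) with the add-one p-value rule,
so a Monte-Carlo p is never exactly zero.

## Synthetic data generator

The generator defines the study conditions the pipeline is validated
under: 3 timepoints × 300 cells, a 7-mutation panel, and a 9-clone truth
tree whose prevalences reproduce, in expectation, the printed
mutated-cell percentages of the emulated case — TP53 rising 20.8% → 63%
then declining, FLT3 rising 16.6% → 25% → 35.6%, the fully-mutated clone
at 9% / 15% / 23%, and FLT3 homozygotes present only at the third
(leukemic) timepoint. Values not printed anywhere were fixed once as
emulations and are listed in `config.emulated`: the prevalences of the
five early clones (chosen so clone-size entropy rises across timepoints,
matching the observed increase in clonal heterogeneity), the TP53
fraction at T3 (0.40 — declining, consistent with the halving of the
bulk TP53 VAF, and bounded below by the nested FLT3 lineage), and the
chain topology (with 7 mutations a perfect phylogeny admits at most 8
presence-distinct clones, so a 9-clone tree necessarily uses zygosity
escalations; the two escalations are placed on the TP53/FLT3 lineage the
case's zygosity dynamics highlight).

Default noise: per-allele ADO 0.1 (typical of PCR-based WGA), miscall
0.01, extra missingness 0.01, 50 colonies per timepoint with equal
colony fitness. Observation order is ADO → miscall (a defined state is
replaced by one of the other two, uniformly) → extra missingness. One
seed drives everything; per-timepoint substreams are derived
deterministically (`SeedSequence([seed, k])`), so partial re-runs
reproduce.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: SRSF2 homozygosity among the nine major
clones (in the real case ~39% of T1 cells were SRSF2-homozygous; adding
it would need a tenth clone), the full 52-clone frequency spectrum,
locus-specific amplification bias, doublets, and chimeric WGA artifacts.
Colony fitness bias is a capability (any clone can be re-weighted,
including to zero) exercised by tests, not a default.

## Validation sizes and numerical choices

The test suite validates the tree construction against brute-force
enumeration of all rooted mutation trees on 1000 random conflict-free
matrices (≤ 6 mutations × ≤ 30 cells), repair minimality against
exhaustive search on 200 planted-error instances (≤ 5 × 12, ≤ 3 flips),
estimator recovery over 100 seeded replicates per dropout rate at 300
cells / 100 colonies, and the Fisher p-value against exact rational
enumeration for every 2×2 table with margins ≤ 15. These sizes were
chosen so the whole suite runs on a laptop in minutes while the
combinatorial checks remain exhaustive.

Determinism: clone labels are assigned by size then signature; repairs,
tree sibling order, and tie-breaks are rank-based; output tables use a
fixed float format; pipeline manifests carry SHA-256 hashes of every
artifact, and identical config + seed reproduce identical hashes.

## Known limitations

- No loss-of-heterozygosity, back-mutation, or copy-number-aware events:
  a HOM→HET transition in real data will surface as a conflict or an
  extra clone, not be modelled.
- The greedy repair is heuristic; flip counts on large noisy matrices
  are upper bounds and repairs may merge genuine rare clones into their
  neighbors.
- Exact-signature clone prevalences are biased downward under dropout
  (a k-heterozygous clone survives intact with probability (1−d)^2k);
  the pipeline reports what it observes, and prevalence recovery is
  validated on the simulator's truth labels and noise-free runs.
- The moment ADO estimator conflates dropout with any other source of
  missingness; the contrast estimator is unbiased only if colony
  outgrowth is representative. Both caveats are intrinsic to the design
  (one locus, marginal counts) rather than implementation choices.
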