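# Methods

## Sign-propagation model

The core procedure treats regulation as integer sign algebra on a directed
graph. A link `u →ˢ v` asserts that `u`'s activity moves `v` in direction
`s` (+1 activation, −1 repression, 0 unknown). Under a perturbation of a
root regulator the expected misregulation of a target along a path is the
product of the edge signs times the root's direction; the *consistency*
relation `d(u)·s = d(v)` is the one-edge version of that statement.

**Scoring rule.** For an unobserved gene `u`,
`score(u) = Σ s·d(v)` over signed out-edges whose child direction is
known, and `d(u) = sign(score(u))`; a zero sum yields *no prediction*.
This concrete rule — an unweighted integer vote over downstream children,
with the sign of the sum as the prediction — is a reconstruction: the
published description of this class of tool gives the iteration scheme
(score upstream regulators from the known misregulated genes, iterate to
the top of the cascade) and the existence of no-prediction outcomes, but
not the exact arithmetic. The vote-sum rule is the simplest rule
consistent with all described behaviours (no-prediction ties, consistency
filtering, upstream iteration) and is flagged here as a design choice.
Parallel edges between the same pair cannot survive deduplication with
different signs and identical directions, so "per edge" and "per child"
summation coincide after dedupe.

**Iteration and cycles.** Updates are synchronous sweeps: every free
node's score is recomputed from the previous sweep's directions, until a
fixed point or `max_iter` (default 100) sweeps. On acyclic graphs this
converges in at most depth-many sweeps. Real interaction compilations
contain cycles; a negative feedback loop can oscillate, in which case the
still-changing nodes are demoted to no-prediction with a warning rather
than being assigned an arbitrary phase of the oscillation.

**Root convention.** Knockout fixes the root at −1 (the regulator is
absent), so a repressive root edge predicts target *up* — the derepression
logic by which miRNA targets surface in knockout transcriptomes.
Overexpression fixes +1. Observed directions always override propagation;
conflicts are reported, never resolved silently.

**Unsigned links** participate in path restriction (they carry
connectivity) but contribute nothing to scores and are always removed by
pruning: a sign-free edge cannot be checked for consistency.

**Ordering.** Pruning precedes shortest-path extraction, and with several
roots the per-root shortest-path sets are unioned; all tied minimum-length
paths are kept. Discarding ties would require an arbitrary edge order and
would make the output depend on input file ordering.

## Interaction tables

Dedupe identity is `(source, sign, target)`; evidence tags of collapsed
duplicates are ";"-joined in first-seen order. Interaction words map to
signs case-insensitively through a configurable vocabulary
(activates/upregulates → +1; represses/inhibits/downregulates → −1;
regulates/unknown → 0 with a warning). Gene IDs are compared
case-sensitively after whitespace trimming — public compilations mix
symbol conventions, and silent case-folding could merge distinct genes; a
normalisation hook is available where one convention is known to apply.
Orthologue conversion renames an endpoint only when the mapping is
one-to-one; interactions touching ambiguous mappings are dropped and
counted, while endpoints absent from the map are assumed already native
(the use case maps one foreign species into an otherwise-native set).
Seed-match target edges are emitted once per (miRNA, upregulated gene)
pair with ≥1 seed-complement match, regardless of match count.

## Seed scanning

The seed complement is the reverse complement, in DNA alphabet, of mature
bases 2–8 (1-based, inclusive); both coordinates are configurable.
Matching is exact, case-insensitive, and counts overlapping windows (`N`
never matches) — the standard motif-count convention, and the one the
brute-force oracle in the tests implements independently. Counts for genes
with several UTR isoforms are summed over all FASTA records sharing the
gene ID (with a per-record breakdown retained): whether a per-gene count
should use the longest isoform instead is not determined by the use case,
and summation is the conservative superset. Strain comparison first drops
genes without a shared (MGI-style) ID — without one the counterpart gene
cannot be identified — then classifies each gene into one of eight
mutually exclusive categories (same count, both-present-different-count,
only-in-A/B, absent-in-both, missing-UTR-A/B/both), which partition the
universe.

## Enrichment landscape

The word universe is defined over word *tokens* (positions), not gene
presence/absence: a UTR of length L contributes max(0, L−6) overlapping
7-mer windows (windows containing non-ACGT characters are skipped), giving
universe size N and per-word totals K_w. For each cumulative leading bin
of n tokens with x occurrences of word w, `p_enrich = P[X ≥ x]` and
`p_deplete = P[X ≤ x]` under `Hypergeometric(N, K_w, n)`; the signed score
is `−log10(p_enrich)` when enrichment is the smaller tail, else
`+log10(p_deplete)`. The final bin equals the universe, where x = K_w and
every score is exactly 0 (asserted, not just expected). Words absent from
the universe are omitted from the output; by the same algebra their score
is 0 everywhere. Raw p-values are reported; the Bonferroni line over all
4^7 heptamers at α = 0.05 (≈5.5 on the −log10 scale) is an annotation
only. Known simplifications relative to dedicated landscape tools:
no composition-bias (Markov background) correction and no word purging, so
scores for low-complexity words are less conservative than those tools
would report. Ranking ties are broken by input order and logged.

## Centralities

Degree counts incident edges (in + out); antiparallel edges count
separately and self-loops once (conventions for self-loops vary across
viewer versions, so the choice is pinned here). Betweenness is directed by
default — regulatory edges have direction — normalised by (n−1)(n−2), with
self-loops excluded and unreachable ordered pairs contributing 0; an
undirected mode exists for comparison. The implementation delegates to
networkx's Brandes algorithm; the tests compare it against an exhaustive
all-paths enumeration oracle on graphs of ≤ 8 nodes.

## Design statistics

`power_two_group_z` uses the two-sided two-sample normal approximation
with a Welch-type standard error:
`power = Φ(δ / √(sd₁²/n₁ + sd₂²/n₂) − z_{1−α/2})`. This form exactly
reproduces the two self-contained published design powers it is tested
against (97.7% for Δ=7, sd=2.5, n=4/group; 97.9% for Δ=0.4, sd=0.01/0.2,
n=4/group) and is adopted as the definition; as δ→0 it tends to α/2 and it
is monotone in δ, n and 1/sd. A third published power (99.7% for a 15 dB
difference, sd 8.45, n=6) is **not** reproduced by this form (it gives
~85%) and that computation — presumably a different design or tool — is
documented as out of reach rather than approximated.

`ratio_summary` reports the observed category percentage (one decimal) and
a 1-df two-category chi-squared goodness-of-fit against the expected
proportion (default 0.25, the homozygote fraction of a heterozygote
intercross). For the 43/242 observation this gives χ² = 6.75, p ≈ 0.009;
the source report prints p = 0.029 for the same counts, which this test
structure does not reproduce — the discrepancy is documented rather than
reverse-engineered, and the printed p is not used anywhere.

## Synthetic data

The generators exist so every pipeline stage is testable without
downloads; all are pure functions of (parameters, seed), each drawing from
its own named stream so adding a generator never perturbs existing
fixtures.

* **Cascades** (`gen_cascade`): a spanning tree grown from the root with
  signed edges (default equal +1/−1 probability, no unsigned edges), true
  directions assigned top-down via `d(child) = d(parent)·sign`, plus
  level-ordered cross-edges (default probability 0.15 per node) signed to
  be consistent with the planted truth — keeping the graph acyclic and
  making noise-free recovery provably exact, which keeps the
  parameter-recovery check sharp. `fraction_observed` samples *leaf* genes
  as the exported measurements (default 1.0), flipped with probability
  `noise` (default 0); internal genes are withheld as recoverable truth.
  Defining observation over leaves makes "recover the internal directions"
  a real prediction task rather than a tautology. Default size 200 nodes,
  depth 6. Unsigned decoy edges can be enabled via `sign_probs`; they are
  always pruned, so they are off by default.
* **UTR sets** (`gen_utr_set`): uniform-random DNA of lengths 50–300 by
  default; a planted heptamer overwrites a random window of each planted
  gene's UTR, and insertion positions are returned so expected minimum
  counts are known. Background match counts follow the binomial
  (L−6)·4⁻⁷ expectation, which the tests check within 3 SD over 1000 UTRs.
* **Ranked lists** (`gen_ranked_list`): a decreasing synthetic statistic
  over n genes; genes in the leading `top_fraction` receive (with
  probability 0.9 by default) a fixed number of non-overlapping copies of
  the enriched heptamer, so the planted word's landscape peak falls in the
  leading bins; `top_fraction = 1` plants uniformly and yields no
  positional signal.

What the generators deliberately do **not** emulate: the topology
statistics of real interaction compilations (degree distributions,
cross-database redundancy), correlated noise between observed genes, UTR
base composition and repeat structure, and isoform structure beyond
multiple records per gene. Passing the recovery and calibration tests
therefore demonstrates algorithmic correctness under the stated model, not
performance on real compilations, where unsigned and erroneous links are
common and no-prediction outcomes are frequent.

## Problem sizes and numerical choices

The test suite and the reproduction script use planted cascades of 200
nodes (20 replicates), 500 random ≤ 8-node graphs for the
exhaustive-oracle comparisons, 1000 random UTRs for match-count
verification and 100–200 replicates for the Monte-Carlo calibration of the
landscape — sizes chosen so every exhaustive oracle remains tractable
while each check still exercises hundreds to thousands of independent
cases. Hypergeometric tails come from scipy (`sf(x−1, ...)` for P[X ≥ x]),
clipped away from 0/1 before taking logarithms. The hold-out validation
battery in the reproduction script is synthetic: planted single-study
networks whose verdict composition (7 correct / 3 incorrect / 4
no-prediction over 14 genes) mirrors the scale of the published hold-out
evaluation, since the original studies' inputs are not redistributable
here; it validates the verdict machinery, not the historical result.

## Known limitations

* The scoring rule is a documented reconstruction (see above); alternative
  rules (e.g. weighting by fold-change, counting distinct children once)
  would change tie behaviour.
* No probabilistic or magnitude-weighted propagation — integer signs only.
* Landscape scores are raw hypergeometric p-values without background
  correction; cross-tool numeric equivalence is approximate at best.
* The published compiled interaction set (~10⁵ links) is not
  reconstructable from public snapshots, so published network sizes
  (e.g. a 114-gene/416-link result) are out of scope for verification.
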