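# Methods

## Problem setting

The learner takes (i) a two-dimensional binary matrix (rows = genes,
columns = samples; numeric matrices are thresholded first), (ii) one
or more OBO ontologies, and (iii) direct annotation maps from row ids
and column ids to term ids. Every matrix cell is one example,
identified by its (row-id, col-id) pair; 1-cells are positive,
0-cells negative. In treatment/control mode the examples are instead
the selected rows crossed with the treatment columns (positive) and
control columns (negative), ignoring cell values. A rule is a set of
terms read as a conjunction; the goal is a small list of significant
rules that together cover the positives.

## Orders, covers, and propagation

Each ontology is a DAG of `is_a` edges (`part_of` is opt-in, because
`is_a` is the only universally safe subsumption relation); the partial
order ≽ is the reflexive-transitive closure of the edge relation,
computed with networkx reachability and validated to be acyclic at
construction. Terms of different ontologies are never comparable, so
rules may freely mix gene-side and sample-side terms. Obsolete terms
are skipped; annotation terms absent from every loaded ontology are
dropped with a logged count rather than an error (real annotation
maps routinely carry retired ids).

Direct annotations are propagated once per run into per-term covers
S(t) = union of direct example sets over t and all its descendants; a
row-axis term covers whole matrix rows restricted to the examples in
scope, dually for columns. The rule cover Θ(R) is the intersection of
member covers; the empty rule is the empty conjunction and covers
everything in scope. Covers are plain frozensets and all cover algebra
is set intersection — adequate at the problem sizes this package
targets and trivially exact.

## Quality and its admissible bound

Three evaluators are provided, selected by token `acc | f1 | auc`,
each with a potential-quality companion Q_p that assumes the best
possible refinement (all covered negatives become uncovered, no
covered positive is lost):

| token | Q | Q_p |
|---|---|---|
| acc | (TP+TN)/N | (TP+TN+FP)/N |
| f1 | 2TP/(2TP+FP+FN) | 2TP/(2TP+FN) |
| auc | FPR·TPR + (1−FPR)·TPR + (1−FPR)(1−TPR)/2 | TPR + (1−TPR)/2 |

Since refining a conjunction can only shrink its cover, Q of any
specialization is bounded by Q_p of the rule — the admissibility that
makes non-potential pruning sound. The suite verifies it exhaustively
over all sub-covers of small worlds rather than trusting the algebra.
The AUC form is a single-point geometry that yields 1 at
TPR = FPR = 1 (unlike the usual single-point trapezoid, which yields
1/2 there); it is kept in this form because its companion bound is
admissible for it and the pair is only ever used relative to itself.
F1 with a zero denominator is defined as 0 rather than an error: an
empty-cover rule is a legal, merely worthless, candidate during
search.

## Significance

Rule significance uses a likelihood-ratio statistic compared against
the χ²(1 df) quantile at the configured confidence level (6.635 at
99%). Two variants exist:

* `printed` (default): covered-set size TP+TN, class terms TP and TN.
* `cn2` (classical): covered-set size TP+FP, class terms TP and FP —
  the in-cover class mix against the global class prior.

The printed variant has two consequential edge cases, characterized in
the test suite: a perfect rule (FP = FN = 0) scores exactly 0 —
its "covered set" TP+TN is then the whole example set, so the compared
distributions coincide — and an empty cover (TP = FP = 0) scores
*positive* whenever both classes are present, because TP+TN
degenerates to the correctly-classified negatives. Hence under the
printed form no perfect rule can ever pass the gate, and the
`onlySig` feature-selection method may keep empty-cover terms, which
breaks the otherwise-natural nesting `onlySig ⊆ sigAtLeastOne`. The
classical form has neither pathology. The printed form remains the
default for fidelity; every test about recovery, pruned/unpruned
equivalence, or feature-set nesting states the variant it runs under
(`cn2`), for the reasons above. The convention 0·log₂(·) = 0 applies,
and any term with a degenerate ratio contributes 0.

## Search

`induce_single_rule` grows conjunctions from the empty rule, one term
per level, up to `max_rule_length` levels:

1. Every beam rule is extended by every admissible feature. With
   pruning on, extensions containing a ≽-comparable pair (Redundant
   Generalizations — including duplicates, via reflexivity) are
   discarded *before* evaluation: by cover preservation they add
   nothing. Identical term sets from different parents are merged.
2. The surviving term sets are evaluated in lexicographic order
   (cover, confusion counts, Q, Q_p, LRS); each unique term set
   counts once per level toward `explored_rules`.
3. The incumbent is updated by any candidate with strictly greater
   quality *that also passes the significance gate* (the gate guards
   becoming the best rule, not beam membership). Ties keep the
   earliest candidate in the deterministic order.
4. With pruning on, candidates whose Q_p is strictly below the
   incumbent quality are dropped (Redundant Non-potentials) — their
   subtrees are never generated. The bound is held fixed while a
   level is generated and refreshed from that level's evaluations
   before the beam filter; this choice affects explored counts only,
   never the final quality.
5. The `beam_width` best survivors (quality desc, then larger cover,
   then lexicographic term tuple) seed the next level.

The incumbent score starts at 0 in every single-rule induction; it is
not carried across covering iterations. `sem1r` wraps the induction in
the covering loop: induce, report the rule with the score it obtained
on the example set it was induced from, remove covered examples,
repeat until the positives are exhausted, `max_rules` is reached, or
no significant rule is found. Removal defaults to excluding *all*
covered examples; `positives-only` gives the classical CN2-unordered
behaviour. The loop also stops if either class empties (AUC is
undefined without both classes, and a one-class remainder admits no
significant rule). `run_exhaustive_baseline` is the identical search
with both reductions disabled — the traditional refinement operator —
used for equivalence and economy comparisons.

Determinism: features are ordered lexicographically by term id,
candidate generation and evaluation follow that order, and all
tie-breaks are explicit, so runs are bit-reproducible; the
`random_seed` field is reserved and currently unused.

## Feature selection

Per induction call, from all loaded terms: `atLeastOne` keeps terms
whose cover intersects the current scope; `onlySig` keeps terms whose
singleton rule passes the LRS gate; `sigAtLeastOne` keeps
non-empty-cover terms that are significant or generalize a significant
term. Under the classical statistic the three are nested by size.

## Synthetic data

The packaged toy world (7 terms t0..t6, examples e1..e3, E⁺ = {e1,e3})
pins every hand-derivable quantity: all seven propagated covers, the
cover of {t0,t2}, the counts (TP=2, FP=1, TN=0, FN=0) and accuracy 2/3
of {t2}, the accuracy 0 and potential 1/3 of {t3}, and the
non-potential pruning of {t3} against an incumbent at 2/3. The edge
set is a committed reconstruction; tests assert the cover invariants,
not the edges, so any reconstruction inducing the same covers is
equivalent.

Random instances draw a single-rooted DAG (each later term picks 1..k
earlier parents), annotate every row (and optionally column) entity
with exactly two direct terms — one-term entities yield pure ancestor
chains containing no incomparable pair, which would make rule planting
infeasible — then plant a pairwise-incomparable conjunction sampled
greedily from an anchor entity's covering terms, rejecting empty or
universal covers. Covered cells become 1, others 0, and each cell is
flipped independently with the configured noise probability
(symmetric noise is the package's choice; nothing in the generator
models expression-scale effects, dropout, or correlated noise, so
passing recovery tests speak to the search's correctness, not to
robustness on real expression data). Generators are bit-reproducible
under fixed seeds; a parameter draw admitting no usable conjunction
raises a generation error rather than silently degrading.

## Test-scale choices and tolerances

Quality equality between pruned and unpruned search is asserted to an
absolute 1e-12 (identical covers give identical floating-point
pipelines; the tolerance absorbs nothing but guards against future
reordering). The equivalence sweep uses 50 instances per evaluator ×
feature-selection combination on 12-term ontologies and 8×5 matrices
with rule length ≤ 3 and beam 200 — sized so the candidate pool never
exceeds the beam, which makes the pruned/unpruned equality exact; with
a binding beam the two searches may retain different candidate sets
and the equality becomes only empirical. Exhaustive-enumeration
oracles (admissibility over all sub-covers, full rule-space search)
run on worlds of ≤ 12 examples and ≤ 10-term ontologies. The noisy
recovery check uses twenty ~500-cell instances at 5% noise and
requires Jaccard ≥ 0.8 between the first induced cover and the
planted cover in at least 18 of them.

## Known limitations

* Covers are materialized as per-term example sets; very large
  matrices or ontologies (10⁴⁺ terms) would want bitset or sparse
  representations.
* The significance gate is per-rule; no multiple-testing control is
  applied across the many candidates examined.
* Rules are conjunctions of positive terms only — no negation,
  disjunction, or numeric conditions — and labels are binary.
* The explored-rule count is an implementation-defined economy metric
  (unique term sets evaluated per level); it supports the
  pruned ≤ unpruned comparison but is not comparable across
  differently structured implementations.
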