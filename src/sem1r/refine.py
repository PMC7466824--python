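"""The ontology-based refinement operator and its two reductions.

Refining a rule means appending one admissible feature (ontology term)
to its conjunction.  Two sound reductions shrink the candidate set:

* **Redundant Generalization** — a candidate containing two comparable
  terms (one more general than the other, duplicates included via
  reflexivity) covers exactly what the reduced rule covers, so it is
  dropped without ever being evaluated.
* **Redundant Non-potential** — a candidate whose potential quality
  Q_p falls strictly below the best quality found so far cannot, nor
  can any of its specializations, beat the current best; it is dropped
  after evaluation and its entire subtree is never generated.

Neither reduction can remove a rule that would have improved the final
result; both are pure search-space economy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .data import ExampleId, ExampleSet, SemanticCover, rule_cover
from .ontology import OntologySet
from .scoring import RuleScore, score_rule

__all__ = [
    "Rule",
    "evaluate_rule",
    "has_redundant_generalization",
    "remove_redundant_generalizations",
    "remove_redundant_nonpotentials",
    "refine_rule",
]


@dataclass(frozen=True)
class Rule:
    """A conjunction of ontology terms with its cached cover and score."""

    terms: frozenset[str]
    cover: frozenset[ExampleId]
    score: RuleScore | None = None

    def __post_init__(self):
        object.__setattr__(self, "terms", frozenset(self.terms))
        object.__setattr__(self, "cover", frozenset(self.cover))

    def key(self) -> tuple[str, ...]:
        """Deterministic identity: the sorted term tuple."""
        return tuple(sorted(self.terms))

    def __len__(self) -> int:
        return len(self.terms)


def evaluate_rule(
    terms: Iterable[str],
    cover_map: SemanticCover,
    examples: ExampleSet,
    evaluator: str = "acc",
    alpha: float = 0.01,
    lrs_variant: str = "printed",
) -> Rule:
    """Compute a rule's cover within the current example scope and score it."""
    scope = examples.all_examples
    cover = rule_cover(terms, cover_map, scope) & scope
    return Rule(
        terms=frozenset(terms),
        cover=cover,
        score=score_rule(cover, examples, evaluator, alpha, lrs_variant),
    )


def has_redundant_generalization(
    terms: Iterable[str], ontologies: OntologySet
) -> bool:
    """True iff any two terms of the rule are comparable under the order."""
    terms = sorted(set(terms))
    return any(
        ontologies.comparable(t1, t2) for t1, t2 in combinations(terms, 2)
    )


def remove_redundant_generalizations(
    candidates: Iterable[Rule], ontologies: OntologySet
) -> list[Rule]:
    """Keep only rules in which no pair of terms is comparable."""
    return [
        r
        for r in candidates
        if not has_redundant_generalization(r.terms, ontologies)
    ]


def remove_redundant_nonpotentials(
    candidates: Iterable[Rule], best_quality: float
) -> list[Rule]:
    """Keep only rules whose potential quality reaches the current best.

    Strictly lower potential prunes the rule together with its whole
    (never generated) specialization subtree; ties survive, preserving
    the guarantee of finding an equal-quality rule.
    """
    kept = []
    for r in candidates:
        if r.score is None:
            raise ValueError("non-potential filtering requires scored rules")
        if r.score.potential >= best_quality:
            kept.append(r)
    return kept


def refine_rule(
    rule: Rule,
    features: Iterable[str],
    ontologies: OntologySet,
    best_quality: float,
    examples: ExampleSet,
    cover_map: SemanticCover,
    evaluator: str = "acc",
    alpha: float = 0.01,
    lrs_variant: str = "printed",
    prune: bool = True,
) -> list[Rule]:
    """One refinement step: append each admissible feature to ``rule``.

    Candidates that are Redundant Generalizations are discarded before
    evaluation (their covers are provably unchanged); the survivors are
    evaluated and then filtered by the Non-potential bound against
    ``best_quality``.  With ``prune=False`` both reductions are skipped
    and every distinct extension is evaluated — the traditional
    exhaustive refinement.  Identical term sets are merged; output order
    is deterministic (lexicographic by sorted term tuple).
    """
    term_sets: dict[tuple[str, ...], frozenset[str]] = {}
    for f in features:
        if f in rule.terms:
            continue
        if prune and any(ontologies.comparable(f, t) for t in rule.terms):
            continue
        new_terms = rule.terms | {f}
        term_sets.setdefault(tuple(sorted(new_terms)), frozenset(new_terms))

    evaluated = [
        evaluate_rule(term_sets[k], cover_map, examples, evaluator, alpha, lrs_variant)
        for k in sorted(term_sets)
    ]
    if prune:
        evaluated = remove_redundant_nonpotentials(evaluated, best_quality)
    return evaluated
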