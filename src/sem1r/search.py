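"""Beam-searched rule induction and the separate-and-conquer covering loop.

``induce_single_rule`` grows conjunctions from the empty rule, one term
per level, keeping the ``beam_width`` best candidates per level and
tracking the best rule found so far.  A rule only becomes the incumbent
if its quality strictly exceeds the incumbent's *and* its likelihood
ratio passes the significance gate.  With pruning enabled, candidates
that are Redundant Generalizations are never evaluated and candidates
whose potential quality falls below the incumbent are dropped after
evaluation (see :mod:`sem1r.refine`).

``sem1r`` wraps that in the classical covering loop: induce a rule,
remove the examples it covers, repeat until the positives are exhausted,
the rule budget is reached, or no significant rule can be found.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from typing import Iterable

from .data import ExampleId, ExampleSet, SemanticCover
from .ontology import OntologySet
from .refine import Rule, evaluate_rule
from .scoring import confusion_counts, is_significant, lrs

__all__ = [
    "SearchConfig",
    "SearchStats",
    "RuleSet",
    "select_features",
    "filter_rules",
    "induce_single_rule",
    "sem1r",
    "run_exhaustive_baseline",
]

logger = logging.getLogger(__name__)

FEATURE_SELECTION_METHODS = ("atLeastOne", "onlySig", "sigAtLeastOne")


@dataclass(frozen=True)
class SearchConfig:
    """All knobs of the rule search.

    Defaults mirror a typical production run: beam of 100, rules of at
    most 10 terms, at most 10 rules, 99% significance.  ``pruning=False``
    turns the ontology-based operator into the traditional exhaustive
    refinement (the beam still applies).  ``random_seed`` is reserved:
    all tie-breaking is deterministic, so no randomness is consumed.
    """

    evaluator: str = "acc"
    feature_selection: str = "atLeastOne"
    beam_width: int = 100
    max_rule_length: int = 10
    max_rules: int = 10
    significance_level: float = 0.99
    covering_removal: str = "all-covered"
    pruning: bool = True
    lrs_variant: str = "printed"
    random_seed: int | None = None

    def __post_init__(self):
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.max_rule_length < 1:
            raise ValueError("max_rule_length must be >= 1")
        if self.max_rules < 1:
            raise ValueError("max_rules must be >= 1")
        if not 0.0 < self.significance_level < 1.0:
            raise ValueError("significance_level must be in (0, 1)")
        if self.feature_selection not in FEATURE_SELECTION_METHODS:
            raise ValueError(
                f"unknown feature selection {self.feature_selection!r}"
            )
        if self.covering_removal not in ("all-covered", "positives-only"):
            raise ValueError(
                f"unknown covering removal policy {self.covering_removal!r}"
            )

    @property
    def alpha(self) -> float:
        """Significance level as a tail probability (0.99 -> 0.01)."""
        return 1.0 - self.significance_level


@dataclass
class SearchStats:
    """Search-effort accounting.

    A candidate counts as explored when its cover and score are
    evaluated, once per unique term set per refinement level.
    """

    explored_rules: int = 0
    runtime: float = 0.0
    per_rule_breakdown: list[int] = field(default_factory=list)

    def merge(self, other: "SearchStats") -> None:
        self.explored_rules += other.explored_rules
        self.runtime += other.runtime
        self.per_rule_breakdown.extend(other.per_rule_breakdown)


@dataclass(frozen=True)
class RuleSet:
    """Ordered induced rules plus the positives no rule ever covered."""

    rules: tuple[Rule, ...]
    uncovered_positives: frozenset[ExampleId]

    def __len__(self) -> int:
        return len(self.rules)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features(
    method: str,
    all_terms: Iterable[str],
    cover_map: SemanticCover,
    examples: ExampleSet,
    ontologies: OntologySet,
    alpha: float = 0.01,
    lrs_variant: str = "printed",
) -> list[str]:
    """Select admissible features (terms) for refinement.

    ``atLeastOne`` keeps terms covering at least one in-scope example;
    ``onlySig`` keeps terms whose singleton rule is significant by LRS;
    ``sigAtLeastOne`` keeps non-empty-cover terms that are significant
    themselves or generalize a significant term.  Output order is
    lexicographic by term id, which fixes candidate generation order.
    """
    scope = examples.all_examples
    all_terms = sorted(set(all_terms))

    def covered(t: str) -> frozenset:
        return cover_map.get(t) & scope

    def significant(t: str) -> bool:
        statistic = lrs(
            confusion_counts(covered(t), examples), variant=lrs_variant
        )
        return is_significant(statistic, alpha)

    if method == "atLeastOne":
        return [t for t in all_terms if covered(t)]
    if method == "onlySig":
        return [t for t in all_terms if significant(t)]
    if method == "sigAtLeastOne":
        sig = {t for t in all_terms if significant(t)}
        generalizes_sig = set(sig)
        for t in sig:
            generalizes_sig.update(ontologies.ancestors(t))
        return [t for t in all_terms if covered(t) and t in generalizes_sig]
    raise ValueError(f"unknown feature selection method {method!r}")


# ---------------------------------------------------------------------------
# beam
# ---------------------------------------------------------------------------

def _beam_key(rule: Rule):
    # quality desc, then larger cover, then lexicographic term tuple
    return (-rule.score.quality, -len(rule.cover), rule.key())


def filter_rules(candidates: Iterable[Rule], beam_width: int) -> list[Rule]:
    """Keep the ``beam_width`` best scored rules, deterministically."""
    return sorted(candidates, key=_beam_key)[:beam_width]


# ---------------------------------------------------------------------------
# single-rule induction
# ---------------------------------------------------------------------------

def induce_single_rule(
    examples: ExampleSet,
    ontologies: OntologySet,
    cover_map: SemanticCover,
    cfg: SearchConfig,
) -> tuple[Rule | None, SearchStats]:
    """Find the best single significant rule by beam search.

    Returns ``(None, stats)`` when no candidate passes the significance
    gate, or when feature selection leaves nothing to refine.
    """
    start = time.perf_counter()
    stats = SearchStats()
    if not examples.positives or not examples.negatives:
        stats.runtime = time.perf_counter() - start
        return None, stats

    features = select_features(
        cfg.feature_selection,
        ontologies.term_ids,
        cover_map,
        examples,
        ontologies,
        cfg.alpha,
        cfg.lrs_variant,
    )
    if not features:
        logger.warning("feature selection left no admissible features")
        stats.runtime = time.perf_counter() - start
        return None, stats

    best_rule: Rule | None = None
    best_score = 0.0
    # level 0: the empty conjunction, covering everything in scope;
    # it is the refinement seed, not a reportable candidate
    beam: list[Rule] = [Rule(frozenset(), examples.all_examples)]

    for level in range(cfg.max_rule_length):
        term_sets: dict[tuple[str, ...], frozenset[str]] = {}
        for parent in beam:
            for f in features:
                if f in parent.terms:
                    continue
                if cfg.pruning and any(
                    ontologies.comparable(f, t) for t in parent.terms
                ):
                    continue  # Redundant Generalization, never evaluated
                new_terms = parent.terms | {f}
                term_sets.setdefault(tuple(sorted(new_terms)), frozenset(new_terms))
        if not term_sets:
            break

        evaluated = [
            evaluate_rule(
                term_sets[k],
                cover_map,
                examples,
                cfg.evaluator,
                cfg.alpha,
                cfg.lrs_variant,
            )
            for k in sorted(term_sets)
        ]
        stats.explored_rules += len(evaluated)

        for cand in evaluated:
            if cand.score.significant and cand.score.quality > best_score:
                best_rule, best_score = cand, cand.score.quality

        if cfg.pruning:
            survivors = [
                c for c in evaluated if c.score.potential >= best_score
            ]
        else:
            survivors = evaluated
        beam = filter_rules(survivors, cfg.beam_width)
        logger.debug(
            "level %d: evaluated %d, beam %d, best quality %.6f",
            level + 1,
            len(evaluated),
            len(beam),
            best_score,
        )
        if not beam:
            break

    stats.runtime = time.perf_counter() - start
    return best_rule, stats


# ---------------------------------------------------------------------------
# covering loop
# ---------------------------------------------------------------------------

def sem1r(
    examples: ExampleSet,
    ontologies: OntologySet,
    cover_map: SemanticCover,
    cfg: SearchConfig,
) -> tuple[RuleSet, SearchStats]:
    """Separate-and-conquer covering: induce, remove covered, repeat.

    The default removal policy excludes *all* examples covered by an
    accepted rule; ``positives-only`` removes only covered positives,
    the classical CN2-unordered behaviour.  Each rule is reported with
    the score it obtained on the example set it was induced from.
    """
    total = SearchStats()
    rules: list[Rule] = []
    current = examples
    covered_union: set[ExampleId] = set()

    while (
        current.positives
        and current.negatives
        and len(rules) < cfg.max_rules
    ):
        rule, stats = induce_single_rule(current, ontologies, cover_map, cfg)
        total.explored_rules += stats.explored_rules
        total.runtime += stats.runtime
        total.per_rule_breakdown.append(stats.explored_rules)
        if rule is None:
            break
        rules.append(rule)
        covered_union.update(rule.cover)
        if cfg.covering_removal == "all-covered":
            current = ExampleSet(
                current.positives - rule.cover,
                current.negatives - rule.cover,
            )
        else:
            current = ExampleSet(
                current.positives - rule.cover, current.negatives
            )

    uncovered = examples.positives - covered_union
    return RuleSet(rules=tuple(rules), uncovered_positives=uncovered), total


def run_exhaustive_baseline(
    examples: ExampleSet,
    ontologies: OntologySet,
    cover_map: SemanticCover,
    cfg: SearchConfig,
) -> tuple[RuleSet, SearchStats]:
    """The same search with both reduction procedures disabled.

    Used for quality-equivalence and explored-count comparisons against
    the ontology-based operator; the beam still applies.
    """
    return sem1r(
        examples, ontologies, cover_map, dataclasses.replace(cfg, pruning=False)
    )
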