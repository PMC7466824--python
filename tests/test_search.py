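"""Feature selection, the beam, single-rule induction, and covering."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as scipy_stats

from sem1r import (
    AnnotationMap,
    ExampleSet,
    Ontology,
    OntologySet,
    SearchConfig,
    Term,
    build_semantic_cover,
    evaluate_rule,
    filter_rules,
    induce_single_rule,
    run_exhaustive_baseline,
    select_features,
    sem1r,
)
from conftest import make_instances

import _oracles


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(beam_width=0)
    with pytest.raises(ValueError):
        SearchConfig(significance_level=1.0)
    with pytest.raises(ValueError):
        SearchConfig(feature_selection="bogus")
    with pytest.raises(ValueError):
        SearchConfig(covering_removal="sometimes")
    assert SearchConfig(significance_level=0.99).alpha == pytest.approx(0.01)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def test_at_least_one_keeps_all_toy_terms(toy):
    selected = select_features(
        "atLeastOne", toy.ontology.term_ids, toy.cover, toy.examples,
        toy.ontologies,
    )
    assert selected == list(toy.ontology.term_ids)  # every S(t) is non-empty


def test_terms_with_empty_cover_are_excluded(toy):
    # add an eighth term nobody is annotated with
    terms = [toy.ontology.term(t) for t in toy.ontology.term_ids]
    terms.append(Term("t7", parent_ids=frozenset({"t0"}), ontology_id="toy"))
    bigger = OntologySet([Ontology("toy", terms)])
    cover = build_semantic_cover(bigger, [toy.annotations], toy.examples)
    selected = select_features(
        "atLeastOne", bigger.term_ids, cover, toy.examples, bigger
    )
    assert "t7" not in selected
    assert len(selected) == 7


def test_sig_at_least_one_adds_generalizations_of_significant_terms(toy):
    # at a permissive gate, t1 (cover {e1}, all-positive) is significant;
    # its ancestor t0 enters sigAtLeastOne through the generalization clause
    only_sig = select_features(
        "onlySig", toy.ontology.term_ids, toy.cover, toy.examples,
        toy.ontologies, alpha=0.45, lrs_variant="cn2",
    )
    sig_plus = select_features(
        "sigAtLeastOne", toy.ontology.term_ids, toy.cover, toy.examples,
        toy.ontologies, alpha=0.45, lrs_variant="cn2",
    )
    assert set(only_sig) <= set(sig_plus)
    for t in sig_plus:
        assert toy.cover[t]
        assert t in only_sig or any(
            toy.ontologies.is_more_general(t, s) for s in only_sig
        )


def test_feature_selection_ordering_on_random_instances():
    """onlySig <= sigAtLeastOne <= atLeastOne, as set sizes (under the
    classical CN2 statistic; the printed LRS form can mark empty-cover
    terms significant and break the first inclusion)."""
    for instance in make_instances(8, noise_rate=0.15, base_seed=40):
        examples, cover, ontologies = instance.problem()
        sizes = {}
        for method in ("onlySig", "sigAtLeastOne", "atLeastOne"):
            sizes[method] = len(
                select_features(
                    method, ontologies.term_ids, cover, examples, ontologies,
                    alpha=0.05, lrs_variant="cn2",
                )
            )
        assert sizes["onlySig"] <= sizes["sigAtLeastOne"] <= sizes["atLeastOne"]


def test_unknown_method_rejected(toy):
    with pytest.raises(ValueError):
        select_features(
            "mystery", toy.ontology.term_ids, toy.cover, toy.examples,
            toy.ontologies,
        )


# ---------------------------------------------------------------------------
# beam filter
# ---------------------------------------------------------------------------

def test_beam_keeps_everything_when_wide(toy):
    rules = [
        evaluate_rule({t}, toy.cover, toy.examples, "acc", 0.5)
        for t in list(toy.ontology.term_ids)[:5]
    ]
    assert len(filter_rules(rules, 100)) == 5


def test_beam_tie_break_is_deterministic(toy):
    # many equal-quality candidates: ties broken by cover size then term ids
    rules = [
        evaluate_rule({t}, toy.cover, toy.examples, "acc", 0.5)
        for t in toy.ontology.term_ids
    ]
    expected = sorted(
        rules,
        key=lambda r: (-r.score.quality, -len(r.cover), tuple(sorted(r.terms))),
    )
    assert filter_rules(rules, 3) == expected[:3]
    assert filter_rules(rules, 3) == filter_rules(list(reversed(rules)), 3)


def test_beam_topk_matches_sort(toy):
    rules = [
        evaluate_rule({t}, toy.cover, toy.examples, "acc", 0.5)
        for t in toy.ontology.term_ids
    ]
    top2 = filter_rules(rules, 2)
    qualities = sorted((r.score.quality for r in rules), reverse=True)
    assert [r.score.quality for r in top2] == qualities[:2]


# ---------------------------------------------------------------------------
# single-rule induction
# ---------------------------------------------------------------------------

def test_toy_best_rule_quality(toy):
    """Exhaustively verifiable: at a permissive significance gate the
    best accuracy over all non-redundant rules on the toy world is 2/3
    (achieved by {t2} among others)."""
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, max_rule_length=7,
        beam_width=1000,
    )
    best, stats = induce_single_rule(toy.examples, toy.ontologies, toy.cover, cfg)
    assert best is not None
    assert best.score.quality == pytest.approx(2 / 3)
    assert stats.explored_rules > 0

    oracle = _oracles.best_gated_quality(
        toy.ontology.term_ids,
        _oracles.parent_map_of(toy.ontology),
        {t: set(toy.cover[t]) for t in toy.ontology.term_ids},
        set(toy.examples.positives),
        set(toy.examples.negatives),
        "acc",
        7,
        critical=float(scipy_stats.chi2.ppf(0.5, 1)),
        lrs_variant="printed",
    )
    assert best.score.quality == pytest.approx(oracle)


def _tiny_world(direct, positives, negatives, edges):
    terms = [
        Term(tid, parent_ids=frozenset(parents), ontology_id="W")
        for tid, parents in edges.items()
    ]
    ontology = Ontology("W", terms)
    ontologies = OntologySet([ontology])
    examples = ExampleSet(frozenset(positives), frozenset(negatives))
    annotations = AnnotationMap(
        direct={e: frozenset(ts) for e, ts in direct.items()}, axis="examples"
    )
    cover = build_semantic_cover(ontologies, [annotations], examples)
    return ontologies, examples, cover


def test_perfectly_separable_singleton():
    """One positive annotated by a unique leaf: that singleton rule is
    found with quality 1."""
    ontologies, examples, cover = _tiny_world(
        direct={"e1": ["leaf"], "e2": ["root"]},
        positives=["e1"],
        negatives=["e2"],
        edges={"root": (), "leaf": ("root",)},
    )
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, lrs_variant="cn2",
        max_rule_length=3,
    )
    best, _ = induce_single_rule(examples, ontologies, cover, cfg)
    assert best is not None
    assert best.terms == {"leaf"}
    assert best.score.quality == 1.0


def test_degenerate_example_sets_yield_nothing(toy):
    cfg = SearchConfig()
    all_neg = ExampleSet(frozenset(), toy.examples.all_examples)
    best, _ = induce_single_rule(all_neg, toy.ontologies, toy.cover, cfg)
    assert best is None


def test_strict_significance_gate_can_reject_everything(toy):
    # three examples cannot reach the 99% chi-square threshold
    cfg = SearchConfig(significance_level=0.99)
    best, _ = induce_single_rule(toy.examples, toy.ontologies, toy.cover, cfg)
    assert best is None


# ---------------------------------------------------------------------------
# covering loop
# ---------------------------------------------------------------------------

TWO_CLUSTER = dict(
    direct={
        "e1": ["A"], "e2": ["A"], "e3": ["B"], "e4": ["B"],
        "e5": ["R"], "e6": ["R"],
    },
    positives=["e1", "e2", "e3", "e4"],
    negatives=["e5", "e6"],
    edges={"R": (), "A": ("R",), "B": ("R",)},
)


def test_covering_splits_two_planted_clusters():
    ontologies, examples, cover = _tiny_world(**TWO_CLUSTER)
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, lrs_variant="cn2",
        max_rule_length=2,
    )
    ruleset, stats = sem1r(examples, ontologies, cover, cfg)
    assert len(ruleset) == 2
    assert ruleset.uncovered_positives == frozenset()
    covered = set()
    for rule in ruleset.rules:
        covered |= rule.cover
    assert covered >= examples.positives
    assert stats.per_rule_breakdown and len(stats.per_rule_breakdown) >= 2


def test_rule_budget_caps_covering():
    ontologies, examples, cover = _tiny_world(**TWO_CLUSTER)
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, lrs_variant="cn2",
        max_rule_length=2, max_rules=1,
    )
    ruleset, _ = sem1r(examples, ontologies, cover, cfg)
    assert len(ruleset) == 1
    assert ruleset.uncovered_positives


def test_all_negative_set_gives_empty_ruleset(toy):
    all_neg = ExampleSet(frozenset(), toy.examples.all_examples)
    ruleset, _ = sem1r(all_neg, toy.ontologies, toy.cover, SearchConfig())
    assert len(ruleset) == 0


def test_positives_only_removal_keeps_negatives():
    ontologies, examples, cover = _tiny_world(**TWO_CLUSTER)
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, lrs_variant="cn2",
        max_rule_length=2, covering_removal="positives-only",
    )
    ruleset, _ = sem1r(examples, ontologies, cover, cfg)
    assert len(ruleset) >= 2
    assert ruleset.uncovered_positives == frozenset()


# ---------------------------------------------------------------------------
# exhaustive baseline
# ---------------------------------------------------------------------------

def test_baseline_matches_quality_and_explores_more():
    for instance in make_instances(5, noise_rate=0.1, base_seed=60):
        examples, cover, ontologies = instance.problem()
        cfg = SearchConfig(
            evaluator="acc", max_rule_length=3, beam_width=200,
            lrs_variant="cn2",
        )
        pruned_rules, pruned_stats = sem1r(examples, ontologies, cover, cfg)
        base_rules, base_stats = run_exhaustive_baseline(
            examples, ontologies, cover, cfg
        )
        assert len(pruned_rules) == len(base_rules)
        for a, b in zip(pruned_rules.rules, base_rules.rules):
            assert a.score.quality == pytest.approx(b.score.quality, abs=1e-12)
        assert pruned_stats.explored_rules <= base_stats.explored_rules


def test_trivial_single_term_ontology():
    ontologies, examples, cover = _tiny_world(
        direct={"e1": ["only"], "e2": []},
        positives=["e1"],
        negatives=["e2"],
        edges={"only": ()},
    )
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, lrs_variant="cn2",
        max_rule_length=3,
    )
    _, stats_on = induce_single_rule(examples, ontologies, cover, cfg)
    _, stats_off = induce_single_rule(
        examples, ontologies, cover, dataclasses.replace(cfg, pruning=False)
    )
    assert stats_on.explored_rules == stats_off.explored_rules == 1


def test_wide_beam_without_pruning_is_full_enumeration():
    """With an unbounded beam and pruning off, the search's best gated
    quality equals brute-force enumeration of every non-redundant rule."""
    rng = np.random.default_rng(0)
    for instance in make_instances(4, n_terms=9, noise_rate=0.2, base_seed=80):
        examples, cover, ontologies = instance.problem()
        cfg = SearchConfig(
            evaluator="acc", max_rule_length=3, beam_width=10**6,
            pruning=False, significance_level=0.95, lrs_variant="cn2",
        )
        best, _ = induce_single_rule(examples, ontologies, cover, cfg)
        oracle = _oracles.best_gated_quality(
            instance.ontology.term_ids,
            _oracles.parent_map_of(instance.ontology),
            {t: set(cover[t]) for t in instance.ontology.term_ids},
            set(examples.positives),
            set(examples.negatives),
            "acc",
            3,
            critical=float(scipy_stats.chi2.ppf(0.95, 1)),
            lrs_variant="cn2",
        )
        if oracle is None:
            assert best is None
        else:
            assert best is not None
            assert best.score.quality == pytest.approx(oracle, abs=1e-12)


def test_search_terminates_within_length_budget(toy):
    cfg = SearchConfig(
        evaluator="acc", significance_level=0.5, max_rule_length=1,
    )
    best, stats = induce_single_rule(toy.examples, toy.ontologies, toy.cover, cfg)
    assert best is not None and len(best.terms) == 1
    assert stats.explored_rules == 7  # exactly the singleton level
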