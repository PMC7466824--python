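"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* —
explicit path enumeration over parent links, per-example membership
checks, exact rational arithmetic — and never calls into the search or
cover machinery it is used to verify.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def reachability(parent_map: dict[str, frozenset[str]]) -> dict[str, set[str]]:
    """Ancestor closure per term via breadth-first search over parent links."""
    closure: dict[str, set[str]] = {}
    for tid in parent_map:
        seen: set[str] = set()
        frontier = list(parent_map[tid])
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(parent_map[node])
        closure[tid] = seen
    return closure


def parent_map_of(ontology) -> dict[str, frozenset[str]]:
    """Extract raw child -> parents links from an ontology's terms."""
    return {tid: ontology.term(tid).parent_ids for tid in ontology.term_ids}


def more_general(parent_map, t1: str, t2: str) -> bool:
    """t1 more-general-or-equal t2: t1 on some upward path from t2."""
    return t1 == t2 or t1 in reachability(parent_map)[t2]


def propagated_cover(parent_map, direct_examples: dict[str, set]) -> dict[str, set]:
    """S(t) by brute force: union of M'(t') over every t' whose upward
    closure contains t (plus t itself)."""
    closure = reachability(parent_map)
    cover: dict[str, set] = {t: set(direct_examples.get(t, set())) for t in parent_map}
    for t_prime, examples in direct_examples.items():
        for t in closure.get(t_prime, set()):
            cover[t] |= set(examples)
    return cover


def conjunction_cover(rule_terms, term_covers: dict[str, set], scope: set) -> set:
    """Per-example membership test of a conjunction."""
    return {
        e
        for e in scope
        if all(e in term_covers.get(t, set()) for t in rule_terms)
    }


def lrs_exact(tp: int, fp: int, fn: int, tn: int, variant: str = "printed") -> float:
    """Direct re-evaluation of the likelihood-ratio statistic with exact
    rational ratios fed to log2."""
    total = tp + fp + fn + tn
    if variant == "printed":
        a, b = tp, tn
    else:
        a, b = tp, fp
    covered = a + b
    pairs = [(a, tp + fn), (b, fp + tn)]
    acc = 0.0
    for x, expected in pairs:
        if x == 0 or covered == 0 or expected == 0 or total == 0:
            continue
        ratio = Fraction(x, covered) / Fraction(expected, total)
        acc += x * math.log2(ratio)
    return 2.0 * acc


def incomparable_subsets(term_ids, parent_map, max_len: int):
    """All non-empty pairwise-incomparable term sets up to ``max_len``."""
    closure = reachability(parent_map)

    def comparable(a, b):
        return a == b or a in closure[b] or b in closure[a]

    for size in range(1, max_len + 1):
        for combo in combinations(sorted(term_ids), size):
            if any(comparable(a, b) for a, b in combinations(combo, 2)):
                continue
            yield frozenset(combo)


def quality(tp: int, fp: int, fn: int, tn: int, evaluator: str) -> float:
    """Direct quality formulas, written out independently."""
    if evaluator == "acc":
        return (tp + tn) / (tp + fp + fn + tn)
    if evaluator == "f1":
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom else 0.0
    if evaluator == "auc":
        tpr = tp / (tp + fn)
        fpr = fp / (fp + tn)
        return fpr * tpr + (1 - fpr) * tpr + (1 - fpr) * (1 - tpr) / 2
    raise ValueError(evaluator)


def best_gated_quality(
    term_ids,
    parent_map,
    term_covers: dict[str, set],
    positives: set,
    negatives: set,
    evaluator: str,
    max_len: int,
    critical: float,
    lrs_variant: str = "cn2",
):
    """Exhaustively enumerate every non-redundant rule up to ``max_len``
    and return the highest quality among those passing the significance
    gate (LRS strictly above ``critical``), or None."""
    scope = positives | negatives
    best = None
    for rule in incomparable_subsets(term_ids, parent_map, max_len):
        cover = conjunction_cover(rule, term_covers, scope)
        tp = len(cover & positives)
        fp = len(cover & negatives)
        fn = len(positives) - tp
        tn = len(negatives) - fp
        if lrs_exact(tp, fp, fn, tn, lrs_variant) <= critical:
            continue
        q = quality(tp, fp, fn, tn, evaluator)
        if best is None or q > best:
            best = q
    return best
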