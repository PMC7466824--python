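"""Rule quality functions, their admissible upper bounds, and significance.

Each candidate rule is scored from its confusion counts against the
current example set.  Three quality functions Q are provided — accuracy,
F1, and a single-point AUC — together with matching *potential* quality
functions Q_p.  Q_p(R) bounds the quality of every possible refinement
of R: refining a conjunction can only shrink its cover, so in the best
case all currently covered negatives (FP) become uncovered (TN) while
every covered positive is kept.  That admissibility (Q of any
specialization <= Q_p of the rule) is what makes branch-and-bound
pruning of the search sound.

Rule significance uses the CN2 likelihood-ratio statistic, compared
against a chi-square quantile with one degree of freedom.  Two variants
of the statistic are provided; see :func:`lrs`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from scipy import stats

from .data import ExampleSet

__all__ = [
    "ConfusionCounts",
    "RuleScore",
    "UndefinedScoreError",
    "confusion_counts",
    "q_acc",
    "q_p_acc",
    "q_f1",
    "q_p_f1",
    "q_auc",
    "q_p_auc",
    "EVALUATORS",
    "lrs",
    "chi2_critical",
    "is_significant",
    "score_rule",
]


class UndefinedScoreError(ValueError):
    """Raised when a quality function is undefined for the given counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts of a rule over a labelled example set."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RuleScore:
    """Quality, potential quality, LRS, and the significance verdict."""

    quality: float
    potential: float
    lrs: float
    significant: bool


def confusion_counts(cover: Iterable, examples: ExampleSet) -> ConfusionCounts:
    """Count TP/FP/FN/TN for a rule cover against labelled examples."""
    cover = frozenset(cover)
    tp = len(cover & examples.positives)
    fp = len(cover & examples.negatives)
    return ConfusionCounts(
        tp=tp,
        fp=fp,
        fn=examples.n_pos - tp,
        tn=examples.n_neg - fp,
    )


# ---------------------------------------------------------------------------
# quality functions and their upper bounds
# ---------------------------------------------------------------------------

def q_acc(c: ConfusionCounts) -> float:
    """Accuracy: (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedScoreError("accuracy undefined for zero examples")
    return (c.tp + c.tn) / c.total


def q_p_acc(c: ConfusionCounts) -> float:
    """Best accuracy reachable by refinement: FP may all turn into TN."""
    if c.total == 0:
        raise UndefinedScoreError("accuracy undefined for zero examples")
    return (c.tp + c.tn + c.fp) / c.total


def q_f1(c: ConfusionCounts) -> float:
    """F1 score 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 0.0


def q_p_f1(c: ConfusionCounts) -> float:
    """Best F1 reachable by refinement: the FP term drops out."""
    denom = 2 * c.tp + c.fn
    return 2 * c.tp / denom if denom else 0.0


def _rates(c: ConfusionCounts) -> tuple[float, float]:
    pos = c.tp + c.fn
    neg = c.fp + c.tn
    if pos == 0 or neg == 0:
        raise UndefinedScoreError(
            "AUC undefined without at least one positive and one negative"
        )
    return c.tp / pos, c.fp / neg


def q_auc(c: ConfusionCounts) -> float:
    """Single-point AUC: two triangles and a rectangle under (FPR, TPR).

    Computed as FPR*TPR + (1-FPR)*TPR + (1-FPR)(1-TPR)/2.  Note this
    geometry yields 1 at TPR=FPR=1, unlike the usual single-point
    trapezoid; it is used as-is because the matching upper bound below
    is admissible for it.
    """
    tpr, fpr = _rates(c)
    return fpr * tpr + (1 - fpr) * tpr + (1 - fpr) * (1 - tpr) / 2


def q_p_auc(c: ConfusionCounts) -> float:
    """Best single-point AUC reachable by refinement: FPR driven to 0."""
    tpr, _ = _rates(c)
    return tpr + (1 - tpr) / 2


#: evaluator token -> (quality function, potential-quality function)
EVALUATORS = {
    "acc": (q_acc, q_p_acc),
    "f1": (q_f1, q_p_f1),
    "auc": (q_auc, q_p_auc),
}


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def lrs(
    c: ConfusionCounts,
    n_total: int | None = None,
    variant: str = "printed",
) -> float:
    """Likelihood-ratio statistic of a rule's cover.

    ``variant="printed"`` evaluates

        2 * ( TP * log2( (TP/(TP+TN)) / ((TP+FN)/|E|) )
            + TN * log2( (TN/(TP+TN)) / ((FP+TN)/|E|) ) )

    which takes TP+TN as the covered-set size.  ``variant="cn2"`` is
    the classical CN2 form, comparing the class mix *inside the cover*
    (TP, FP with covered-set size TP+FP) against the global class
    distribution; it is positive for any rule whose cover is enriched
    in one class, including the perfect rule.  Zero-count terms and
    degenerate ratios contribute 0, the standard convention.
    """
    if n_total is None:
        n_total = c.total
    elif n_total != c.total:
        raise ValueError("n_total must equal tp + fp + fn + tn")

    if variant == "printed":
        a, b = c.tp, c.tn
    elif variant == "cn2":
        a, b = c.tp, c.fp
    else:
        raise ValueError(f"unknown LRS variant {variant!r}")
    covered = a + b
    expected_a = c.tp + c.fn  # |E+|
    expected_b = c.fp + c.tn  # |E-|

    def contribution(x: int, expected: int) -> float:
        if x == 0 or covered == 0 or expected == 0 or n_total == 0:
            return 0.0
        return x * math.log2((x / covered) / (expected / n_total))

    return 2.0 * (contribution(a, expected_a) + contribution(b, expected_b))


@lru_cache(maxsize=None)
def chi2_critical(alpha: float) -> float:
    """Chi-square(1 df) critical value at significance level ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"significance level must be in (0, 1), got {alpha}")
    return float(stats.chi2.ppf(1.0 - alpha, df=1))


def is_significant(lrs_value: float, alpha: float) -> bool:
    """True iff the statistic exceeds the chi-square(1 df) quantile.

    At ``alpha=0.01`` (the 99% confidence level) the critical value is
    6.635; at ``alpha=0.05`` it is 3.841.
    """
    return lrs_value > chi2_critical(alpha)


def score_rule(
    cover: Iterable,
    examples: ExampleSet,
    evaluator: str = "acc",
    alpha: float = 0.01,
    lrs_variant: str = "printed",
) -> RuleScore:
    """Score a rule cover: quality, potential, LRS, significance."""
    try:
        quality_fn, potential_fn = EVALUATORS[evaluator]
    except KeyError:
        raise ValueError(f"unknown evaluator {evaluator!r}") from None
    counts = confusion_counts(cover, examples)
    statistic = lrs(counts, variant=lrs_variant)
    return RuleScore(
        quality=quality_fn(counts),
        potential=potential_fn(counts),
        lrs=statistic,
        significant=is_significant(statistic, alpha),
    )
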