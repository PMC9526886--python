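"""Brute-force reference implementations used only to check the package.

Everything here is written from first principles (sums, pair counting,
rational arithmetic) and deliberately shares no code path with irsflow.
"""

from __future__ import annotations

import math
from fractions import Fraction


def geometric_mean(values) -> float:
    """exp of the compensated-sum mean of natural logs."""
    logs = [math.log(v) for v in values]
    return math.exp(math.fsum(logs) / len(logs))


def ols_slope(x, y) -> float:
    """Closed-form least-squares slope sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)."""
    n = len(x)
    xbar = math.fsum(x) / n
    ybar = math.fsum(y) / n
    num = math.fsum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    den = math.fsum((xi - xbar) ** 2 for xi in x)
    return num / den


def pearson_r(x, y) -> float:
    """Product-moment correlation from the covariance formula."""
    n = len(x)
    xbar = math.fsum(x) / n
    ybar = math.fsum(y) / n
    sxy = math.fsum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    sxx = math.fsum((xi - xbar) ** 2 for xi in x)
    syy = math.fsum((yi - ybar) ** 2 for yi in y)
    return sxy / math.sqrt(sxx * syy)


def anova_f(groups) -> float:
    """Textbook one-way ANOVA F from the sum-of-squares decomposition."""
    all_values = [v for g in groups for v in g]
    n = len(all_values)
    k = len(groups)
    grand = math.fsum(all_values) / n
    ss_between = math.fsum(len(g) * (math.fsum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = math.fsum(
        math.fsum((v - math.fsum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def residual_fraction_pct(gm_t, gm_30, gm_control) -> Fraction:
    """%Residual in exact rational arithmetic (inputs must be rational)."""
    return 100 * Fraction(gm_t - gm_control) / Fraction(gm_30 - gm_control)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """2x2 arithmetic in percent; None where the denominator is zero."""

    def pct(num, den):
        return None if den == 0 else 100.0 * num / den

    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "accuracy": pct(tp + tn, tp + fp + tn + fn),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def auc_pair_counting(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive pairing: concordant + half-ties over
    all positive x negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
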