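"""Direction-of-change composition by event category, plus PSI concordance.

Summarises, per event category, how many events were testable, how many
were called differential, and the included/excluded split; tests (a)
whether a category is hit more or less often than the remaining categories
(two-proportion test, Bonferroni over categories) and (b) whether the
included/excluded split departs from 50:50 (chi-square, exact binomial for
small counts, Bonferroni).  Also fits the ordinary least-squares
concordance line between two PSI measurement methods (e.g. RT-PCR vs
RNA-seq), reporting R^2.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .models import CategoryComposition, ConcordanceResult, ContrastResult

EXCLUDED_OVER_INCLUDED = "excluded_over_included"
INCLUDED_OVER_EXCLUDED = "included_over_excluded"

# Below this many significant events the exact binomial replaces the
# chi-square for the 50:50 imbalance test.
SMALL_COUNT_BINOMIAL = 20
# A 2x2 cell below this triggers Fisher's exact test instead of the
# two-proportion z-test.
SMALL_CELL_FISHER = 5


def direction_ratio(
    n_excluded: int, n_included: int, orientation: str = EXCLUDED_OVER_INCLUDED
) -> float:
    """Ratio of excluded to included significant events (or the inverse).

    Returns ``inf`` for a zero denominator with nonzero numerator and NaN
    for 0/0.
    """
    if n_excluded < 0 or n_included < 0:
        raise ValueError("counts must be >= 0")
    if orientation == EXCLUDED_OVER_INCLUDED:
        num, den = n_excluded, n_included
    elif orientation == INCLUDED_OVER_EXCLUDED:
        num, den = n_included, n_excluded
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided category-vs-complement rate comparison.

    Pooled-variance z-test, falling back to Fisher's exact test when any
    cell of the 2x2 table is small.
    """
    cells = (k1, n1 - k1, k2, n2 - k2)
    if min(cells) < SMALL_CELL_FISHER:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def category_proportion_test(
    per_category: Mapping[str, tuple[int, int]],
) -> dict[str, tuple[float, float]]:
    """Per-category (raw, Bonferroni-adjusted) p for differential-rate enrichment.

    ``per_category`` maps category -> (n_significant, n_tested).  Each
    category's rate is compared against the pooled rate of all remaining
    categories.  Categories with no tested events, or with an empty
    complement, get NaN (untested).  The Bonferroni multiplier is the number
    of categories actually tested.
    """
    tested = {c: (k, n) for c, (k, n) in per_category.items() if n > 0}
    total_k = sum(k for k, _ in tested.values())
    total_n = sum(n for _, n in tested.values())
    raw: dict[str, float] = {}
    for cat, (k, n) in per_category.items():
        if n == 0:
            raw[cat] = math.nan
            continue
        if k > n:
            raise ValueError(f"category {cat}: n_significant {k} > n_tested {n}")
        comp_k, comp_n = total_k - k, total_n - n
        if comp_n == 0:  # single category holds every tested event
            raw[cat] = math.nan
            continue
        raw[cat] = _two_proportion_p(k, n, comp_k, comp_n)
    m = sum(1 for p in raw.values() if not math.isnan(p))
    return {
        cat: (p, min(p * m, 1.0) if not math.isnan(p) else math.nan)
        for cat, p in raw.items()
    }


def inclusion_imbalance_test(
    per_category: Mapping[str, tuple[int, int]],
) -> dict[str, tuple[float, float]]:
    """Per-category (raw, adjusted) p for departure of the included/excluded
    split from 50:50.

    ``per_category`` maps category -> (n_included, n_excluded).  Chi-square
    with 1 df and Yates continuity correction (the R default, and close to
    the exact tail) for n >= 20, exact two-sided binomial below that;
    Bonferroni over categories with at least one significant event.
    """
    raw: dict[str, float] = {}
    for cat, (n_inc, n_exc) in per_category.items():
        n = n_inc + n_exc
        if n == 0:
            raw[cat] = math.nan
            continue
        if n < SMALL_COUNT_BINOMIAL:
            raw[cat] = float(stats.binomtest(n_inc, n, 0.5).pvalue)
        else:
            dev = max(abs(n_inc - n / 2.0) - 0.5, 0.0)
            chi2 = 4.0 * dev * dev / n
            raw[cat] = float(stats.chi2.sf(chi2, 1))
    m = sum(1 for p in raw.values() if not math.isnan(p))
    return {
        cat: (p, min(p * m, 1.0) if not math.isnan(p) else math.nan)
        for cat, p in raw.items()
    }


def summarize_composition(
    contrast: ContrastResult,
    orientation: str = EXCLUDED_OVER_INCLUDED,
) -> list[CategoryComposition]:
    """Full per-category composition table for one contrast.

    Conservation: the per-category n_significant sum to the contrast's
    n_significant.
    """
    tested: dict[str, int] = defaultdict(int)
    included: dict[str, int] = defaultdict(int)
    excluded: dict[str, int] = defaultdict(int)
    for call in contrast.calls:
        if not call.testable:
            continue
        tested[call.category] += 1
        if call.significant:
            if call.direction == "included":
                included[call.category] += 1
            else:
                excluded[call.category] += 1
    categories = sorted(tested)
    prop_p = category_proportion_test(
        {c: (included[c] + excluded[c], tested[c]) for c in categories}
    )
    imb_p = inclusion_imbalance_test({c: (included[c], excluded[c]) for c in categories})
    out = []
    for cat in categories:
        n_sig = included[cat] + excluded[cat]
        out.append(
            CategoryComposition(
                category=cat,
                n_tested=tested[cat],
                n_significant=n_sig,
                n_included=included[cat],
                n_excluded=excluded[cat],
                ratio=direction_ratio(excluded[cat], included[cat], orientation),
                proportion_p_raw=prop_p[cat][0],
                proportion_p=prop_p[cat][1],
                imbalance_p_raw=imb_p[cat][0],
                imbalance_p=imb_p[cat][1],
            )
        )
    return out


def psi_concordance(
    psi_method1: Sequence[float], psi_method2: Sequence[float]
) -> ConcordanceResult:
    """OLS concordance line between two PSI measurements of the same events.

    R^2 is the squared Pearson correlation.  Zero variance in either
    coordinate makes the fit undefined (NaN fields).
    """
    x = np.asarray(psi_method1, dtype=float)
    y = np.asarray(psi_method2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, got {x.size}")
    if np.any((x < 0) | (x > 1) | (y < 0) | (y > 1)):
        raise ValueError("PSI values must lie in [0, 1]")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceResult(math.nan, math.nan, math.nan, int(x.size))
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
    )
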