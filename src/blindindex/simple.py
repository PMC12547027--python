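"""Simple blinding index: between-arm difference in active-treatment guesses.

On 2x2 data (two arms, guesses "active" or "control", no IDK option),

    SBI = P_A - P_B = n_AA / (n_AA + n_BA) - n_AB / (n_AB + n_BB),

the difference between arms in the proportion guessing the *active*
treatment.  0 means both arms are equally inclined to guess active
(blinding), +/-1 means the arms separate completely.  The design question
"did randomization leak?" reduces to a two-sample difference of binomial
proportions, so the index is robust to any allocation ratio.

IDK responses are not part of the design: a ternary table is first reduced
with :func:`~blindindex.table.drop_idk` and the exclusions are flagged and
reported, shrinking the analytical sample size.

The confidence interval is the Newcombe/MOVER hybrid of two Wilson score
intervals, which respects the [-1, 1] range, needs no symmetry, and never
collapses to zero width on finite samples.
"""

from __future__ import annotations

import math

from statsmodels.stats.proportion import proportion_confint

from .estimate import IndexEstimate
from .table import DegenerateDataError, GuessTable, collapse_likert, drop_idk

__all__ = ["wilson_interval", "simple_point", "simple_ci"]


def wilson_interval(successes: int, trials: int, alpha: float = 0.05):
    """Wilson score interval for a binomial proportion.

    Returns ``(low, high)`` within [0, 1]; the interval has positive width
    for any finite number of trials, including 0 or all successes.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="wilson")
    return max(0.0, float(lo)), min(1.0, float(hi))


def _reduce(table: GuessTable) -> tuple[GuessTable, bool]:
    if table.scale == "likert5":
        table = collapse_likert(table)
    if table.k != 2:
        raise DegenerateDataError(
            f"the Simple index is defined for two-arm tables, got k={table.k}"
        )
    if table.has_idk:
        return drop_idk(table), True
    return table, False


def simple_point(table: GuessTable) -> float:
    """Point estimate of the Simple index (IDK responses excluded)."""
    table, _ = _reduce(table)
    g = table.treatment_counts
    p_a = g[0, 0] / g[0].sum()
    p_b = g[1, 0] / g[1].sum()
    return float(p_a - p_b)


def simple_ci(table: GuessTable, alpha: float = 0.05) -> IndexEstimate:
    """Simple index with its Wilson-score MOVER (Newcombe) interval.

    With per-arm Wilson bounds ``(l1, u1)`` and ``(l2, u2)`` around the
    active-guess proportions ``p1`` and ``p2``, the interval around
    ``d = p1 - p2`` is

        ( d - sqrt((p1 - l1)^2 + (u2 - p2)^2),
          d + sqrt((u1 - p1)^2 + (p2 - l2)^2) ).
    """
    table, excluded = _reduce(table)
    g = table.treatment_counts
    n1, n2 = int(g[0].sum()), int(g[1].sum())
    p1, p2 = g[0, 0] / n1, g[1, 0] / n2
    value = float(p1 - p2)
    l1, u1 = wilson_interval(int(g[0, 0]), n1, alpha)
    l2, u2 = wilson_interval(int(g[1, 0]), n2, alpha)
    lo = value - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    hi = value + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    # Approximate SE implied by the per-arm Wilson half-widths; reported for
    # completeness, the interval itself is the inferential object.
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    flags = {"idk_excluded"} if excluded else set()
    return IndexEstimate(
        "SBI", value, se, max(-1.0, lo), min(1.0, hi),
        1 - alpha, "wilson-mover", n1 + n2, flags,
    )
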