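"""Bang blinding index: within-arm correct-guess excess, plus a study sum.

For arm ``j`` the index is the difference between the proportions of
correct and incorrect guesses, with IDK responses kept in the denominator:

    BBI_j = (n_correct - n_incorrect) / N_j,            (direct form)

equivalently, for an arm with at least one non-IDK response,

    BBI_j = [2 p_correct|answered - 1] * (answered / N_j),   (product form)

so 0 means blinding (guessing no better than chance within the arm), +1
complete correct guessing, and -1 complete opposite guessing.  Both forms
are evaluated and checked against each other; they diverge only for an
all-IDK arm, where the product form is 0/0 and the estimate is refused
with a degeneracy error.  The study-level summary ``sumBI = BBI_A + BBI_B``
behaves like a between-arm difference despite being a sum (each arm's
"correct" guess is the opposite treatment).

The variance is the standard multinomial-contrast form
``[p1 + p2 - (p1 - p2)^2] / N_j`` with a normal CI; all respondents in an
arm guessing identically gives a zero-width interval, which is flagged.
Two-arm tables with visibly unequal arm sizes carry an
``unequal_allocation`` caveat flag, since the index was designed for 1:1
allocation.

Five-point Likert tables are scored on the collapsed ternary counts by
default; ``likert_weights`` instead applies a weighted contrast in which a
"strongly" belief counts fully and a "somewhat" belief partially
(default 1 and 0.5) toward the correct or incorrect side.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np
from scipy import stats

from .estimate import IndexEstimate
from .table import DegenerateDataError, GuessTable, collapse_likert

__all__ = ["bang_arm", "bang_sum"]

_SIDES = ("two", "lower", "upper")


def _z(alpha: float, sided: str) -> float:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}, got {sided!r}")
    return float(stats.norm.ppf(1 - alpha / 2 if sided == "two" else 1 - alpha))


def _arm_contrast(row: np.ndarray, correct: int) -> tuple[float, float, float, float]:
    """Direct-form value, its product-form twin, and (p1, p2) for an arm row."""
    n = float(row.sum())
    guesses = row[:-1]
    p1 = float(row[correct] / n)
    p2 = float((guesses.sum() - row[correct]) / n)
    direct = p1 - p2
    answered = float(guesses.sum())
    if answered == 0:
        raise DegenerateDataError(
            "arm has only IDK responses; the Bang index is undefined "
            "(its conditional form divides by zero)"
        )
    product = (2.0 * row[correct] / answered - 1.0) * (answered / n)
    # The two published forms must agree whenever any guess was ventured.
    assert math.isclose(direct, product, rel_tol=0, abs_tol=1e-12), (direct, product)
    return direct, product, p1, p2


def _likert_contrast(row: np.ndarray, arm: int, strong: float, somewhat: float):
    """Weighted correct-minus-incorrect contrast on a five-point Likert row.

    Columns are (strongly-A, somewhat-A, somewhat-B, strongly-B, IDK); for
    arm A the A-side beliefs are correct, for arm B the B-side ones.
    """
    coef = np.array([strong, somewhat, -somewhat, -strong, 0.0])
    if arm == 1:
        coef = -coef
    n = float(row.sum())
    p = row / n
    value = float(coef @ p)
    var = float(((coef**2) @ p - value**2) / n)
    return value, var


def bang_arm(
    table: GuessTable,
    arm: Union[int, str],
    alpha: float = 0.05,
    sided: str = "two",
    likert_weights: tuple[float, float] | None = None,
) -> IndexEstimate:
    """Arm-specific Bang index with a normal-approximation CI.

    ``sided`` selects a two-sided interval (default) or a one-sided bound
    at level ``1 - alpha`` (``"lower"``/``"upper"``); the unused bound is
    the range limit.  ``likert_weights=(strong, somewhat)`` scores a
    five-point Likert table with a weighted contrast instead of collapsing.
    """
    flags = set()
    if likert_weights is not None:
        if table.scale != "likert5":
            raise DegenerateDataError(
                "likert_weights requires a five-point Likert table"
            )
        j = table.arm_index(arm)
        row = table.likert_counts[j].astype(float)
        if row[:-1].sum() == 0:
            raise DegenerateDataError("arm has only IDK responses")
        value, var = _likert_contrast(row, j, *likert_weights)
        flags.add("likert_weighted")
        n_arm = int(row.sum())
    else:
        if table.scale == "likert5":
            table = collapse_likert(table)
        j = table.arm_index(arm)
        row = table.counts[j]
        value, _, p1, p2 = _arm_contrast(row, j)
        n_arm = int(row.sum())
        var = (p1 + p2 - (p1 - p2) ** 2) / n_arm
    if table.k == 2 and table.arm_totals[0] != table.arm_totals[1]:
        flags.add("unequal_allocation")
    if table.k > 2:
        flags.add("multi_arm")
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        flags.add("zero_width_ci")
    z = _z(alpha, sided)
    lo = value - z * se if sided in ("two", "lower") else -1.0
    hi = value + z * se if sided in ("two", "upper") else 1.0
    name = f"BBI_{table.arm_labels[j]}"
    return IndexEstimate(
        name, value, se, lo, hi,
        1 - alpha, "multinomial-normal", n_arm, flags,
    )


def bang_sum(
    table: GuessTable,
    alpha: float = 0.05,
    sided: str = "two",
    likert_weights: tuple[float, float] | None = None,
) -> IndexEstimate:
    """Study-level sum of the two arm indices, ``sumBI = BBI_A + BBI_B``.

    The variance is the sum of the arm variances (arms are independent by
    randomization).  On a table with no IDK responses ``sumBI`` equals
    exactly twice the Simple index.
    """
    if table.k != 2:
        raise DegenerateDataError(
            f"sumBI is defined for two-arm tables, got k={table.k}"
        )
    a = bang_arm(table, 0, alpha, "two", likert_weights)
    b = bang_arm(table, 1, alpha, "two", likert_weights)
    value = a.value + b.value
    se = math.sqrt(a.se**2 + b.se**2)
    flags = (a.flags | b.flags) - {"zero_width_ci"}
    if se == 0.0:
        flags = flags | {"zero_width_ci"}
    z = _z(alpha, sided)
    lo = value - z * se if sided in ("two", "lower") else -2.0
    hi = value + z * se if sided in ("two", "upper") else 2.0
    return IndexEstimate(
        "sumBI", value, se, lo, hi,
        1 - alpha, "multinomial-normal", a.n_used + b.n_used, flags,
    )
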