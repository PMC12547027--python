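"""James blinding index: disagreement beyond chance, scaled to [0, 1].

The index summarizes a whole trial in one number.  Each guess cell gets a
constant weight — 0 for a correct guess, 0.5 for an incorrect one, 1 for
"I don't know" — and the weighted observed guess proportion is contrasted
with the proportion expected under independence of guess and arm, in a
kappa-like term.  With ``P_D`` the IDK proportion,

    JBI = [1 + P_D + (1 - P_D) * (P_O - P_E) / P_E] / 2,

so 1 means perfect blinding (everyone uncertain, or maximal disagreement),
0.5 random guessing, and values below 0.5 excess correct guessing.  IDK
responses therefore dominate the index.  When every response is IDK the
kappa term is 0/0: the index is reported as undefined with a flag, or as 1
under an optional convention.

The variance is estimated by a leave-one-respondent-out jackknife, computed
here over distinct cells weighted by their counts (identical to the naive
loop over all N respondents, but O(k^2) recomputations instead of O(N)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimate import IndexEstimate
from .table import DegenerateDataError, GuessTable, collapse_likert

__all__ = ["WeightScheme", "JamesComponents", "james_point", "james_jackknife_ci"]


@dataclass(frozen=True)
class WeightScheme:
    """Guess-cell weights ``w_ij`` for the James index.

    ``correct`` applies where guess position equals arm position,
    ``incorrect`` elsewhere, and ``idk`` multiplies the IDK proportion in
    the index formula.  A full ``k x k`` ``matrix`` (rows = arms, columns =
    guesses) overrides the two scalars for multi-arm designs needing
    non-uniform weights.  All weights must lie in [0, 1].
    """

    correct: float = 0.0
    incorrect: float = 0.5
    idk: float = 1.0
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("correct", "incorrect", "idk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"weight {name}={v} outside [0, 1]")
        if self.matrix is not None:
            m = np.asarray(self.matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError("weight matrix must be square (arms x guesses)")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("weight matrix entries must lie in [0, 1]")
            object.__setattr__(self, "matrix", m)

    def as_matrix(self, k: int) -> np.ndarray:
        """Weights as a ``k x k`` array indexed [arm, guess]."""
        if self.matrix is not None:
            if self.matrix.shape != (k, k):
                raise ValueError(
                    f"weight matrix is {self.matrix.shape}, table has k={k}"
                )
            return self.matrix
        m = np.full((k, k), self.incorrect, dtype=float)
        np.fill_diagonal(m, self.correct)
        return m


#: Default 0 / 0.5 / 1 weights.
DEFAULT_WEIGHTS = WeightScheme()


@dataclass(frozen=True)
class JamesComponents:
    """The pieces of the James index for one table.

    ``p_idk`` is the IDK proportion P_D; ``p_obs`` and ``p_exp`` are the
    weighted observed and expected guess proportions among respondents who
    ventured a guess; ``kappa`` is their relative difference
    (P_O - P_E)/P_E, comparable to the kappa statistic; ``value`` is the
    index, NaN when undefined (all-IDK without the convention option).
    """

    p_idk: float
    p_obs: float
    p_exp: float
    kappa: float
    value: float
    undefined: bool = False


def _components_from_counts(
    counts: np.ndarray, w: np.ndarray, idk_weight: float, undefined_as_one: bool
) -> JamesComponents:
    """Core evaluation on a float count/weight matrix (rows arms, IDK last).

    Works on fractional "counts" too, which is how population values under a
    probability model are obtained.
    """
    total = counts.sum()
    if total <= 0:
        raise DegenerateDataError("empty table")
    p_idk = float(counts[:, -1].sum() / total)
    if p_idk >= 1.0 - 1e-15:
        value = 1.0 if undefined_as_one else math.nan
        return JamesComponents(1.0, math.nan, math.nan, math.nan, value, True)
    guesses = counts[:, :-1]
    denom = 1.0 - p_idk
    p_obs = float((w * guesses).sum() / total / denom)
    p_guess = guesses.sum(axis=0) / total          # marginal of each guess
    p_arm_answered = guesses.sum(axis=1) / total   # non-IDK share of each arm
    p_exp = float((w * np.outer(p_arm_answered, p_guess)).sum() / denom**2)
    if p_exp <= 0.0:
        raise DegenerateDataError(
            "expected weighted guess proportion is zero; the kappa term of the "
            "James index is undefined on this table"
        )
    kappa = (p_obs - p_exp) / p_exp
    value = (1.0 + idk_weight * p_idk + (1.0 - p_idk) * kappa) / 2.0
    return JamesComponents(p_idk, p_obs, p_exp, kappa, value, False)


def _prepare(table: GuessTable) -> GuessTable:
    # Five-point Likert data are collapsed by belief side before scoring;
    # the index is then the ternary one.
    if table.scale == "likert5":
        return collapse_likert(table)
    return table


def james_point(
    table: GuessTable,
    weights: WeightScheme | None = None,
    undefined_as_one: bool = False,
) -> JamesComponents:
    """Point estimate of the James index with its components.

    ``undefined_as_one`` adopts the convention that an all-IDK table scores
    1 (perfect blinding) instead of being flagged undefined.
    """
    table = _prepare(table)
    weights = weights or DEFAULT_WEIGHTS
    w = weights.as_matrix(table.k)
    return _components_from_counts(
        table.counts.astype(float), w, weights.idk, undefined_as_one
    )


def _leave_one_out_values(
    counts: np.ndarray, w: np.ndarray, idk_weight: float, undefined_as_one: bool
):
    """Distinct leave-one-respondent-out index values and their multiplicities.

    Removing any respondent from the same cell gives the same replicate, so
    the N replicates collapse to one recomputation per occupied cell.
    Returns ``(values, weights, n_degenerate)``; degenerate replicates (the
    reduced table has an empty arm or an undefined kappa term) score the
    all-IDK convention value when possible and are counted.
    """
    values = []
    mult = []
    n_degenerate = 0
    for j, i in np.argwhere(counts > 0):
        reduced = counts.astype(float).copy()
        reduced[j, i] -= 1
        try:
            comp = _components_from_counts(reduced, w, idk_weight, True)
            if comp.undefined:
                n_degenerate += 1
            values.append(comp.value)
        except DegenerateDataError:
            n_degenerate += 1
            continue
        mult.append(int(counts[j, i]))
    return np.asarray(values), np.asarray(mult, dtype=float), n_degenerate


def james_jackknife_ci(
    table: GuessTable,
    weights: WeightScheme | None = None,
    alpha: float = 0.05,
    undefined_as_one: bool = False,
) -> IndexEstimate:
    """James index with a jackknife-variance normal CI, truncated to [0, 1].

    The jackknife variance is ``(N-1)/N * sum_r (theta_(-r) - mean)^2`` over
    the N leave-one-respondent-out recomputations; the interval is centered
    on the full-sample point estimate, not on the jackknife mean.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    table = _prepare(table)
    n = table.n_total
    if n < 2:
        raise DegenerateDataError("jackknife needs at least two respondents")
    weights = weights or DEFAULT_WEIGHTS
    w = weights.as_matrix(table.k)
    point = _components_from_counts(
        table.counts.astype(float), w, weights.idk, undefined_as_one
    )
    flags = set()
    if point.undefined:
        flags.add("undefined")
    if math.isnan(point.value):
        return IndexEstimate(
            "JBI", math.nan, None, math.nan, math.nan, 1 - alpha,
            "jackknife-normal", n, flags,
        )
    loo, mult, n_deg = _leave_one_out_values(
        table.counts, w, weights.idk, undefined_as_one or point.undefined
    )
    if n_deg:
        flags.add("jackknife_replicate_degenerate")
    n_eff = mult.sum()
    mean = float((loo * mult).sum() / n_eff)
    var = float((n_eff - 1) / n_eff * (mult * (loo - mean) ** 2).sum())
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        flags.add("zero_width_ci")
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, point.value - z * se)
    hi = min(1.0, point.value + z * se)
    return IndexEstimate(
        "JBI", point.value, se, lo, hi, 1 - alpha, "jackknife-normal", n, flags
    )
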