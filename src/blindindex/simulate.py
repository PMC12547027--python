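"""Scenario simulator and Monte-Carlo test-bed for the blinding indices.

A scenario fixes, per arm, a probability vector over the guess categories
(treatment guesses plus IDK) and a sample size; tables are drawn arm-wise
from the multinomial.  Population (true) index values are obtained by
evaluating the same index formulas on the expected cell counts, so a
scenario doubles as a ground truth for coverage and bias experiments.

Reproducibility: one scenario seed governs a counter-based stream — the
table for replicate ``r`` is drawn from ``default_rng([seed, r])`` — so any
replicate can be regenerated in isolation and experiments are independent
of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import bang, james, simple
from .table import DegenerateDataError, GuessTable

__all__ = [
    "ScenarioSpec",
    "PRESETS",
    "preset_scenario",
    "simulate_table",
    "population_indices",
    "coverage_experiment",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Per-arm guess probabilities, arm sizes, and a seed.

    ``probs`` is ``k x (k+1)`` (last column IDK), each row summing to 1;
    ``n_per_arm`` the respondent count per arm.
    """

    probs: np.ndarray
    n_per_arm: tuple
    seed: int = 0
    arm_labels: tuple | None = None
    guess_labels: tuple | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != p.shape[0] + 1:
            raise ValueError(f"probs must be k x (k+1), got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ValueError("each arm's probabilities must sum to 1")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)
        n = tuple(int(x) for x in (
            [self.n_per_arm] * p.shape[0]
            if np.isscalar(self.n_per_arm)
            else self.n_per_arm
        ))
        if len(n) != p.shape[0] or any(x < 0 for x in n):
            raise ValueError("n_per_arm needs one non-negative size per arm")
        object.__setattr__(self, "n_per_arm", n)
        k = p.shape[0]
        arms = self.arm_labels or tuple("ABCDEFGH"[i] for i in range(k))
        object.__setattr__(self, "arm_labels", tuple(arms))
        guesses = self.guess_labels or tuple(f"guess{a}" for a in arms)
        object.__setattr__(self, "guess_labels", tuple(guesses))

    @property
    def k(self) -> int:
        return self.probs.shape[0]


#: Named two-arm scenarios (rows: arm A, arm B; columns: guess-A, guess-B, IDK).
PRESETS = {
    # every respondent reports genuine uncertainty
    "all_idk": [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]],
    # guesses invert the assignment
    "opposite_guess": [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0]],
    # uninformative guessing, no IDK option
    "random_guess": [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]],
    # both arms lean to the active treatment, e.g. hopeful participants
    "same_guess_active": [[0.8, 0.1, 0.1], [0.8, 0.1, 0.1]],
    # assignment has leaked: most guesses are correct
    "unblinded": [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1]],
}


def preset_scenario(name: str, n_per_arm=100, seed: int = 0) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a named preset."""
    try:
        probs = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
    return ScenarioSpec(np.asarray(probs, dtype=float), n_per_arm, seed)


def simulate_table(spec: ScenarioSpec, replicate: int | None = None) -> GuessTable:
    """Draw one guess table from the scenario's multinomial model.

    With ``replicate`` given, the draw comes from the counter-based stream
    ``default_rng([seed, replicate])``; otherwise from ``default_rng(seed)``.
    The same spec and replicate always give the same table.
    """
    rng = np.random.default_rng(
        spec.seed if replicate is None else [spec.seed, replicate]
    )
    counts = np.vstack(
        [rng.multinomial(n, p) for n, p in zip(spec.n_per_arm, spec.probs)]
    )
    scale = "binary" if not counts[:, -1].any() else "ternary"
    return GuessTable(spec.arm_labels, spec.guess_labels, counts, scale)


def population_indices(spec: ScenarioSpec) -> dict:
    """True index values under the scenario's probability model.

    Evaluates the index formulas on expected counts ``n_j * p_j``; applied
    to a table's own empirical proportions this reproduces the sample
    estimates exactly.  ``jbi`` is NaN for an all-IDK population (the same
    undefined case as the sample version); arm-level values are NaN where
    an arm answers IDK with probability 1.
    """
    expected = spec.probs * np.asarray(spec.n_per_arm, dtype=float)[:, None]
    w = james.DEFAULT_WEIGHTS
    try:
        comp = james._components_from_counts(
            expected, w.as_matrix(spec.k), w.idk, False
        )
        jbi = comp.value
    except DegenerateDataError:
        jbi = math.nan
    out = {"jbi": jbi}
    if spec.k == 2:
        arm_vals = []
        for j in range(2):
            p = spec.probs[j]
            answered = p[:-1].sum()
            if answered == 0:
                arm_vals.append(math.nan)
            else:
                arm_vals.append(float(p[j] - (answered - p[j])))
        out["bbi_A"], out["bbi_B"] = arm_vals
        out["sum_bi"] = arm_vals[0] + arm_vals[1]
        answered = spec.probs[:, :-1].sum(axis=1)
        if np.all(answered > 0):
            out["sbi"] = float(
                spec.probs[0, 0] / answered[0] - spec.probs[1, 0] / answered[1]
            )
        else:
            out["sbi"] = math.nan
    return out


def _estimates_for(table: GuessTable, alpha: float) -> dict:
    """Point estimate and CI per index for one simulated table."""
    out = {}
    try:
        e = james.james_jackknife_ci(table, alpha=alpha)
        out["jbi"] = (e.value, e.ci_low, e.ci_high)
    except DegenerateDataError:
        out["jbi"] = (math.nan,) * 3
    if table.k == 2:
        for key, j in (("bbi_A", 0), ("bbi_B", 1)):
            try:
                e = bang.bang_arm(table, j, alpha)
                out[key] = (e.value, e.ci_low, e.ci_high)
            except DegenerateDataError:
                out[key] = (math.nan,) * 3
        try:
            e = bang.bang_sum(table, alpha)
            out["sum_bi"] = (e.value, e.ci_low, e.ci_high)
        except DegenerateDataError:
            out["sum_bi"] = (math.nan,) * 3
        try:
            e = simple.simple_ci(table, alpha)
            out["sbi"] = (e.value, e.ci_low, e.ci_high)
        except DegenerateDataError:
            out["sbi"] = (math.nan,) * 3
    return out


def coverage_experiment(
    spec: ScenarioSpec,
    true_values: dict | None = None,
    reps: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Empirical CI coverage and bias of each index under a scenario.

    For every index, over ``reps`` seeded replicates: the fraction of
    nominal ``1 - alpha`` intervals covering the true value, the mean bias
    of the point estimate, and Monte-Carlo standard errors for both.
    ``true_values`` defaults to :func:`population_indices`; replicates on
    which an index is undefined are counted separately and excluded.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    truth = dict(true_values) if true_values is not None else population_indices(spec)
    truth = {k: v for k, v in truth.items() if not math.isnan(v)}
    hits = {k: [] for k in truth}
    errors = {k: [] for k in truth}
    skipped = {k: 0 for k in truth}
    for r in range(reps):
        est = _estimates_for(simulate_table(spec, replicate=r), alpha)
        for key, tv in truth.items():
            value, lo, hi = est.get(key, (math.nan,) * 3)
            if math.isnan(value):
                skipped[key] += 1
                continue
            hits[key].append(lo <= tv <= hi)
            errors[key].append(value - tv)
    summary = {}
    for key, tv in truth.items():
        n = len(hits[key])
        cov = float(np.mean(hits[key])) if n else math.nan
        bias = float(np.mean(errors[key])) if n else math.nan
        summary[key] = {
            "true_value": tv,
            "coverage": cov,
            "coverage_mc_se": math.sqrt(cov * (1 - cov) / n) if n else math.nan,
            "mean_bias": bias,
            "bias_mc_se": float(np.std(errors[key], ddof=1) / math.sqrt(n))
            if n > 1
            else math.nan,
            "n_reps_used": n,
            "n_reps_degenerate": skipped[key],
        }
    return summary
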