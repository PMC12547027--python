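"""Assemble index estimates into an interpreted blinding report.

The report bundles, for one guess table, the James index (with jackknife
CI), the two arm-level Bang indices and their sum, and the Simple index,
together with cutoff-based interpretation labels and caveat notes (IDK
exclusions, unequal allocation, degeneracies).  Conventional ad-hoc
cutoffs: James > 0.5 suggests blinding success (stronger when the CI lower
limit clears 0.5); Bang within |0.2| (stringent) or |0.3| (less stringent)
suggests success, with the sign separating correct-guess excess from
opposite guessing.  No interpretation cutoff has been established for the
Simple index, and none is invented here.  Blinding success is not binary:
a report always carries the estimates and intervals, never only a verdict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from . import bang, james, simple
from .estimate import IndexEstimate
from .table import DegenerateDataError, GuessTable, collapse_likert

__all__ = ["BlindingReport", "analyze", "interpret", "render_report"]


@dataclass
class BlindingReport:
    """All requested index estimates for one table, with labels and notes."""

    input_summary: dict
    estimates: list
    labels: dict
    notes: list = field(default_factory=list)

    def estimate(self, name: str) -> IndexEstimate:
        for e in self.estimates:
            if e.index_name == name:
                return e
        raise KeyError(f"no estimate named {name!r}")


def _nan_estimate(name: str, ci_method: str, n: int, alpha: float, flags) -> IndexEstimate:
    return IndexEstimate(
        name, math.nan, None, math.nan, math.nan, 1 - alpha, ci_method, n, flags
    )


def analyze(
    table: GuessTable,
    alpha: float = 0.05,
    indices: str = "all",
    stringent: bool = True,
    likert_weights: tuple | None = None,
    undefined_as_one: bool = False,
) -> BlindingReport:
    """Compute the requested indices on one table and interpret them.

    ``indices`` is ``"all"`` or a comma-separated subset of
    ``jbi,bbi,sbi``.  Degenerate inputs (e.g. an all-IDK arm) do not abort
    the report: the affected index appears with an ``undefined`` or
    ``degenerate`` flag and an explanatory note.  Multi-arm tables get the
    James index only, with a note.
    """
    wanted = (
        {"jbi", "bbi", "sbi"}
        if indices == "all"
        else {s.strip().lower() for s in indices.split(",") if s.strip()}
    )
    unknown = wanted - {"jbi", "bbi", "sbi"}
    if unknown:
        raise ValueError(f"unknown indices {sorted(unknown)}; choose from jbi,bbi,sbi")
    estimates: list = []
    notes: list = []
    scored = table
    if table.scale == "likert5":
        scored = collapse_likert(table)
        notes.append(
            "five-point Likert responses collapsed to guess-A/guess-B/IDK "
            "(strong + somewhat per side)"
        )
    if "jbi" in wanted:
        est = james.james_jackknife_ci(
            scored, alpha=alpha, undefined_as_one=undefined_as_one
        )
        estimates.append(est)
        if not est.defined:
            notes.append(
                "James index undefined: every response is IDK (use the "
                "all-IDK convention to report 1)"
            )
    if "bbi" in wanted:
        if table.k != 2:
            notes.append(
                f"Bang index skipped: needs two arms, table has {table.k}"
            )
        else:
            bang_table = table if likert_weights else scored
            for j in range(2):
                try:
                    est = bang.bang_arm(
                        bang_table, j, alpha, likert_weights=likert_weights
                    )
                except DegenerateDataError as err:
                    est = _nan_estimate(
                        f"BBI_{table.arm_labels[j]}", "multinomial-normal",
                        int(table.arm_totals[j]), alpha, {"undefined", "degenerate"},
                    )
                    notes.append(f"BBI_{table.arm_labels[j]}: {err}")
                estimates.append(est)
            try:
                estimates.append(
                    bang.bang_sum(bang_table, alpha, likert_weights=likert_weights)
                )
            except DegenerateDataError as err:
                estimates.append(
                    _nan_estimate(
                        "sumBI", "multinomial-normal", table.n_total, alpha,
                        {"undefined", "degenerate"},
                    )
                )
                notes.append(f"sumBI: {err}")
    if "sbi" in wanted:
        if table.k != 2:
            notes.append(
                f"Simple index skipped: needs two arms, table has {table.k}"
            )
        else:
            try:
                estimates.append(simple.simple_ci(scored, alpha))
            except DegenerateDataError as err:
                estimates.append(
                    _nan_estimate(
                        "SBI", "wilson-mover", table.n_total, alpha,
                        {"undefined", "degenerate"},
                    )
                )
                notes.append(f"SBI: {err}")
    for est in estimates:
        if "unequal_allocation" in est.flags:
            notes.append(
                f"{est.index_name}: arms are not 1:1 "
                f"({'/'.join(str(int(n)) for n in table.arm_totals)}); the Bang "
                "index assumes equal allocation — interpret with caution"
            )
            break
    for est in estimates:
        if "idk_excluded" in est.flags:
            n_idk = int(table.counts[:, -1].sum()) if table.scale != "binary" else 0
            notes.append(
                f"{est.index_name}: {n_idk} IDK respondent(s) excluded; "
                f"analytical sample size {est.n_used} of {table.n_total}"
            )
    for est in estimates:
        if "zero_width_ci" in est.flags:
            notes.append(
                f"{est.index_name}: zero-width CI from a normality-based "
                "variance of zero (all informative responses identical)"
            )
    return BlindingReport(table.summary(), estimates, interpret(estimates, stringent), notes)


def interpret(estimates, stringent: bool = True) -> dict:
    """Cutoff-based labels, one per estimate; a pure function of the inputs.

    James: > 0.5 suggests success (stronger when the CI lower limit clears
    0.5); an interval containing 0.5 reads as random guessing.  Bang: the
    magnitude is held against 0.2 (stringent) or 0.3, the sign telling
    correct-guess excess from opposite guessing.  sumBI is described as the
    between-arm difference it measures (no established cutoff); the Simple
    index has no published interpretation guidance.
    """
    cutoff = 0.2 if stringent else 0.3
    labels = {}
    for est in estimates:
        name = est.index_name
        if not est.defined:
            labels[name] = "undefined on this input (degenerate data)"
        elif name == "JBI":
            if est.ci_low > 0.5:
                labels[name] = "blinding success (CI lower limit > 0.5)"
            elif est.ci_low <= 0.5 <= est.ci_high:
                labels[name] = "random guess (CI includes 0.5)"
            elif est.value > 0.5:
                labels[name] = "blinding success (point estimate > 0.5)"
            else:
                labels[name] = "blinding not demonstrated (JBI below 0.5)"
        elif name.startswith("BBI"):
            v = est.value
            if v == 1.0 and est.zero_width:
                labels[name] = (
                    "complete correct guessing within arm; see study-level indices"
                )
            elif v == 0.0:
                labels[name] = "perfect blinding (BBI = 0)"
            elif abs(v) < cutoff:
                labels[name] = (
                    f"blinding success (|BBI| < {cutoff:g}, "
                    f"{'stringent' if stringent else 'less stringent'} cutoff)"
                )
            elif v > 0:
                labels[name] = (
                    f"correct-guess excess within arm (BBI >= {cutoff:g})"
                )
            else:
                labels[name] = f"opposite guessing within arm (BBI <= -{cutoff:g})"
        elif name == "sumBI":
            labels[name] = (
                "between-arm difference in same-guess proportions (a sum in "
                "form only); no established cutoff"
            )
        elif name == "SBI":
            labels[name] = "no interpretation guidance available"
        else:
            labels[name] = "no interpretation rule for this index"
    return labels


def _fmt2(x: float) -> str:
    if math.isnan(x):
        return "undefined"
    r = round(x, 2) + 0.0  # -0.0 -> 0.0
    return f"{r:.2f}"


def render_report(report: BlindingReport, format: str = "text") -> str:
    """Serialize a report: ``"text"`` (two-decimal display) or ``"json"``.

    The JSON schema is stable — keys ``input``, ``estimates`` (list of
    estimate dicts), ``labels``, ``notes`` — and keeps full precision;
    text output rounds points and CI bounds to two decimals in the
    ``value (low, high)`` style.
    """
    if format == "json":
        payload = {
            "input": report.input_summary,
            "estimates": [e.to_dict() for e in report.estimates],
            "labels": report.labels,
            "notes": report.notes,
        }
        return json.dumps(payload, indent=2)
    if format != "text":
        raise ValueError(f"unknown format {format!r}; use 'text' or 'json'")
    lines = []
    s = report.input_summary
    lines.append(
        f"Blinding assessment — {len(s['arms'])} arms, N={s['n_total']} "
        f"({s['scale']} scale)"
    )
    for arm, tot, idk in zip(s["arms"], s["arm_totals"], s["idk_counts"]):
        lines.append(f"  arm {arm}: n={tot}, IDK={idk}")
    lines.append("")
    for est in report.estimates:
        if est.defined:
            lines.append(
                f"{est.index_name} = {_fmt2(est.value)} "
                f"({_fmt2(est.ci_low)}, {_fmt2(est.ci_high)})"
                f" [{est.ci_method}, {est.ci_level:.0%}]"
            )
        else:
            lines.append(f"{est.index_name} = undefined")
        lines.append(f"    {report.labels[est.index_name]}")
    if report.notes:
        lines.append("")
        lines.append("Notes:")
        lines.extend(f"  - {n}" for n in report.notes)
    return "\n".join(lines)
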