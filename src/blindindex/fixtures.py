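"""Bundled blinding-assessment datasets with published reference values.

Two families of small guess cross-tabulations, generated programmatically:

* ``hypothetical_01`` .. ``hypothetical_07`` — canonical two-arm scenarios
  from the blinding-index literature (all-IDK, opposite guessing, random
  guessing, half-certain, mostly-uncertain, and two unbalanced-allocation
  variants) that tease the three indices apart.
* six real-world randomized trials: an AI-vs-sonographer echocardiography
  trial, a blinded violin tonal-comparison study, a statin trial with
  five-point Likert guesses, a spinal-manual-therapy sham-control trial
  (also Likert), an acupuncture trial collected in 2x2 format, and a
  three-arm disulfiram trial (kept both in its original 3x4 form and with
  the two active-dose arms combined against the control).

Each manifest entry carries the reference index values (rounded to two
decimals, as conventionally reported) that the regression suite checks.
A reference cell is ``None`` where no consistent computation reproduces
the published figure — the sumBI interval method is unstated, the
disulfiram 3x4 James value depends on an unpublished multi-arm weight
matrix, the statin Bang control-arm value mixes weighting conventions, and
one published sumBI is the sum of *rounded* arm values — and the
surrounding docs explain each gap.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .table import GuessTable, combine_arms, write_crosstab

__all__ = ["fixture", "fixture_names", "manifest", "write_fixtures"]


def _t(counts, **kw) -> GuessTable:
    return GuessTable.build(np.asarray(counts), **kw)


def _disulfiram_original() -> GuessTable:
    return _t(
        [[41, 66, 30, 44], [27, 72, 24, 51], [22, 36, 64, 52]],
        arm_labels=("low_disulfiram", "high_disulfiram", "riboflavin"),
        guess_labels=("guess_low_disulfiram", "guess_high_disulfiram", "guess_riboflavin"),
    )


def _disulfiram_combined() -> GuessTable:
    return combine_arms(
        _disulfiram_original(),
        [
            ("disulfiram", ["low_disulfiram", "high_disulfiram"]),
            ("riboflavin", ["riboflavin"]),
        ],
        [
            ("guess_disulfiram", ["guess_low_disulfiram", "guess_high_disulfiram"]),
            ("guess_riboflavin", ["guess_riboflavin"]),
        ],
    )


_BUILDERS = {
    "hypothetical_01": lambda: _t([[0, 0, 100], [0, 0, 100]]),
    "hypothetical_02": lambda: _t([[0, 100, 0], [100, 0, 0]]),
    "hypothetical_03": lambda: _t([[50, 50, 0], [50, 50, 0]]),
    "hypothetical_04": lambda: _t([[50, 0, 50], [0, 50, 50]]),
    "hypothetical_05": lambda: _t([[15, 0, 85], [0, 15, 85]]),
    "hypothetical_06": lambda: _t([[36, 12, 19], [18, 6, 9]]),
    "hypothetical_07": lambda: _t([[50, 17, 0], [25, 8, 0]], scale="ternary"),
    "ai_echo": lambda: _t([[557, 427, 756], [418, 573, 764]]),
    "violins": lambda: _t([[15, 18, 0], [13, 18, 5]], scale="ternary"),
    "statin": lambda: _t([[38, 44, 21, 4, 170], [11, 16, 21, 8, 83]]),
    "spinal_manual": lambda: _t([[0, 4, 3, 0, 32], [0, 6, 3, 0, 32]]),
    "acupuncture": lambda: _t([[42, 0], [19, 2]]),
    "disulfiram": _disulfiram_original,
    "disulfiram_combined": _disulfiram_combined,
}

# Reference estimates: points and 95% CIs rounded to two decimals.  ``None``
# marks cells without a reproducible published value (see module docstring).
_MANIFEST = [
    {
        "name": "hypothetical_01",
        "description": "All responses IDK in both arms: no information at all.",
        "expected": {
            "jbi": None, "jbi_ci": None,
            "bbi_a": None, "bbi_a_ci": None,
            "bbi_b": None, "bbi_b_ci": None,
            "sum_bi": None, "sbi": None, "sbi_ci": None,
        },
        "options": {"jbi_undefined": True, "degenerate": True},
        "notes": "JBI undefined (1 under the all-IDK convention); BBI and SBI "
                 "are refused with a degeneracy error.",
    },
    {
        "name": "hypothetical_02",
        "description": "Every respondent guesses the opposite treatment.",
        "expected": {
            "jbi": 1.0, "jbi_ci": (1.0, 1.0),
            "bbi_a": -1.0, "bbi_a_ci": (-1.0, -1.0),
            "bbi_b": -1.0, "bbi_b_ci": (-1.0, -1.0),
            "sum_bi": -2.0, "sbi": -1.0, "sbi_ci": (-1.0, -0.95),
        },
        "options": {},
        "notes": "Zero-width normal CIs for JBI and BBI; the Wilson-based SBI "
                 "interval keeps positive width.",
    },
    {
        "name": "hypothetical_03",
        "description": "Uniform random guessing, balanced arms.",
        "expected": {
            "jbi": 0.5, "jbi_ci": (0.43, 0.57),
            "bbi_a": 0.0, "bbi_a_ci": (-0.20, 0.20),
            "bbi_b": 0.0, "bbi_b_ci": (-0.20, 0.20),
            "sum_bi": 0.0, "sbi": 0.0, "sbi_ci": (-0.14, 0.14),
        },
        "options": {},
        "notes": "",
    },
    {
        "name": "hypothetical_04",
        "description": "Half of each arm guesses correctly, half says IDK.",
        "expected": {
            "jbi": 0.5, "jbi_ci": (0.43, 0.57),
            "bbi_a": 0.5, "bbi_a_ci": (0.40, 0.60),
            "bbi_b": 0.5, "bbi_b_ci": (0.40, 0.60),
            "sum_bi": 1.0, "sbi": 1.0, "sbi_ci": (0.90, 1.0),
        },
        "options": {},
        "notes": "",
    },
    {
        "name": "hypothetical_05",
        "description": "Mostly IDK; the few guesses are all correct.",
        "expected": {
            "jbi": 0.85, "jbi_ci": (0.80, 0.90),
            "bbi_a": 0.15, "bbi_a_ci": (0.08, 0.22),
            "bbi_b": 0.15, "bbi_b_ci": (0.08, 0.22),
            "sum_bi": 0.30, "sbi": 1.0, "sbi_ci": (0.71, 1.0),
        },
        "options": {},
        "notes": "SBI discards the 170 IDK respondents and judges the "
                 "remaining 30 maximally unblinded.",
    },
    {
        "name": "hypothetical_06",
        "description": "2:1 allocation; mirrored guess proportions across arms.",
        "expected": {
            "jbi": 0.64, "jbi_ci": (0.55, 0.73),
            "bbi_a": 0.36, "bbi_a_ci": (0.17, 0.54),
            "bbi_b": -0.36, "bbi_b_ci": (-0.63, -0.10),
            "sum_bi": None, "sbi": 0.0, "sbi_ci": (-0.19, 0.22),
        },
        "options": {},
        "notes": "The published sumBI (0) is the sum of the rounded arm "
                 "values (0.36 - 0.36); exact computation gives -0.005 -> "
                 "-0.01, so the cell is excluded from the regression.",
    },
    {
        "name": "hypothetical_07",
        "description": "2:1 allocation, no IDK option, same-guess pattern.",
        "expected": {
            "jbi": 0.51, "jbi_ci": (0.41, 0.60),
            "bbi_a": 0.49, "bbi_a_ci": (0.28, 0.70),
            "bbi_b": -0.52, "bbi_b_ci": (-0.81, -0.22),
            "sum_bi": -0.02, "sbi": -0.01, "sbi_ci": (-0.17, 0.18),
        },
        "options": {},
        "notes": "",
    },
    {
        "name": "ai_echo",
        "description": "AI vs sonographer echocardiogram interpretation; "
                       "cardiologists guessed the source (N=3495).",
        "expected": {
            "jbi": 0.68, "jbi_ci": (0.66, 0.69),
            "bbi_a": 0.07, "bbi_a_ci": (0.04, 0.11),
            "bbi_b": 0.09, "bbi_b_ci": (0.05, 0.12),
            "sum_bi": 0.16, "sbi": 0.14, "sbi_ci": (0.10, 0.19),
        },
        "options": {},
        "notes": "",
    },
    {
        "name": "violins",
        "description": "New vs old violins, blinded soloists.",
        "expected": {
            "jbi": 0.52, "jbi_ci": (0.40, 0.64),
            "bbi_a": -0.09, "bbi_a_ci": (-0.43, 0.25),
            "bbi_b": 0.14, "bbi_b_ci": (-0.16, 0.44),
            "sum_bi": 0.05, "sbi": 0.04, "sbi_ci": (-0.20, 0.26),
        },
        "options": {},
        "notes": "",
    },
    {
        "name": "statin",
        "description": "Statin vs placebo; five-point Likert guesses.",
        "expected": {
            "jbi": 0.75, "jbi_ci": None,
            "bbi_a": 0.16, "bbi_a_ci": (0.11, 0.21),
            "bbi_b": None, "bbi_b_ci": None,
            "sum_bi": 0.16, "sbi": 0.28, "sbi_ci": (0.13, 0.43),
        },
        "options": {"bbi_likert_weighted": True},
        "notes": "BBI scored with strongly/somewhat weights 1 and 0.5; the "
                 "published control-arm value (0.01 with CI -0.06, 0.08) is "
                 "reproduced by no single weighting convention and is left "
                 "out of the regression.  The published JBI CI (0.71, 0.78) "
                 "used a closed-form variance; the jackknife gives (0.71, "
                 "0.79) and the interval is excluded from the regression.",
    },
    {
        "name": "spinal_manual",
        "description": "Spinal manual therapy vs sham; five-point Likert "
                       "guesses by outcome assessors.",
        "expected": {
            "jbi": 0.91, "jbi_ci": (0.85, 0.97),
            "bbi_a": 0.03, "bbi_a_ci": (-0.11, 0.16),
            "bbi_b": -0.07, "bbi_b_ci": (-0.21, 0.07),
            "sum_bi": None, "sbi": -0.10, "sbi_ci": (-0.48, 0.32),
        },
        "options": {},
        "notes": "The published sumBI (-0.04) is the sum of the *rounded* arm "
                 "values; exact computation gives -0.048 -> -0.05, so the "
                 "cell is excluded from the regression.",
    },
    {
        "name": "acupuncture",
        "description": "Active vs sham acupuncture; guesses collected without "
                       "an IDK option (2x2 format).",
        "expected": {
            "jbi": 0.44, "jbi_ci": None,
            "bbi_a": 1.0, "bbi_a_ci": (1.0, 1.0),
            "bbi_b": -0.81, "bbi_b_ci": (-1.06, -0.56),
            "sum_bi": 0.19, "sbi": 0.10, "sbi_ci": (-0.01, 0.29),
        },
        "options": {},
        "notes": "Complete correct guessing in the active arm gives BBI_A = 1 "
                 "with a zero-width CI; the study-level indices temper the "
                 "within-arm reading.  The published JBI CI (0.36, 0.52) used "
                 "a closed-form variance; the jackknife gives (0.35, 0.52) "
                 "and the interval is excluded from the regression.",
    },
    {
        "name": "disulfiram",
        "description": "Three-arm disulfiram trial (low dose, high dose, "
                       "riboflavin control) in its original 3x4 form.",
        "expected": {
            "jbi": None, "jbi_ci": None,
            "bbi_a": None, "bbi_a_ci": None,
            "bbi_b": None, "bbi_b_ci": None,
            "sum_bi": None, "sbi": None, "sbi_ci": None,
        },
        "options": {"multi_arm": True},
        "notes": "Uniform 0/0.5/1 weights give JBI 0.57; the published 0.56 "
                 "rests on an unstated multi-arm weight matrix, so the cell "
                 "is excluded.  BBI and SBI need two arms (see the combined "
                 "variant).",
    },
    {
        "name": "disulfiram_combined",
        "description": "Disulfiram trial with both dose arms combined against "
                       "the riboflavin control (~2:1 allocation).",
        "expected": {
            "jbi": 0.52, "jbi_ci": (0.48, 0.57),
            "bbi_a": 0.43, "bbi_a_ci": (0.35, 0.51),
            "bbi_b": 0.03, "bbi_b_ci": (-0.09, 0.16),
            "sum_bi": 0.46, "sbi": 0.32, "sbi_ci": (0.21, 0.41),
        },
        "options": {},
        "notes": "BBI assumes 1:1 allocation; the 2:1 design is reported "
                 "with an unequal-allocation caveat, not refused.",
    },
]


def fixture_names() -> list:
    """Names of all bundled datasets, hypothetical then real-world."""
    return list(_BUILDERS)


def fixture(name: str) -> GuessTable:
    """Build a bundled dataset by name."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_BUILDERS)}"
        ) from None


def manifest() -> list:
    """Deep copy of the manifest (name, description, reference values)."""
    return json.loads(json.dumps(_MANIFEST))


def write_fixtures(outdir) -> list:
    """Write every dataset as cross-tab CSV plus ``manifest.json``.

    Returns the written file paths.  Output is deterministic: regenerating
    into the same directory reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    entries = []
    for entry in manifest():
        name = entry["name"]
        path = outdir / f"{name}.csv"
        write_crosstab(fixture(name), path)
        written.append(path)
        entry["file"] = path.name
        entries.append(entry)
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(entries, indent=2) + "\n", encoding="utf-8")
    written.append(man_path)
    return written
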