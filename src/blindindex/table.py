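"""Cross-tabulated treatment-guess data for blinding assessment.

A blinding questionnaire asks each trial participant (or assessor) which
treatment they believe they received.  The answers, cross-tabulated against
the randomized arm, form the input to every blinding index: a ``k x (k+1)``
integer table whose rows are arms, whose first ``k`` columns are treatment
guesses (the guess at ordinal position ``j`` is the *correct* guess for arm
``j``), and whose last column counts "I don't know" (IDK) responses.

Tables without an IDK option (the 2x2 format) are represented with an
all-zero IDK column so every estimator consumes a single type.  Five-point
Likert responses ("strongly/somewhat believe I received A/B" plus IDK) are
stored alongside their collapsed ternary form.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "GuessTable",
    "BlindingDataError",
    "TableFormatError",
    "DegenerateDataError",
    "read_crosstab",
    "read_long",
    "collapse_likert",
    "combine_arms",
    "drop_idk",
    "write_crosstab",
    "IDK_LABEL",
    "LIKERT5_LABELS",
]

IDK_LABEL = "IDK"

#: Canonical five-point Likert guess labels for a two-arm trial, in column
#: order: strong/weak belief in the first arm's treatment, weak/strong belief
#: in the second arm's treatment, and genuine uncertainty.
LIKERT5_LABELS = ("strongly_A", "somewhat_A", "somewhat_B", "strongly_B", IDK_LABEL)

SCALES = ("binary", "ternary", "likert5")


class BlindingDataError(ValueError):
    """Base class for invalid blinding-table input."""


class TableFormatError(BlindingDataError):
    """Malformed cross-tab or long-format input (bad cell, label, header)."""


class DegenerateDataError(BlindingDataError):
    """Structurally valid data on which an estimator is undefined."""


def _as_count_matrix(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise TableFormatError(f"{what} must be a 2-D matrix, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        as_int = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(as_int)) or np.any(as_int != np.floor(as_int)):
            raise TableFormatError(f"{what} must contain integers only")
        arr = as_int.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise TableFormatError(f"negative count at row {i}, column {j} of {what}")
    return arr


@dataclass(frozen=True, eq=False)
class GuessTable:
    """Guess counts cross-tabulated by randomized arm.

    Parameters
    ----------
    arm_labels
        Ordered arm identifiers (length ``k >= 2``).
    guess_labels
        Ordered treatment-guess identifiers (length ``k``); the guess at
        position ``j`` is the correct guess for arm ``j``.
    counts
        ``k x (k+1)`` non-negative integer matrix; the last column is IDK.
    scale
        ``"binary"`` (no IDK option; IDK column all zero), ``"ternary"``
        (guesses plus IDK), or ``"likert5"`` (two arms, five-point responses
        collapsed into the ternary ``counts``).
    likert_counts
        The raw ``2 x 5`` matrix (columns per :data:`LIKERT5_LABELS`),
        retained when ``scale == "likert5"``.
    idk_excluded
        Per-arm counts of IDK responses removed by :func:`drop_idk`;
        carried so downstream reports can state the analytical sample loss.
    """

    arm_labels: tuple
    guess_labels: tuple
    counts: np.ndarray
    scale: str = "ternary"
    likert_counts: np.ndarray | None = None
    idk_excluded: tuple | None = None

    def __post_init__(self) -> None:
        arms = tuple(str(a) for a in self.arm_labels)
        guesses = tuple(str(g) for g in self.guess_labels)
        object.__setattr__(self, "arm_labels", arms)
        object.__setattr__(self, "guess_labels", guesses)
        if len(arms) < 2:
            raise TableFormatError("need at least two arms")
        if len(set(arms)) != len(arms):
            raise TableFormatError(f"duplicate arm labels: {arms}")
        if len(set(guesses)) != len(guesses):
            raise TableFormatError(f"duplicate guess labels: {guesses}")
        if len(guesses) != len(arms):
            raise TableFormatError(
                f"{len(arms)} arms need {len(arms)} guess labels, got {len(guesses)}"
            )
        counts = _as_count_matrix(self.counts, "counts")
        k = len(arms)
        if counts.shape != (k, k + 1):
            raise TableFormatError(
                f"counts must be {k}x{k + 1} (guesses + IDK), got {counts.shape}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        row_totals = counts.sum(axis=1)
        if np.any(row_totals < 1):
            empty = arms[int(np.argmin(row_totals))]
            raise TableFormatError(f"arm {empty!r} has no responses")
        if self.scale not in SCALES:
            raise TableFormatError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.scale == "binary" and counts[:, -1].any():
            raise TableFormatError("binary tables must have an all-zero IDK column")
        if self.scale == "likert5":
            if k != 2:
                raise TableFormatError("likert5 tables must have exactly two arms")
            if self.likert_counts is None:
                raise TableFormatError("likert5 tables require likert_counts")
            lik = _as_count_matrix(self.likert_counts, "likert_counts")
            if lik.shape != (2, 5):
                raise TableFormatError(f"likert_counts must be 2x5, got {lik.shape}")
            lik.setflags(write=False)
            object.__setattr__(self, "likert_counts", lik)
            collapsed = np.column_stack(
                [lik[:, 0] + lik[:, 1], lik[:, 2] + lik[:, 3], lik[:, 4]]
            )
            if not np.array_equal(collapsed, counts):
                raise TableFormatError(
                    "counts must equal the likert_counts collapsed by belief side"
                )
        elif self.likert_counts is not None:
            raise TableFormatError("likert_counts only allowed when scale='likert5'")
        if self.idk_excluded is not None:
            excl = tuple(int(x) for x in self.idk_excluded)
            if len(excl) != k or any(x < 0 for x in excl):
                raise TableFormatError("idk_excluded must be k non-negative integers")
            object.__setattr__(self, "idk_excluded", excl)

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        counts,
        arm_labels: Sequence[str] | None = None,
        guess_labels: Sequence[str] | None = None,
        scale: str | None = None,
    ) -> "GuessTable":
        """Build a table from a count matrix, padding and inferring as needed.

        Accepts a ``k x k`` matrix (no IDK column: padded with zeros,
        inferred binary), a ``k x (k+1)`` matrix, or a ``2 x 5`` matrix
        (inferred likert5).  Default labels are ``A, B, C ...`` for arms and
        ``guess_<arm>`` for guesses.
        """
        arr = _as_count_matrix(counts, "counts")
        rows, cols = arr.shape
        likert = None
        if rows == 2 and cols == 5 and (scale is None or scale == "likert5"):
            likert = arr
            arr = np.column_stack(
                [arr[:, 0] + arr[:, 1], arr[:, 2] + arr[:, 3], arr[:, 4]]
            )
            scale = "likert5"
        elif cols == rows:  # no IDK column supplied
            arr = np.column_stack([arr, np.zeros(rows, dtype=np.int64)])
            if scale is None:
                scale = "binary"
        elif cols != rows + 1:
            raise TableFormatError(
                f"cannot interpret a {rows}x{cols} matrix as a guess table"
            )
        if scale is None:
            scale = "binary" if not arr[:, -1].any() else "ternary"
        if scale == "binary" and not arr[:, -1].any():
            pass
        k = arr.shape[0]
        if arm_labels is None:
            arm_labels = tuple("ABCDEFGH"[i] for i in range(k))
        if guess_labels is None:
            guess_labels = tuple(f"guess{a}" for a in arm_labels)
        return cls(tuple(arm_labels), tuple(guess_labels), arr, scale, likert)

    # -- views -------------------------------------------------------------

    @property
    def k(self) -> int:
        """Number of arms."""
        return len(self.arm_labels)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def arm_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def idk_counts(self) -> np.ndarray:
        return self.counts[:, -1]

    @property
    def has_idk(self) -> bool:
        return bool(self.counts[:, -1].any())

    @property
    def treatment_counts(self) -> np.ndarray:
        """The ``k x k`` block of treatment guesses (IDK column removed)."""
        return self.counts[:, :-1]

    def arm_index(self, arm: Union[int, str]) -> int:
        if isinstance(arm, (int, np.integer)):
            if not 0 <= arm < self.k:
                raise IndexError(f"arm index {arm} out of range for k={self.k}")
            return int(arm)
        try:
            return self.arm_labels.index(str(arm))
        except ValueError:
            raise KeyError(f"unknown arm {arm!r}; arms are {self.arm_labels}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, GuessTable):
            return NotImplemented
        return (
            self.arm_labels == other.arm_labels
            and self.guess_labels == other.guess_labels
            and self.scale == other.scale
            and np.array_equal(self.counts, other.counts)
            and (
                (self.likert_counts is None) == (other.likert_counts is None)
                and (
                    self.likert_counts is None
                    or np.array_equal(self.likert_counts, other.likert_counts)
                )
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rows = "; ".join(
            f"{a}: {', '.join(str(c) for c in row)}"
            for a, row in zip(self.arm_labels, self.counts)
        )
        return f"GuessTable({self.scale}, N={self.n_total}, {rows})"

    def summary(self) -> dict:
        """Input summary used by reports: totals, IDK counts, scale."""
        out = {
            "arms": list(self.arm_labels),
            "guesses": list(self.guess_labels),
            "scale": self.scale,
            "n_total": self.n_total,
            "arm_totals": [int(x) for x in self.arm_totals],
            "idk_counts": [int(x) for x in self.idk_counts],
        }
        if self.idk_excluded is not None:
            out["idk_excluded"] = list(self.idk_excluded)
        return out

    def to_long_records(self, idk_token: str = IDK_LABEL) -> list:
        """Expand to one ``(arm, guess)`` record per respondent."""
        records = []
        labels = self.guess_labels + (idk_token,)
        for a, row in zip(self.arm_labels, self.counts):
            for lab, c in zip(labels, row):
                records.extend([(a, lab)] * int(c))
        return records


# -- I/O -------------------------------------------------------------------


def _open_source(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" in text or "," in text:
        return io.StringIO(text)
    return open(text, "r", encoding="utf-8", newline="")


def read_crosstab(source, has_idk: bool | None = None, scale: str | None = None) -> GuessTable:
    """Read a cross-tab CSV: header ``arm,<guess labels...>[,IDK]``, one row per arm.

    ``has_idk`` may force interpretation of the last column; by default a
    final header equal to ``"IDK"`` (case-insensitive) marks the IDK column.
    A two-arm table with four guess columns plus IDK is read as a five-point
    Likert table and collapsed.
    """
    stream = _open_source(source)
    reader = csv.reader(stream)
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if len(rows) < 3:
        raise TableFormatError("need a header row and at least two arm rows")
    header = [c.strip() for c in rows[0]]
    guess_labels = header[1:]
    if has_idk is None:
        has_idk = bool(guess_labels) and guess_labels[-1].upper() == IDK_LABEL
    if has_idk:
        idk_header = guess_labels[-1]
        guess_labels = guess_labels[:-1]
    if len(set(guess_labels)) != len(guess_labels):
        raise TableFormatError(f"duplicate guess labels in header: {guess_labels}")

    arm_labels = []
    data = []
    for r in rows[1:]:
        cells = [c.strip() for c in r]
        arm = cells[0]
        if arm in arm_labels:
            raise TableFormatError(f"duplicate arm label {arm!r}")
        arm_labels.append(arm)
        if len(cells) - 1 != len(guess_labels) + (1 if has_idk else 0):
            raise TableFormatError(
                f"arm {arm!r} has {len(cells) - 1} cells, expected "
                f"{len(guess_labels) + (1 if has_idk else 0)}"
            )
        parsed = []
        for col, cell in zip(header[1:], cells[1:]):
            try:
                val = int(cell)
            except ValueError:
                raise TableFormatError(
                    f"non-integer count {cell!r} at arm {arm!r}, column {col!r}"
                ) from None
            if val < 0:
                raise TableFormatError(
                    f"negative count {val} at arm {arm!r}, column {col!r}"
                )
            parsed.append(val)
        data.append(parsed)

    arr = np.asarray(data, dtype=np.int64)
    k = len(arm_labels)
    if k == 2 and len(guess_labels) == 4 and has_idk:
        # five-point Likert layout
        return GuessTable(
            tuple(arm_labels),
            (f"guess{arm_labels[0]}", f"guess{arm_labels[1]}"),
            np.column_stack([arr[:, 0] + arr[:, 1], arr[:, 2] + arr[:, 3], arr[:, 4]]),
            "likert5",
            arr,
        )
    if len(guess_labels) != k:
        raise TableFormatError(
            f"{k} arms need {k} guess columns (+ optional IDK), got {len(guess_labels)}"
        )
    if not has_idk:
        arr = np.column_stack([arr, np.zeros(k, dtype=np.int64)])
    if scale is None:
        scale = "binary" if not arr[:, -1].any() else "ternary"
    return GuessTable(tuple(arm_labels), tuple(guess_labels), arr, scale)


def read_long(
    source,
    arm_column: str = "arm",
    guess_column: str = "guess",
    idk_token: str = IDK_LABEL,
    arm_labels: Sequence[str] | None = None,
    guess_labels: Sequence[str] | None = None,
) -> GuessTable:
    """Read respondent-level records (one row per respondent) into a table.

    When ``arm_labels``/``guess_labels`` are not given they are the sorted
    distinct values found in the data, so the result does not depend on
    record order; position ``j`` of ``guess_labels`` is taken as the correct
    guess for arm ``j``.
    """
    stream = _open_source(source)
    reader = csv.DictReader(stream)
    if reader.fieldnames is None or arm_column not in reader.fieldnames:
        raise TableFormatError(f"missing arm column {arm_column!r}")
    if guess_column not in reader.fieldnames:
        raise TableFormatError(f"missing guess column {guess_column!r}")
    pairs = []
    for i, rec in enumerate(reader, start=2):
        arm = (rec[arm_column] or "").strip()
        guess = (rec[guess_column] or "").strip()
        if not arm:
            raise TableFormatError(f"row {i}: missing arm value")
        if not guess:
            raise TableFormatError(f"row {i}: missing guess value")
        pairs.append((arm, guess))
    if not pairs:
        raise TableFormatError("no respondent records found")

    arms = tuple(arm_labels) if arm_labels is not None else tuple(
        sorted({a for a, _ in pairs})
    )
    if guess_labels is not None:
        guesses = tuple(guess_labels)
    else:
        guesses = tuple(sorted({g for _, g in pairs if g != idk_token}))
    vocab = set(guesses) | {idk_token}
    counts = np.zeros((len(arms), len(guesses) + 1), dtype=np.int64)
    arm_pos = {a: j for j, a in enumerate(arms)}
    guess_pos = {g: i for i, g in enumerate(guesses)}
    for arm, guess in pairs:
        if arm not in arm_pos:
            raise TableFormatError(f"unknown arm {arm!r}; declared arms {arms}")
        if guess not in vocab:
            raise TableFormatError(
                f"unknown guess {guess!r}; allowed {sorted(vocab)}"
            )
        col = len(guesses) if guess == idk_token else guess_pos[guess]
        counts[arm_pos[arm], col] += 1
    scale = "binary" if not counts[:, -1].any() else "ternary"
    return GuessTable(arms, guesses, counts, scale)


def write_crosstab(table: GuessTable, dest) -> None:
    """Write a table as cross-tab CSV (Likert tables keep all five columns)."""
    own = not hasattr(dest, "write")
    stream = open(dest, "w", encoding="utf-8", newline="") if own else dest
    try:
        writer = csv.writer(stream, lineterminator="\n")
        if table.scale == "likert5":
            writer.writerow(["arm", *LIKERT5_LABELS])
            for arm, row in zip(table.arm_labels, table.likert_counts):
                writer.writerow([arm, *[int(c) for c in row]])
        elif table.scale == "binary":
            writer.writerow(["arm", *table.guess_labels])
            for arm, row in zip(table.arm_labels, table.treatment_counts):
                writer.writerow([arm, *[int(c) for c in row]])
        else:
            writer.writerow(["arm", *table.guess_labels, IDK_LABEL])
            for arm, row in zip(table.arm_labels, table.counts):
                writer.writerow([arm, *[int(c) for c in row]])
    finally:
        if own:
            stream.close()


# -- transformations -------------------------------------------------------


def collapse_likert(table: GuessTable) -> GuessTable:
    """Collapse a five-point Likert table to ternary ("strong" + "somewhat").

    The belief side is preserved: the two "believe A" columns merge into the
    guess-A count, the two "believe B" columns into guess-B; IDK is kept and
    the grand total is unchanged.
    """
    if table.scale != "likert5":
        raise BlindingDataError(
            f"collapse_likert needs a likert5 table, got scale={table.scale!r}"
        )
    return GuessTable(
        table.arm_labels,
        table.guess_labels,
        table.counts.copy(),
        "ternary",
        None,
        table.idk_excluded,
    )


def _normalize_groups(
    groups, labels: Sequence[str], what: str
) -> "list[tuple[str, list[str]]]":
    if isinstance(groups, Mapping):
        items = [(str(k), [str(m) for m in v]) for k, v in groups.items()]
    else:
        items = [(str(k), [str(m) for m in v]) for k, v in groups]
    seen: list[str] = []
    for _, members in items:
        seen.extend(members)
    if sorted(seen) != sorted(labels):
        raise BlindingDataError(
            f"{what} groups must partition {list(labels)}, got {sorted(seen)}"
        )
    return items


def combine_arms(table: GuessTable, arm_groups, guess_groups) -> GuessTable:
    """Merge arms and guess categories by summing their cells.

    ``arm_groups`` / ``guess_groups`` map each new label to the old labels it
    absorbs (a dict or a list of ``(new, [old...])`` pairs) and must
    partition the existing labels; the IDK column always maps to IDK.  Used
    e.g. to reduce a three-arm, two-dose design to an active-vs-control 2x3
    table.  The grand total is unchanged.
    """
    a_items = _normalize_groups(arm_groups, table.arm_labels, "arm")
    g_items = _normalize_groups(guess_groups, table.guess_labels, "guess")
    if len(a_items) != len(g_items):
        raise BlindingDataError(
            "combined table needs as many guess groups as arm groups"
        )
    arm_pos = {a: j for j, a in enumerate(table.arm_labels)}
    guess_pos = {g: i for i, g in enumerate(table.guess_labels)}
    k_new = len(a_items)
    out = np.zeros((k_new, k_new + 1), dtype=np.int64)
    for jn, (_, arms) in enumerate(a_items):
        rows = [arm_pos[a] for a in arms]
        merged = table.counts[rows].sum(axis=0)
        for in_, (_, guesses) in enumerate(g_items):
            out[jn, in_] = merged[[guess_pos[g] for g in guesses]].sum()
        out[jn, -1] = merged[-1]
    scale = "binary" if not out[:, -1].any() else "ternary"
    return GuessTable(
        tuple(k for k, _ in a_items),
        tuple(k for k, _ in g_items),
        out,
        scale,
    )


def drop_idk(table: GuessTable) -> GuessTable:
    """Remove IDK responses, recording the exclusions per arm.

    Returns a binary-format table whose arm totals shrink by the IDK counts;
    the removed counts are attached as ``idk_excluded`` so reports can state
    the loss of analytical sample size.  An arm left with no responses makes
    the reduction undefined.
    """
    if table.scale == "likert5":
        table = collapse_likert(table)
    excluded = tuple(int(x) for x in table.idk_counts)
    remaining = table.treatment_counts
    arm_left = remaining.sum(axis=1)
    if np.any(arm_left == 0):
        bad = [a for a, n in zip(table.arm_labels, arm_left) if n == 0]
        raise DegenerateDataError(
            f"arm(s) {bad} have only IDK responses; cannot form a 2x2 table"
        )
    counts = np.column_stack([remaining, np.zeros(table.k, dtype=np.int64)])
    return GuessTable(
        table.arm_labels,
        table.guess_labels,
        counts,
        "binary",
        None,
        excluded if any(excluded) else table.idk_excluded,
    )
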