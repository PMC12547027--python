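"""Shared result container for blinding-index estimates."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["IndexEstimate", "FLAGS"]

#: Recognized degeneracy / caveat flags.
FLAGS = frozenset(
    {
        "degenerate",
        "zero_width_ci",
        "undefined",
        "unequal_allocation",
        "idk_excluded",
        "likert_weighted",
        "jackknife_replicate_degenerate",
        "multi_arm",
    }
)


@dataclass(frozen=True)
class IndexEstimate:
    """One blinding-index estimate with its uncertainty and provenance.

    ``value`` is NaN when the index is undefined on the input (flag
    ``undefined``).  ``ci_method`` names how the interval was formed:
    ``jackknife-normal`` (James), ``multinomial-normal`` (Bang), or
    ``wilson-mover`` (Simple).
    """

    index_name: str
    value: float
    se: float | None
    ci_low: float
    ci_high: float
    ci_level: float
    ci_method: str
    n_used: int
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        unknown = self.flags - FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")
        if not (0 < self.ci_level < 1):
            raise ValueError(f"ci_level must be in (0,1), got {self.ci_level}")
        if self.defined and not (
            self.ci_low <= self.value + 1e-12 and self.value - 1e-12 <= self.ci_high
        ):
            raise ValueError(
                f"{self.index_name}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"contain the estimate {self.value}"
            )

    @property
    def defined(self) -> bool:
        return "undefined" not in self.flags and not math.isnan(self.value)

    @property
    def zero_width(self) -> bool:
        return "zero_width_ci" in self.flags

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "value": None if math.isnan(self.value) else self.value,
            "se": self.se,
            "ci_low": None if math.isnan(self.ci_low) else self.ci_low,
            "ci_high": None if math.isnan(self.ci_high) else self.ci_high,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "n_used": self.n_used,
            "flags": sorted(self.flags),
        }
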