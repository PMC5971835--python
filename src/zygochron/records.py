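"""Domain types for zygantral growth records.

A snake vertebra carries a pair of zygantral facets (left and right) whose
surfaces preserve an unremodelled sequence of annual growth lines.  Each
facet is scored independently under the microscope; a vertebra therefore
yields two line counts, a body-size proxy (centrum length), and condition
flags.  These types model one scored vertebra and the parameters of the
pairwise compatibility rule used to resolve commingled material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Condition(str, Enum):
    """Preservation state of one zygantral facet.

    INTACT facets carry a trustworthy count.  DAMAGED facets may carry a
    count (preparation damage can shave off peripheral lines) but are
    excluded from modal statistics by default.  OBSCURED_FUSED covers
    facets unreadable because of vertebral fusion; MISSING covers facets
    absent altogether.
    """

    INTACT = "intact"
    DAMAGED = "damaged"
    OBSCURED_FUSED = "obscured_fused"
    MISSING = "missing"


class DataError(Exception):
    """Base class for dataset problems."""


class FormatError(DataError):
    """Malformed table structure (e.g. missing header columns)."""


class RowError(DataError):
    """A single unparseable row; carries the offending record_id."""

    def __init__(self, record_id: str, message: str):
        self.record_id = record_id
        super().__init__(f"record {record_id!r}: {message}")


class ValidationError(DataError):
    """Dataset-level invariant violation (e.g. duplicate record ids)."""


class SizeCapError(DataError):
    """Exact partition enumeration refused: component exceeds the cap."""


@dataclass(frozen=True)
class ZygantralRecord:
    """Growth record of one zygantral facet.

    ``line_positions``, when present, gives the position of each growth
    line along the facet's long axis normalized by final facet length;
    values are strictly increasing in (0, 1].
    """

    side: Side
    line_count: Optional[int] = None
    line_positions: Optional[tuple[float, ...]] = None
    condition: Condition = Condition.INTACT

    def __post_init__(self) -> None:
        if self.line_count is not None and self.line_count < 0:
            raise ValueError("line_count must be nonnegative")
        if self.condition is Condition.INTACT and self.line_count is None:
            raise ValueError("an intact zygantrum must carry a line count")
        if self.line_count is None and self.line_positions is not None:
            raise ValueError("line_positions without a line_count")
        if self.line_positions is not None:
            pos = self.line_positions
            if len(pos) != self.line_count:
                raise ValueError("len(line_positions) must equal line_count")
            if any(not (0.0 < p <= 1.0) for p in pos):
                raise ValueError("line positions must lie in (0, 1]")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("line positions must be strictly increasing")

    @property
    def scorable(self) -> bool:
        return self.condition is Condition.INTACT and self.line_count is not None


@dataclass(frozen=True)
class VertebraRecord:
    """One vertebra: paired zygantral records plus size and provenance."""

    record_id: str
    lot_id: str
    left: ZygantralRecord
    right: ZygantralRecord
    specimen_id: Optional[str] = None
    column_position: Optional[int] = None
    centrum_length_mm: Optional[float] = None

    def __post_init__(self) -> None:
        # centrum_length_mm > 0 and column_position >= 1 are dataset-level
        # invariants surfaced by validate_dataset, which must be able to
        # list offending records rather than refuse to represent them.
        if self.left.side is not Side.LEFT or self.right.side is not Side.RIGHT:
            raise ValueError("left/right zygantral records have swapped sides")

    def intact_counts(self) -> list[int]:
        return [z.line_count for z in (self.left, self.right) if z.scorable]


@dataclass(frozen=True)
class CombinedCount:
    """Per-vertebra combined line count under a side-merging policy.

    ``status`` is "ok" when a count was produced, "ambiguous" when the
    agree_only policy met diverging sides, "unscorable" when neither side
    is intact.  ``divergent`` flags any inter-side disagreement among
    intact facets, regardless of policy.
    """

    value: Optional[int]
    status: str = "ok"
    divergent: bool = False

    @property
    def scorable(self) -> bool:
        return self.status == "ok" and self.value is not None


def combined_count(v: VertebraRecord, policy: str = "max_intact") -> CombinedCount:
    """Merge the two zygantral counts of one vertebra into a single age input.

    Under ``max_intact`` (default) the larger intact count wins: divergent
    facets typically lose a line to faint peripheral LAGs rather than gain
    one, so the maximum is the best single-vertebra age estimate.  Under
    ``agree_only`` a shared value is required and disagreement is flagged
    ambiguous.  Both-sides-unreadable vertebrae come back unscorable.
    """
    if policy not in ("max_intact", "agree_only"):
        raise ValueError(f"unknown policy {policy!r}")
    counts = v.intact_counts()
    if not counts:
        return CombinedCount(None, status="unscorable")
    divergent = len(set(counts)) > 1
    if policy == "agree_only" and divergent:
        return CombinedCount(None, status="ambiguous", divergent=True)
    return CombinedCount(max(counts), divergent=divergent)


def _percent(tally: int, total: int) -> int:
    """Integer percent, round half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return math.floor(100 * tally / total + 0.5)


@dataclass(frozen=True)
class CountTable:
    """Line-count tallies per category (left, right, combined).

    Only integer tallies are stored; percentages are derived on demand so
    they are always consistent with the tallies.
    """

    left: dict[int, int] = field(default_factory=dict)
    right: dict[int, int] = field(default_factory=dict)
    combined: dict[int, int] = field(default_factory=dict)

    def tallies(self, category: str) -> dict[int, int]:
        if category not in ("left", "right", "combined"):
            raise ValueError(f"unknown category {category!r}")
        return dict(getattr(self, category))

    def total(self, category: str) -> int:
        return sum(self.tallies(category).values())

    def percents(self, category: str) -> dict[int, int]:
        t = self.tallies(category)
        total = sum(t.values())
        return {c: _percent(n, total) for c, n in t.items()}

    def to_dict(self) -> dict:
        return {
            cat: {str(c): n for c, n in sorted(self.tallies(cat).items())}
            for cat in ("left", "right", "combined")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CountTable":
        return cls(**{
            cat: {int(c): int(n) for c, n in d.get(cat, {}).items()}
            for cat in ("left", "right", "combined")
        })


@dataclass(frozen=True)
class CompatibilityParams:
    """Parameters of the pairwise same-individual rule.

    age_margin
        Maximum tolerated difference in combined line counts between two
        vertebrae of one individual.  Default 1: intra-column counts in
        extant snakes vary by at most one line.
    k_sigma, cv_percent
        Size envelope.  Two vertebrae of equal (or near-equal) age must
        have centrum lengths within ``k_sigma`` standard deviations of one
        another, with the standard deviation expressed as ``cv_percent``
        of the pair mean.  Defaults: k_sigma 2 with cv_percent evaluated
        at 12.7 and 19.5, the within-column coefficients of variation of
        the two extant species phylogenetically bracketing the fossil.
    spacing_threshold
        Optional cap on the RMS spacing-pattern dissimilarity; disabled by
        default (the qualitative published procedure reports no number).
    missing_length_policy
        "pass" (default): a missing centrum length does not block a match;
        "fail": it does.
    """

    age_margin: int = 1
    k_sigma: float = 2.0
    cv_percent: float = 12.7
    spacing_threshold: Optional[float] = None
    missing_length_policy: str = "pass"

    DEFAULT_CV_BRACKET = (12.7, 19.5)

    def __post_init__(self) -> None:
        if self.age_margin < 0:
            raise ValueError("age_margin must be >= 0")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")
        if not (0 < self.cv_percent < 100):
            raise ValueError("cv_percent must be in (0, 100)")
        if self.spacing_threshold is not None and self.spacing_threshold < 0:
            raise ValueError("spacing_threshold must be >= 0")
        if self.missing_length_policy not in ("pass", "fail"):
            raise ValueError("missing_length_policy must be 'pass' or 'fail'")

    def with_cv(self, cv_percent: float) -> "CompatibilityParams":
        return replace(self, cv_percent=cv_percent)

    def to_dict(self) -> dict:
        return {
            "age_margin": self.age_margin,
            "k_sigma": self.k_sigma,
            "cv_percent": self.cv_percent,
            "spacing_threshold": self.spacing_threshold,
            "missing_length_policy": self.missing_length_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompatibilityParams":
        return cls(**d)


@dataclass(frozen=True)
class ValidationIssue:
    record_id: Optional[str]
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    n_records: int
    n_missing_centrum: int
    n_unscorable: int
    issues: tuple[ValidationIssue, ...] = ()

    @property
    def proportion_unscorable(self) -> float:
        return self.n_unscorable / self.n_records if self.n_records else 0.0

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(records: Sequence[VertebraRecord]) -> ValidationReport:
    """Report-only dataset check: duplicates, impossible values, damage rate.

    Never mutates or filters; callers decide what to do with the report.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    n_missing = 0
    n_unscorable = 0
    for v in records:
        if v.record_id in seen:
            issues.append(ValidationIssue(v.record_id, "duplicate_id",
                                          "record_id appears more than once"))
        seen.add(v.record_id)
        if v.centrum_length_mm is None:
            n_missing += 1
        elif v.centrum_length_mm <= 0:
            issues.append(ValidationIssue(v.record_id, "impossible_value",
                                          f"centrum_length_mm = {v.centrum_length_mm}"))
        if v.column_position is not None and v.column_position < 1:
            issues.append(ValidationIssue(v.record_id, "impossible_value",
                                          f"column_position = {v.column_position}"))
        if not combined_count(v).scorable:
            n_unscorable += 1
    return ValidationReport(
        n_records=len(records),
        n_missing_centrum=n_missing,
        n_unscorable=n_unscorable,
        issues=tuple(issues),
    )
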