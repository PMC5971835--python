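"""Stage 1: summarize an articulated vertebral column.

An articulated column from a known individual is reduced to (i) per-side
and per-vertebra line-count tallies, (ii) a modal age estimate with its
support, (iii) centrum-length statistics (mean, sample sd, CV%), and
(iv) a consensus growth-line spacing pattern.  These summaries both
characterize extant reference species and calibrate the margins used when
fingerprinting isolated fossil material.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import CountTable, DataError, VertebraRecord, combined_count


@dataclass(frozen=True)
class SpacingPattern:
    """Normalized growth-line positions along the zygantral long axis."""

    positions: tuple[float, ...]

    def __post_init__(self) -> None:
        pos = self.positions
        if any(not (0.0 < p <= 1.0) for p in pos):
            raise ValueError("positions must lie in (0, 1]")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ModalEstimate:
    """Modal combined line count with support; ties carry all candidates."""

    candidates: tuple[int, ...]
    support: float

    @property
    def is_ambiguous(self) -> bool:
        return len(self.candidates) > 1

    @property
    def count(self) -> int:
        if self.is_ambiguous:
            raise DataError(f"modal count is ambiguous: {self.candidates}")
        return self.candidates[0]


@dataclass(frozen=True)
class CentrumStats:
    mean_mm: float
    sd_mm: float

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd_mm / self.mean_mm


@dataclass(frozen=True)
class ColumnProfile:
    """Per-individual summary in the shape of the published species table."""

    counts: CountTable
    modal: ModalEstimate
    centrum: Optional[CentrumStats] = None
    spacing_consensus: Optional[SpacingPattern] = None
    label: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "counts": self.counts.to_dict(),
            "modal": {"candidates": list(self.modal.candidates),
                      "support": self.modal.support},
            "centrum": None if self.centrum is None else
                       {"mean_mm": self.centrum.mean_mm,
                        "sd_mm": self.centrum.sd_mm,
                        "cv_percent": self.centrum.cv_percent},
            "spacing_consensus": None if self.spacing_consensus is None
                                 else list(self.spacing_consensus.positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnProfile":
        centrum = d.get("centrum")
        spacing = d.get("spacing_consensus")
        return cls(
            counts=CountTable.from_dict(d["counts"]),
            modal=ModalEstimate(tuple(d["modal"]["candidates"]),
                                d["modal"]["support"]),
            centrum=None if centrum is None else
                    CentrumStats(centrum["mean_mm"], centrum["sd_mm"]),
            spacing_consensus=None if spacing is None
                              else SpacingPattern(tuple(spacing)),
            label=d.get("label"),
        )


def count_table(column: Sequence[VertebraRecord]) -> CountTable:
    """Tally line counts per side and per vertebra.

    Per-side tallies run over intact zygantra only.  The per-vertebra
    ("combined") tally applies the both-sides-divergent rule: a vertebra
    counts at the column-modal value as long as at least one intact facet
    shows it, and at its own (shared or maximal) divergent value only when
    both facets miss the mode.  This is the convention under which the
    published combined columns are reproducible from the per-side ones.
    """
    left = Counter(z.line_count for v in column for z in (v.left,) if z.scorable)
    right = Counter(z.line_count for v in column for z in (v.right,) if z.scorable)
    pooled = left + right
    if not pooled:
        raise DataError("no scorable zygantra in column")
    modal_pool = max(pooled, key=lambda c: (pooled[c], -c))

    comb: Counter = Counter()
    for v in column:
        counts = v.intact_counts()
        if not counts:
            continue
        comb[modal_pool if modal_pool in counts else max(counts)] += 1
    return CountTable(left=dict(left), right=dict(right), combined=dict(comb))


def modal_age_estimate(column: Sequence[VertebraRecord]) -> ModalEstimate:
    """Modal combined count and its support fraction; ties are reported."""
    table = count_table(column).tallies("combined")
    total = sum(table.values())
    top = max(table.values())
    candidates = tuple(sorted(c for c, n in table.items() if n == top))
    return ModalEstimate(candidates=candidates, support=top / total)


def centrum_stats(column: Sequence[VertebraRecord]) -> Optional[CentrumStats]:
    """Mean, sample (n-1) standard deviation and CV%% of centrum lengths.

    Returns None (undefined statistics) with fewer than two measured
    lengths.
    """
    lengths = np.array([v.centrum_length_mm for v in column
                        if v.centrum_length_mm is not None], dtype=float)
    if lengths.size < 2:
        return None
    return CentrumStats(mean_mm=float(lengths.mean()),
                        sd_mm=float(lengths.std(ddof=1)))


def spacing_consensus(column: Sequence[VertebraRecord]) -> Optional[SpacingPattern]:
    """Element-wise mean spacing pattern over modal-count zygantra.

    Zygantra whose count differs from the column mode are excluded so the
    average is taken over aligned, equal-length vectors.  Returns None
    when no positional data are available at the modal count.
    """
    modal = modal_age_estimate(column)
    if modal.is_ambiguous:
        raise DataError(f"modal count is ambiguous: {modal.candidates}")
    vectors = [z.line_positions for v in column for z in (v.left, v.right)
               if z.scorable and z.line_count == modal.count
               and z.line_positions is not None]
    if not vectors:
        return None
    mean = np.mean(np.array(vectors, dtype=float), axis=0)
    return SpacingPattern(tuple(float(x) for x in mean))


def spacing_similarity(a: SpacingPattern, b: SpacingPattern) -> float:
    """RMS dissimilarity between two spacing patterns.

    Equal-length patterns are compared element-wise.  Patterns whose
    lengths differ by one are aligned by dropping whichever terminal
    element of the longer minimizes the RMS difference.  A larger length
    difference makes the patterns incomparable (DataError): the records
    they summarize could not belong to one individual anyway.
    """
    pa, pb = np.asarray(a.positions), np.asarray(b.positions)
    if abs(len(pa) - len(pb)) > 1:
        raise DataError("patterns differ in length by more than one line")
    if len(pa) == len(pb):
        if len(pa) == 0:
            return 0.0
        return float(math.sqrt(np.mean((pa - pb) ** 2)))
    longer, shorter = (pa, pb) if len(pa) > len(pb) else (pb, pa)
    best = min(
        float(math.sqrt(np.mean((cand - shorter) ** 2))) if len(shorter) else 0.0
        for cand in (longer[1:], longer[:-1])
    )
    return best


def profile_column(column: Sequence[VertebraRecord],
                   label: Optional[str] = None) -> ColumnProfile:
    """Full stage-1 summary of one articulated column."""
    modal = modal_age_estimate(column)
    consensus = None
    if not modal.is_ambiguous:
        consensus = spacing_consensus(column)
    return ColumnProfile(
        counts=count_table(column),
        modal=modal,
        centrum=centrum_stats(column),
        spacing_consensus=consensus,
        label=label,
    )
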