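"""Human-readable text tables mirroring the published table layouts."""

from __future__ import annotations

from typing import Sequence, Union

from .fingerprint import MNIResult
from .profiling import ColumnProfile


def _fmt_len(x) -> str:
    return "-" if x is None else f"{x:g}"


def render_individuals_table(result: MNIResult) -> str:
    """One row per vertebra: lot, id, count, length, candidate labels.

    Candidate individual labels are rendered "2, 3"-style; numbering is
    deterministic, ascending by the youngest member of each candidate
    individual.
    """
    header = f"{'Lot':<14} {'Record':<12} {'LAGs':>4} {'Centrum (mm)':>12}  Individuals"
    lines = [header, "-" * len(header)]
    for lot in result.lots:
        for rid in sorted(lot.ambiguity):
            labels = ", ".join(str(l) for l in lot.ambiguity[rid])
            count, length = lot.nodes.get(rid, ("?", None))
            lines.append(f"{lot.lot_id:<14} {rid:<12} {count:>4} "
                         f"{_fmt_len(length):>12}  {labels}")
        for rid in lot.excluded:
            lines.append(f"{lot.lot_id:<14} {rid:<12} {'-':>4} {'-':>12}  unscorable")
        lines.append(f"{'':<14} {'':<12} {'':>4} {'':>12}  "
                     f"count: {lot.min_individuals}"
                     + (f", {lot.max_individuals}"
                        if lot.max_individuals != lot.min_individuals else ""))
    lines.append("-" * len(header))
    lines.append(f"Totals: min {result.total_min}, max {result.total_max}")
    return "\n".join(lines) + "\n"


def render_profile_table(profiles: Union[ColumnProfile, Sequence[ColumnProfile]]
                         ) -> str:
    """Species-table-shaped summary: tallies, integer percents, size stats."""
    if isinstance(profiles, ColumnProfile):
        profiles = [profiles]
    header = (f"{'Column':<26} {'Cat.':<9} {'Lines':>5} {'#':>5} {'%':>4}   "
              f"{'Mean CL (mm)':>12} {'sd (mm)':>8} {'sd (%)':>7}")
    lines = [header, "-" * len(header)]
    for prof in profiles:
        label = prof.label or "<column>"
        first = True
        for cat in ("left", "right", "combined"):
            tallies = prof.counts.tallies(cat)
            pcts = prof.counts.percents(cat)
            for c in sorted(tallies):
                if first and prof.centrum is not None:
                    stats = (f"{prof.centrum.mean_mm:>12.2f} "
                             f"{prof.centrum.sd_mm:>8.2f} "
                             f"{prof.centrum.cv_percent:>7.1f}")
                elif first:
                    stats = f"{'-':>12} {'-':>8} {'-':>7}"
                else:
                    stats = ""
                lines.append(f"{label if first else '':<26} {cat:<9} "
                             f"{c:>5} {tallies[c]:>5} {pcts[c]:>4}   {stats}")
                first = False
        modal = "/".join(str(c) for c in prof.modal.candidates)
        lines.append(f"{'':<26} modal {modal} "
                     f"(support {prof.modal.support:.3f})")
    return "\n".join(lines) + "\n"


def render_report(result) -> str:
    if isinstance(result, MNIResult):
        return render_individuals_table(result)
    if isinstance(result, ColumnProfile):
        return render_profile_table(result)
    if isinstance(result, dict):
        chunks = []
        for cv in sorted(result):
            chunks.append(f"== size envelope CV {cv}% ==\n"
                          + render_individuals_table(result[cv]))
        return "\n".join(chunks)
    raise TypeError(f"cannot render {type(result).__name__}")
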