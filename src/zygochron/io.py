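"""Readers and writers for vertebra-record tables and result reports.

One table dialect: comma-delimited UTF-8 text with a mandatory header and
"." as the decimal separator.  Normalized line positions are packed into a
single cell with ";" separators.  Absent numeric cells are absent — they
never silently become zero.
"""

from __future__ import annotations

import csv
import io as _io
import json
from importlib import resources
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .records import (
    Condition,
    CountTable,
    FormatError,
    RowError,
    Side,
    ValidationError,
    VertebraRecord,
    ZygantralRecord,
)

REQUIRED_COLUMNS = (
    "record_id", "lot_id",
    "left_count", "right_count",
    "left_condition", "right_condition",
)
OPTIONAL_COLUMNS = (
    "specimen_id", "centrum_length_mm", "column_position",
    "left_positions", "right_positions",
)

Source = Union[str, IO[str]]


def _cell(row: dict, key: str) -> str:
    val = row.get(key)
    return "" if val is None else str(val).strip()


def _parse_positions(raw: str, record_id: str, col: str) -> tuple[float, ...]:
    try:
        return tuple(float(p) for p in raw.split(";") if p.strip())
    except ValueError:
        raise RowError(record_id, f"unparseable positions in {col}: {raw!r}")


def _parse_zygantrum(row: dict, side: Side, record_id: str) -> ZygantralRecord:
    prefix = side.value
    raw_count = _cell(row, f"{prefix}_count")
    raw_cond = _cell(row, f"{prefix}_condition") or Condition.INTACT.value
    try:
        condition = Condition(raw_cond)
    except ValueError:
        raise RowError(record_id, f"unknown condition {raw_cond!r}")
    count = None
    if raw_count:
        try:
            count = int(raw_count)
        except ValueError:
            raise RowError(record_id, f"non-numeric count {raw_count!r}")
    positions = None
    raw_pos = _cell(row, f"{prefix}_positions")
    if raw_pos:
        positions = _parse_positions(raw_pos, record_id, f"{prefix}_positions")
    try:
        return ZygantralRecord(side=side, line_count=count,
                               line_positions=positions, condition=condition)
    except ValueError as exc:
        raise RowError(record_id, str(exc))


def read_vertebra_table(source: Source) -> list[VertebraRecord]:
    """Read a delimited vertebra table into records.

    ``source`` is a path or an open text stream.  Raises
    :class:`FormatError` when required header columns are missing,
    :class:`RowError` on unparseable cells, and :class:`ValidationError`
    on duplicate record ids.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_vertebra_table(fh)
    reader = csv.DictReader(source)
    header = reader.fieldnames or []
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"missing required columns: {', '.join(missing)}")

    records: list[VertebraRecord] = []
    seen: set[str] = set()
    for row in reader:
        record_id = _cell(row, "record_id")
        if not record_id:
            raise RowError("<blank>", "empty record_id")
        if record_id in seen:
            raise ValidationError(f"duplicate record_id {record_id!r}")
        seen.add(record_id)
        centrum = None
        raw_cl = _cell(row, "centrum_length_mm")
        if raw_cl:
            try:
                centrum = float(raw_cl)
            except ValueError:
                raise RowError(record_id, f"non-numeric centrum length {raw_cl!r}")
        colpos = None
        raw_cp = _cell(row, "column_position")
        if raw_cp:
            try:
                colpos = int(raw_cp)
            except ValueError:
                raise RowError(record_id, f"non-numeric column position {raw_cp!r}")
        records.append(VertebraRecord(
            record_id=record_id,
            lot_id=_cell(row, "lot_id"),
            specimen_id=_cell(row, "specimen_id") or None,
            column_position=colpos,
            centrum_length_mm=centrum,
            left=_parse_zygantrum(row, Side.LEFT, record_id),
            right=_parse_zygantrum(row, Side.RIGHT, record_id),
        ))
    return records


def write_vertebra_table(records: Sequence[VertebraRecord], sink: Source) -> None:
    """Write records in the same dialect ``read_vertebra_table`` accepts."""
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            write_vertebra_table(records, fh)
        return
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    writer = csv.DictWriter(sink, fieldnames=columns, lineterminator="\n")
    writer.writeheader()
    for v in records:
        row = {
            "record_id": v.record_id,
            "lot_id": v.lot_id,
            "specimen_id": v.specimen_id or "",
            "column_position": "" if v.column_position is None else v.column_position,
            "centrum_length_mm": ""
            if v.centrum_length_mm is None else repr(v.centrum_length_mm),
        }
        for side, z in (("left", v.left), ("right", v.right)):
            row[f"{side}_count"] = "" if z.line_count is None else z.line_count
            row[f"{side}_condition"] = z.condition.value
            row[f"{side}_positions"] = (
                "" if z.line_positions is None
                else ";".join(repr(p) for p in z.line_positions)
            )
        writer.writerow(row)


# ---------------------------------------------------------------------------
# Structured reports

def write_report(result, sink: Source, format: str = "structured") -> None:
    """Serialize an analysis result.

    ``structured`` emits a JSON document that round-trips through
    :func:`read_report`; ``tabular`` emits the human-readable text table.
    """
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            write_report(result, fh, format=format)
        return
    if format == "structured":
        json.dump(_report_dict(result), sink, indent=2, sort_keys=True)
        sink.write("\n")
    elif format == "tabular":
        from .render import render_report
        sink.write(render_report(result))
    else:
        raise ValueError(f"unknown format {format!r}")


def _report_dict(result) -> dict:
    from .fingerprint import MNIResult
    from .profiling import ColumnProfile
    if isinstance(result, MNIResult):
        return {"kind": "mni_result", "payload": result.to_dict()}
    if isinstance(result, ColumnProfile):
        return {"kind": "column_profile", "payload": result.to_dict()}
    if isinstance(result, dict):  # cv bracket: cv -> MNIResult
        return {"kind": "mni_bracket",
                "payload": {str(cv): r.to_dict() for cv, r in result.items()}}
    raise TypeError(f"cannot serialize {type(result).__name__}")


def read_report(source: Source):
    """Inverse of structured :func:`write_report`."""
    from .fingerprint import MNIResult
    from .profiling import ColumnProfile
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_report(fh)
    doc = json.load(source)
    kind = doc.get("kind")
    if kind == "mni_result":
        return MNIResult.from_dict(doc["payload"])
    if kind == "column_profile":
        return ColumnProfile.from_dict(doc["payload"])
    if kind == "mni_bracket":
        return {float(cv): MNIResult.from_dict(d)
                for cv, d in doc["payload"].items()}
    raise FormatError(f"unknown report kind {kind!r}")


# ---------------------------------------------------------------------------
# Packaged fixtures (the published tables, re-keyed as delimited text)

def _data_text(name: str) -> str:
    return resources.files("zygochron.data").joinpath(name).read_text("utf-8")


def load_boavus_table() -> list[VertebraRecord]:
    """The 12 isolated fossil vertebrae (two museum lots)."""
    return read_vertebra_table(_io.StringIO(_data_text("table2_boavus.csv")))


def load_extant_count_tables() -> dict[str, CountTable]:
    """Published per-species line-count tallies, keyed by species.

    The returned :class:`CountTable` objects hold the printed integer
    tallies; the printed percentages are available separately from
    :func:`load_extant_percents` for cross-checking.
    """
    df = pd.read_csv(_io.StringIO(_data_text("table1_counts.csv")))
    tables: dict[str, CountTable] = {}
    for species, grp in df.groupby("species", sort=False):
        sides = {"left": {}, "right": {}, "combined": {}}
        for _, row in grp.iterrows():
            sides[row["side"]][int(row["line_count"])] = int(row["tally"])
        tables[species] = CountTable(**sides)
    return tables


def load_extant_percents() -> dict[str, dict[str, dict[int, int]]]:
    """Published integer percentages: species -> category -> count -> %."""
    df = pd.read_csv(_io.StringIO(_data_text("table1_counts.csv")))
    out: dict[str, dict[str, dict[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["species"], {}).setdefault(row["side"], {})[
            int(row["line_count"])] = int(row["percent"])
    return out


def load_extant_centrum_stats() -> pd.DataFrame:
    """Published centrum-length mean, sd and sd%% per extant species."""
    return pd.read_csv(_io.StringIO(_data_text("table1_centrum.csv")),
                       index_col="species")
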