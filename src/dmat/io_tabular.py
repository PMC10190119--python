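"""Flat-file (CSV) serialisation of assessment records and scores.

The layout flattens the two-level spreadsheet headers of the data-entry
workbook to one snake_case header row: record metadata and the room-level
odor columns first, then seven columns per room component
(``<component>_present``, three factor-score columns,
``<component>_near_exterior``, ``<component>_nothing_found``,
``<component>_note``), then free-text assessment notes and a schema
version column.

Cell conventions on **read** follow the data-entry sheet:

* an empty ``<component>_present`` cell means the component does not
  exist in the room and contributes no observation;
* an empty factor-score cell on a *present* component decodes to 0;
* the mold-odor score cell must be non-empty (no odor is entered as
  ``0``, never left blank);
* any factor entry on a component that is not marked present is a
  violation.

On **write** zeros are always emitted explicitly so that a written file
never relies on the blank-means-zero rule, and rows are sorted by
(building, room, date, observer) so output is byte-deterministic.
Unknown columns are tolerated and ignored on read.
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path
from typing import Iterable, Sequence

from .datamodel import (
    Component,
    ComponentObservation,
    Factor,
    OdorIntensity,
    OdorObservation,
    RoomAssessment,
    Violation,
    validate_assessment,
)
from .scoring import RoomScores

__all__ = [
    "SCHEMA_VERSION",
    "ASSESSMENT_COLUMNS",
    "SCORE_COLUMNS",
    "read_assessments",
    "write_assessments",
    "write_scores",
    "write_assessments_xlsx",
]

SCHEMA_VERSION = "dmat-csv-1"

_FACTOR_SUFFIX: dict[Factor, str] = {
    Factor.WATER_DAMAGE_STAINS: "damage_stain",
    Factor.VISIBLE_MOLD: "visible_mold",
    Factor.WET_DAMP: "wet_damp",
}

_META_COLUMNS = [
    "building_id",
    "room_id",
    "date",
    "observer_id",
    "floor_level",
    "room_type",
    "odor_intensity",
    "odor_score",
    "odor_source",
    "odor_source_unknown",
]


def _component_columns(c: Component) -> list[str]:
    return [
        f"{c.value}_present",
        f"{c.value}_damage_stain",
        f"{c.value}_visible_mold",
        f"{c.value}_wet_damp",
        f"{c.value}_near_exterior",
        f"{c.value}_nothing_found",
        f"{c.value}_note",
    ]


#: The fixed, versioned header for assessment CSV files.
ASSESSMENT_COLUMNS: list[str] = (
    _META_COLUMNS
    + [col for c in Component for col in _component_columns(c)]
    + ["assessment_notes", "schema_version"]
)

#: Header for derived room-score CSV files.
SCORE_COLUMNS: list[str] = (
    ["building_id", "room_id", "date", "observer_id"]
    + [f"{c.value}_total" for c in Component]
    + ["room_total"]
    + [f"{_FACTOR_SUFFIX[f]}_avg" for f in Factor]
    + ["room_average", "odor_score", "n_components", "color_band"]
)

_TRUE_CELLS = {"1", "true", "yes", "x"}
_FALSE_CELLS = {"", "0", "false", "no"}


def _parse_flag(cell: str) -> bool | None:
    cell = cell.strip().lower()
    if cell in _TRUE_CELLS:
        return True
    if cell in _FALSE_CELLS:
        return False
    return None


def read_assessments(
    path: str | Path,
) -> tuple[list[RoomAssessment], list[tuple[int, Violation]]]:
    """Read assessment records from a CSV file.

    Returns ``(records, report)`` where *report* is a list of
    ``(row_number, Violation)`` pairs covering both cell-convention
    problems found while parsing and model-invariant violations in the
    parsed records.  Row numbers are 1-based data-row indices.  A row
    whose mandatory cells cannot be parsed is reported and skipped;
    missing mandatory header columns raise :class:`ValueError`.
    """
    path = Path(path)
    records: list[RoomAssessment] = []
    report: list[tuple[int, Violation]] = []

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ASSESSMENT_COLUMNS if c not in header and c != "schema_version"]
        if missing:
            raise ValueError(f"missing mandatory columns in {path.name}: {missing}")

        for row_no, row in enumerate(reader, start=1):
            record, row_violations = _parse_row(row)
            report.extend((row_no, v) for v in row_violations)
            if record is not None:
                records.append(record)
                report.extend((row_no, v) for v in validate_assessment(record))

    return records, report


def _parse_row(
    row: dict[str, str],
) -> tuple[RoomAssessment | None, list[Violation]]:
    v: list[Violation] = []

    def cell(name: str) -> str:
        return (row.get(name) or "").strip()

    def text_cell(name: str) -> str:
        # Free text is carried verbatim; only structured cells are stripped.
        return row.get(name) or ""

    date_text = cell("date")
    try:
        date = _dt.date.fromisoformat(date_text)
    except ValueError:
        v.append(
            Violation(
                code="bad_date",
                path="date",
                message=f"date must be ISO-8601 (YYYY-MM-DD), got {date_text!r}",
            )
        )
        return None, v

    odor_cell = cell("odor_score")
    if odor_cell == "":
        v.append(
            Violation(
                code="odor_score_missing",
                path="odor_score",
                message="mold-odor score must be entered; no odor is entered as '0'",
            )
        )
        return None, v
    try:
        odor_score = int(odor_cell)
        intensity = OdorIntensity.from_score(odor_score)
    except ValueError:
        v.append(
            Violation(
                code="bad_odor_score",
                path="odor_score",
                message=f"odor score must be an integer 0-3, got {odor_cell!r}",
            )
        )
        return None, v

    intensity_cell = cell("odor_intensity")
    if intensity_cell:
        try:
            named = OdorIntensity(intensity_cell.lower())
        except ValueError:
            named = None
            v.append(
                Violation(
                    code="bad_odor_intensity",
                    path="odor_intensity",
                    message=f"unknown odor intensity {intensity_cell!r}",
                )
            )
        if named is not None and named is not intensity:
            v.append(
                Violation(
                    code="odor_intensity_score_mismatch",
                    path="odor_intensity",
                    message=(
                        f"odor intensity {named.value!r} does not match "
                        f"score {odor_score}"
                    ),
                )
            )

    source_unknown = _parse_flag(cell("odor_source_unknown"))
    if source_unknown is None:
        v.append(
            Violation(
                code="bad_flag",
                path="odor_source_unknown",
                message=f"cannot interpret {cell('odor_source_unknown')!r} as a checkbox",
            )
        )
        source_unknown = False

    odor = OdorObservation(
        intensity=intensity,
        source_description=text_cell("odor_source"),
        source_unknown=source_unknown,
    )

    observations: list[ComponentObservation] = []
    for component in Component:
        present_cell = cell(f"{component.value}_present")
        present = _parse_flag(present_cell)
        if present is None:
            v.append(
                Violation(
                    code="bad_present_flag",
                    path=f"{component.value}_present",
                    message=(
                        f"component-present cell must be '1' or empty, "
                        f"got {present_cell!r}"
                    ),
                )
            )
            present = False

        scores: dict[Factor, int] = {}
        for factor in Factor:
            col = f"{component.value}_{_FACTOR_SUFFIX[factor]}"
            raw = cell(col)
            if not present:
                if raw != "":
                    v.append(
                        Violation(
                            code="score_on_absent_component",
                            path=col,
                            message=(
                                f"factor score entered for {component.value!r} "
                                "which is not marked present"
                            ),
                        )
                    )
                scores[factor] = 0
                continue
            if raw == "":
                scores[factor] = 0  # blank means assessed as zero
                continue
            try:
                scores[factor] = int(raw)
            except ValueError:
                v.append(
                    Violation(
                        code="bad_score",
                        path=col,
                        message=f"score must be an integer 0-3, got {raw!r}",
                    )
                )
                scores[factor] = 0

        if not present:
            continue

        near = _parse_flag(cell(f"{component.value}_near_exterior"))
        nothing = _parse_flag(cell(f"{component.value}_nothing_found"))
        for flag, name in ((near, "near_exterior"), (nothing, "nothing_found")):
            if flag is None:
                v.append(
                    Violation(
                        code="bad_flag",
                        path=f"{component.value}_{name}",
                        message="cannot interpret checkbox cell",
                    )
                )
        observations.append(
            ComponentObservation(
                component=component,
                damage_stain=scores[Factor.WATER_DAMAGE_STAINS],
                visible_mold=scores[Factor.VISIBLE_MOLD],
                wet_damp=scores[Factor.WET_DAMP],
                near_exterior_wall=bool(near),
                nothing_found=bool(nothing),
                component_note=text_cell(f"{component.value}_note"),
            )
        )

    record = RoomAssessment(
        building_id=cell("building_id"),
        room_id=cell("room_id"),
        assessment_date=date,
        observer_id=cell("observer_id"),
        floor_level=cell("floor_level"),
        room_type=cell("room_type"),
        odor=odor,
        observations=tuple(observations),
        assessment_notes=text_cell("assessment_notes"),
    )
    return record, v


def _record_sort_key(r: RoomAssessment) -> tuple[str, str, str, str]:
    return (r.building_id, r.room_id, r.assessment_date.isoformat(), r.observer_id)


def _record_to_row(record: RoomAssessment) -> dict[str, str]:
    row: dict[str, str] = {c: "" for c in ASSESSMENT_COLUMNS}
    row.update(
        building_id=record.building_id,
        room_id=record.room_id,
        date=record.assessment_date.isoformat(),
        observer_id=record.observer_id,
        floor_level=record.floor_level,
        room_type=record.room_type,
        odor_intensity=record.odor.intensity.value,
        odor_score=str(record.odor.score),
        odor_source=record.odor.source_description,
        odor_source_unknown="1" if record.odor.source_unknown else "0",
        assessment_notes=record.assessment_notes,
        schema_version=SCHEMA_VERSION,
    )
    for obs in record.observations:
        c = obs.component.value
        row[f"{c}_present"] = "1"
        row[f"{c}_damage_stain"] = str(obs.damage_stain)
        row[f"{c}_visible_mold"] = str(obs.visible_mold)
        row[f"{c}_wet_damp"] = str(obs.wet_damp)
        row[f"{c}_near_exterior"] = "1" if obs.near_exterior_wall else "0"
        row[f"{c}_nothing_found"] = "1" if obs.nothing_found else "0"
        row[f"{c}_note"] = obs.component_note
    return row


def write_assessments(records: Iterable[RoomAssessment], path: str | Path) -> None:
    """Write records to CSV with the fixed header and deterministic order.

    Rows are sorted by (building, room, date, observer); zeros are
    written explicitly so "assessed as 0" is never confused with "not
    assessed".
    """
    path = Path(path)
    ordered = sorted(records, key=_record_sort_key)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=ASSESSMENT_COLUMNS)
        writer.writeheader()
        for record in ordered:
            writer.writerow(_record_to_row(record))


def write_scores(scores: Iterable[RoomScores], path: str | Path) -> None:
    """Write derived room scores to CSV (averages to 6 decimal places)."""
    path = Path(path)
    ordered = sorted(
        scores, key=lambda s: (s.building_id, s.room_id, s.assessment_date, s.observer_id)
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=SCORE_COLUMNS)
        writer.writeheader()
        for s in ordered:
            row: dict[str, str] = {
                "building_id": s.building_id,
                "room_id": s.room_id,
                "date": s.assessment_date,
                "observer_id": s.observer_id,
                "room_total": str(s.room_total),
                "room_average": f"{s.room_average:.6f}",
                "odor_score": str(s.odor_score),
                "n_components": str(s.n_components),
                "color_band": s.color_band.value,
            }
            for c in Component:
                row[f"{c.value}_total"] = (
                    str(s.component_totals[c]) if c in s.component_totals else ""
                )
            for f in Factor:
                row[f"{_FACTOR_SUFFIX[f]}_avg"] = f"{s.factor_averages[f]:.6f}"
            writer.writerow(row)


def write_assessments_xlsx(records: Iterable[RoomAssessment], path: str | Path) -> None:
    """Convenience Excel export mirroring the two-level data-entry layout.

    Row 1 carries the group headers (component names spanning their
    columns); row 2 the per-column labels; data rows follow the same cell
    conventions as the CSV writer.
    """
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "assessments"

    top: list[str] = []
    for col in ASSESSMENT_COLUMNS:
        group = ""
        for c in Component:
            if col.startswith(c.value + "_"):
                group = c.value.replace("_", " ")
                break
        if col.startswith("odor_"):
            group = "mold odor"
        top.append(group)
    ws.append(top)
    ws.append(ASSESSMENT_COLUMNS)
    for record in sorted(records, key=_record_sort_key):
        row = _record_to_row(record)
        ws.append([row[c] for c in ASSESSMENT_COLUMNS])
    wb.save(Path(path))
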