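"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from dmat import (
    Component,
    ComponentObservation,
    OdorIntensity,
    OdorObservation,
    RoomAssessment,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"

_IDENT = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=6)
_NOTE = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz ,.-\"'", max_size=20
)
_OPTIONAL = sorted(
    set(Component) - {Component.CEILING, Component.WALLS, Component.FLOOR},
    key=lambda c: c.value,
)


@st.composite
def component_observations(draw, component: Component) -> ComponentObservation:
    scores = draw(
        st.tuples(
            st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)
        )
    )
    any_damage = any(s > 0 for s in scores)
    return ComponentObservation(
        component=component,
        damage_stain=scores[0],
        visible_mold=scores[1],
        wet_damp=scores[2],
        near_exterior_wall=draw(st.booleans()) if any_damage else False,
        nothing_found=not any_damage,
        component_note=draw(_NOTE),
    )


@st.composite
def odor_observations(draw) -> OdorObservation:
    intensity = draw(st.sampled_from(list(OdorIntensity)))
    unknown = draw(st.booleans()) if intensity is not OdorIntensity.NONE else False
    return OdorObservation(
        intensity=intensity,
        source_description=draw(_NOTE) if intensity is not OdorIntensity.NONE else "",
        source_unknown=unknown,
    )


@st.composite
def room_assessments(draw) -> RoomAssessment:
    """Random valid assessment records (pass validation with no errors)."""
    extras = draw(st.lists(st.sampled_from(_OPTIONAL), unique=True, max_size=5))
    components = [Component.CEILING, Component.WALLS, Component.FLOOR, *extras]
    components.sort(key=lambda c: list(Component).index(c))
    return RoomAssessment(
        building_id=draw(_IDENT),
        room_id=draw(_IDENT),
        assessment_date=draw(
            st.dates(min_value=dt.date(2020, 1, 1), max_value=dt.date(2030, 12, 31))
        ),
        observer_id=draw(_IDENT),
        floor_level=draw(st.sampled_from(["B", "1", "2", "3"])),
        room_type=draw(st.sampled_from(["classroom", "office", "gym", "storage"])),
        odor=draw(odor_observations()),
        observations=tuple(draw(component_observations(c)) for c in components),
        assessment_notes=draw(_NOTE),
    )


@st.composite
def campaigns(draw, min_rooms=1, max_rooms=8) -> list[RoomAssessment]:
    """A small campaign of rooms with unique keys and one shared date."""
    n = draw(st.integers(min_rooms, max_rooms))
    date = draw(st.dates(min_value=dt.date(2022, 1, 1), max_value=dt.date(2026, 1, 1)))
    rooms = []
    for i in range(n):
        rec = draw(room_assessments())
        rooms.append(
            RoomAssessment(
                building_id="B01",
                room_id=f"R{i + 1:03d}",
                assessment_date=date,
                observer_id="OBS1",
                floor_level=rec.floor_level,
                room_type=rec.room_type,
                odor=rec.odor,
                observations=rec.observations,
                assessment_notes=rec.assessment_notes,
            )
        )
    return rooms


@pytest.fixture
def two_room_records() -> list[RoomAssessment]:
    """The worked two-room example: one damaged classroom, one clean office.

    Hand computation for R101 (components ceiling, walls, floor,
    windows; odor mild = 1):

    * component totals: ceiling 2, walls 1+1=2, floor 0, windows 1
    * room total = 2+2+0+1 + 1 = 6 (yellow)
    * factor averages over 4 components: stains 3/4, mold 1/4, wet 1/4
    * room average = 0.75+0.25+0.25 + 1 = 2.25

    R102 is all-clear: total 0, band none.
    """
    r1 = RoomAssessment(
        building_id="B01",
        room_id="R101",
        assessment_date=dt.date(2024, 5, 1),
        observer_id="OBS1",
        floor_level="1",
        room_type="classroom",
        odor=OdorObservation(intensity=OdorIntensity.MILD, source_unknown=True),
        observations=(
            ComponentObservation(
                Component.CEILING,
                damage_stain=2,
                near_exterior_wall=True,
                component_note="acoustic tile",
            ),
            ComponentObservation(Component.WALLS, damage_stain=1, visible_mold=1),
            ComponentObservation(Component.FLOOR, nothing_found=True),
            ComponentObservation(
                Component.WINDOWS, wet_damp=1, component_note="condensation on sill"
            ),
        ),
        assessment_notes="stain under roof joint",
    )
    r2 = RoomAssessment(
        building_id="B01",
        room_id="R102",
        assessment_date=dt.date(2024, 5, 1),
        observer_id="OBS1",
        floor_level="1",
        room_type="office",
        odor=OdorObservation(),
        observations=(
            ComponentObservation(Component.CEILING, nothing_found=True),
            ComponentObservation(Component.WALLS, nothing_found=True),
            ComponentObservation(Component.FLOOR, nothing_found=True),
        ),
    )
    return [r1, r2]
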