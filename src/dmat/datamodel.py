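"""Typed data model for observational dampness/mold assessment records.

The assessment instrument records four dampness/mold-related factors for a
room or area: mold odor (judged at room level by intensity) and, for each
room component that exists in the room, water damage/stains, visible mold
and the presence of wet or damp materials, each on a semi-quantitative
0-3 scale.  Eight room components are recognised: ceiling, walls, floor,
windows, furnishings, the HVAC system, supplies/materials and pipes.
The ceiling, walls and floor are the basic components of an enclosed room
and are expected to be present in every assessment.

Records are plain frozen dataclasses.  Validation never raises on bad
field combinations: :func:`validate_assessment` returns every invariant
violation as data so that batch imports can report all problems at once.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Component",
    "Factor",
    "OdorIntensity",
    "BASIC_COMPONENTS",
    "SCORE_VALUES",
    "OdorObservation",
    "ComponentObservation",
    "RoomAssessment",
    "Violation",
    "validate_assessment",
    "room_key",
]


class Component(str, enum.Enum):
    """The eight recognised room components."""

    CEILING = "ceiling"
    WALLS = "walls"
    FLOOR = "floor"
    WINDOWS = "windows"
    FURNISHINGS = "furnishings"
    HVAC = "hvac"
    SUPPLIES_MATERIALS = "supplies_materials"
    PIPES = "pipes"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Components assumed present in every enclosed room.
BASIC_COMPONENTS: frozenset[Component] = frozenset(
    {Component.CEILING, Component.WALLS, Component.FLOOR}
)


class Factor(str, enum.Enum):
    """The three component-level dampness/mold factors.

    Mold odor is assessed once per room, not per component, and is
    therefore represented separately (see :class:`OdorObservation`).
    """

    WATER_DAMAGE_STAINS = "water_damage_stains"
    VISIBLE_MOLD = "visible_mold"
    WET_DAMP = "wet_damp"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Valid ordinal damage scores.  0 means no damage observed.
SCORE_VALUES: tuple[int, ...] = (0, 1, 2, 3)


class OdorIntensity(str, enum.Enum):
    """Judged intensity of mold odor; maps one-to-one onto scores 0-3."""

    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    STRONG = "strong"

    @property
    def score(self) -> int:
        return _ODOR_SCORES[self]

    @classmethod
    def from_score(cls, score: int) -> "OdorIntensity":
        for intensity, s in _ODOR_SCORES.items():
            if s == score:
                return intensity
        raise ValueError(f"odor score must be one of {SCORE_VALUES}, got {score!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_ODOR_SCORES: dict[OdorIntensity, int] = {
    OdorIntensity.NONE: 0,
    OdorIntensity.MILD: 1,
    OdorIntensity.MODERATE: 2,
    OdorIntensity.STRONG: 3,
}


@dataclass(frozen=True)
class OdorObservation:
    """Room-level mold odor finding.

    ``source_unknown`` marks odor whose source could not be located,
    which may indicate hidden mold; it is meaningful only when odor was
    actually smelled (intensity above ``none``).
    """

    intensity: OdorIntensity = OdorIntensity.NONE
    source_description: str = ""
    source_unknown: bool = False

    @property
    def score(self) -> int:
        """Ordinal odor score: none=0, mild=1, moderate=2, strong=3."""
        return self.intensity.score


@dataclass(frozen=True)
class ComponentObservation:
    """Scores and flags for one existing room component.

    ``nothing_found`` is the form's shortcut for "all three factors are
    zero"; ``near_exterior_wall`` qualifies observed damage as lying
    within three feet of an exterior wall, so it is meaningful only when
    at least one factor score is non-zero.
    """

    component: Component
    damage_stain: int = 0
    visible_mold: int = 0
    wet_damp: int = 0
    near_exterior_wall: bool = False
    nothing_found: bool = False
    component_note: str = ""

    def factor_score(self, factor: Factor) -> int:
        return {
            Factor.WATER_DAMAGE_STAINS: self.damage_stain,
            Factor.VISIBLE_MOLD: self.visible_mold,
            Factor.WET_DAMP: self.wet_damp,
        }[factor]

    @property
    def factor_scores(self) -> dict[Factor, int]:
        return {f: self.factor_score(f) for f in Factor}


@dataclass(frozen=True)
class RoomAssessment:
    """One visit to one room/area by one observer on one date."""

    building_id: str
    room_id: str
    assessment_date: _dt.date
    observer_id: str = ""
    floor_level: str = ""
    room_type: str = ""
    odor: OdorObservation = field(default_factory=OdorObservation)
    observations: tuple[ComponentObservation, ...] = ()
    assessment_notes: str = ""

    def __post_init__(self) -> None:
        # Normalise to a tuple so records hash and compare by value.
        object.__setattr__(self, "observations", tuple(self.observations))

    @property
    def components(self) -> tuple[Component, ...]:
        """Components that exist (and were assessed) in this room."""
        return tuple(o.component for o in self.observations)

    def observation(self, component: Component) -> ComponentObservation | None:
        for o in self.observations:
            if o.component == component:
                return o
        return None

    def with_observer(self, observer_id: str) -> "RoomAssessment":
        return replace(self, observer_id=observer_id)


def room_key(record: RoomAssessment) -> tuple[str, str]:
    """Key identifying a room across campaigns: (building_id, room_id)."""
    return (record.building_id, record.room_id)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found in a record.

    ``severity`` is ``"error"`` for hard invariant breaks and
    ``"warning"`` for advisory findings (e.g. an unlisted school room
    type); violations are returned, never raised.
    """

    code: str
    path: str
    message: str
    severity: str = "error"


def _check_score(violations: list[Violation], path: str, value: int) -> None:
    if value not in SCORE_VALUES:
        violations.append(
            Violation(
                code="score_out_of_range",
                path=path,
                message=f"score must be one of {SCORE_VALUES}, got {value!r}",
            )
        )


def validate_assessment(
    record: RoomAssessment,
    school_room_types: Iterable[str] | None = None,
) -> list[Violation]:
    """Validate one assessment record against every model invariant.

    Returns the (possibly empty) list of violations; an empty list means
    the record is valid.  Validation is pure and idempotent.  When
    ``school_room_types`` is given, a room type outside that controlled
    list yields a *warning*, never an error.
    """
    v: list[Violation] = []

    # Odor invariants.
    _check_score(v, "odor.score", record.odor.score)
    if record.odor.source_unknown and record.odor.intensity == OdorIntensity.NONE:
        v.append(
            Violation(
                code="odor_source_unknown_without_odor",
                path="odor.source_unknown",
                message="'source unknown' may be checked only when odor was smelled",
            )
        )

    # Component observations.
    seen: set[Component] = set()
    for i, obs in enumerate(record.observations):
        prefix = f"observations[{i}]"
        if obs.component in seen:
            v.append(
                Violation(
                    code="duplicate_component",
                    path=f"{prefix}.component",
                    message=f"duplicate component {obs.component.value!r}",
                )
            )
        seen.add(obs.component)

        for factor in Factor:
            _check_score(v, f"{prefix}.{factor.value}", obs.factor_score(factor))

        any_damage = any(obs.factor_score(f) > 0 for f in Factor)
        if obs.nothing_found and any_damage:
            v.append(
                Violation(
                    code="nothing_found_with_damage",
                    path=f"{prefix}.nothing_found",
                    message=(
                        f"'nothing found' checked on {obs.component.value!r} "
                        "but a factor score is non-zero"
                    ),
                )
            )
        if obs.near_exterior_wall and not any_damage:
            v.append(
                Violation(
                    code="near_exterior_without_damage",
                    path=f"{prefix}.near_exterior_wall",
                    message=(
                        f"'near exterior wall' checked on {obs.component.value!r} "
                        "but no damage was scored"
                    ),
                )
            )

    if not record.observations:
        v.append(
            Violation(
                code="no_components",
                path="observations",
                message="a room must have at least one existing component",
            )
        )
    else:
        missing_basic = BASIC_COMPONENTS - seen
        for component in sorted(missing_basic, key=lambda c: c.value):
            v.append(
                Violation(
                    code="missing_basic_component",
                    path="observations",
                    message=(
                        f"basic component {component.value!r} is expected in "
                        "every enclosed room"
                    ),
                    severity="warning",
                )
            )

    if school_room_types is not None and record.room_type:
        allowed = {t.strip().lower() for t in school_room_types}
        if record.room_type.strip().lower() not in allowed:
            v.append(
                Violation(
                    code="unlisted_room_type",
                    path="room_type",
                    message=f"room type {record.room_type!r} is not on the school form",
                    severity="warning",
                )
            )

    return v


def validate_campaign(
    records: Sequence[RoomAssessment],
    school_room_types: Iterable[str] | None = None,
) -> dict[tuple[str, str, str, str], list[Violation]]:
    """Validate many records; also flags duplicate record keys.

    Returns a map from record key (building, room, date, observer) to its
    violations; only keys with at least one violation appear.
    """
    out: dict[tuple[str, str, str, str], list[Violation]] = {}
    seen: set[tuple[str, str, str, str]] = set()
    for rec in records:
        key = (
            rec.building_id,
            rec.room_id,
            rec.assessment_date.isoformat(),
            rec.observer_id,
        )
        violations = validate_assessment(rec, school_room_types)
        if key in seen:
            violations = violations + [
                Violation(
                    code="duplicate_record_key",
                    path="",
                    message=f"duplicate record key {key!r}",
                )
            ]
        seen.add(key)
        if violations:
            out[key] = violations
    return out
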