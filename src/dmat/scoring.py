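"""Scoring rules: damage-size thresholds, room summary scores, color bands.

Each component-level factor is scored 0-3 by the combined size of all
damage patches on that component.  The reference sizes are everyday
objects: a sheet of standard paper (8.5 x 11 in) separates score 1 from
score 2, and a standard interior door (32 x 80 in) separates score 2
from score 3.

Room-level summaries:

* component total      = damage/stain + visible mold + wet/damp (0-9)
* room total           = sum of component totals + mold-odor score
* factor average       = factor scores summed over *existing* components,
                         divided by the number of existing components
* room average         = sum of the three factor averages + odor score

The odor score is added undivided to both the room total and the room
average — odor is judged once per room, so it is never spread over
components.

For floor-map display, room totals are banded: 1-2 green (low), 3-6
yellow (medium), 7+ red (high).  A total of 0 falls outside the printed
bands; it is reported as the explicit band ``none`` rather than being
folded into green.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .datamodel import (
    Component,
    ComponentObservation,
    Factor,
    RoomAssessment,
)

__all__ = [
    "PAPER_SHEET_AREA_IN2",
    "INTERIOR_DOOR_AREA_IN2",
    "ColorBand",
    "RoomScores",
    "size_to_score",
    "component_total",
    "room_total",
    "factor_average",
    "room_average",
    "classify_room",
    "score_room",
]

#: Combined damaged area of a standard sheet of paper, 8.5 x 11 inches.
PAPER_SHEET_AREA_IN2: float = 8.5 * 11.0  # 93.5 in^2

#: Combined damaged area of a standard interior door, 32 x 80 inches.
INTERIOR_DOOR_AREA_IN2: float = 32.0 * 80.0  # 2560 in^2


class ColorBand(str, enum.Enum):
    """Floor-map classification of a room total score."""

    NONE = "none"
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def size_to_score(combined_damaged_area_in2: float) -> int:
    """Map a combined damaged area (square inches) to an ordinal score.

    The area is the combined size of all damage patches on one
    component.  Zero area scores 0; areas up to a paper sheet score 1;
    up to an interior door score 2; larger areas score 3.  Areas exactly
    at a threshold take the lower score (the instrument's wording leaves
    exact equality unassigned; the lower closed interval is this
    package's fixed convention).

    This is a helper for training and for synthetic data; observers
    normally judge and record the ordinal score directly.
    """
    area = float(combined_damaged_area_in2)
    if math.isnan(area) or area < 0:
        raise ValueError(f"damaged area must be >= 0, got {combined_damaged_area_in2!r}")
    if area == 0:
        return 0
    if area <= PAPER_SHEET_AREA_IN2:
        return 1
    if area <= INTERIOR_DOOR_AREA_IN2:
        return 2
    return 3


def component_total(obs: ComponentObservation) -> int:
    """Sum of the three factor scores for one component (0-9)."""
    return obs.damage_stain + obs.visible_mold + obs.wet_damp


def room_total(record: RoomAssessment) -> int:
    """Sum of all component totals plus the mold-odor score."""
    return sum(component_total(o) for o in record.observations) + record.odor.score


def factor_average(record: RoomAssessment, factor: Factor) -> float:
    """Mean of one factor's scores over the room's existing components.

    Components that do not exist in the room are excluded from both the
    numerator and the denominator.
    """
    if not record.observations:
        raise ValueError("factor_average requires at least one existing component")
    scores = [o.factor_score(factor) for o in record.observations]
    return sum(scores) / len(scores)


def room_average(record: RoomAssessment) -> float:
    """Sum of the three factor averages plus the mold-odor score."""
    return sum(factor_average(record, f) for f in Factor) + record.odor.score


def classify_room(total: int) -> ColorBand:
    """Band a room total for floor-map display.

    0 -> none, 1-2 -> green, 3-6 -> yellow, >=7 -> red.
    """
    if total < 0:
        raise ValueError(f"room total must be >= 0, got {total!r}")
    if total == 0:
        return ColorBand.NONE
    if total <= 2:
        return ColorBand.GREEN
    if total <= 6:
        return ColorBand.YELLOW
    return ColorBand.RED


@dataclass(frozen=True)
class RoomScores:
    """All derived summary scores for one assessed room.

    Satisfies, by construction:

    * ``room_total == sum(component_totals.values()) + odor_score``
    * ``factor_averages[f] * n_components == sum of f's scores``
    * ``room_average == sum(factor_averages.values()) + odor_score``
    * ``room_average - odor_score == (room_total - odor_score) / n_components``
    """

    building_id: str
    room_id: str
    assessment_date: str
    observer_id: str
    component_totals: dict[Component, int]
    room_total: int
    factor_averages: dict[Factor, float]
    room_average: float
    odor_score: int
    n_components: int
    color_band: ColorBand


def score_room(record: RoomAssessment) -> RoomScores:
    """Compute every room-level summary score for one record."""
    totals = {o.component: component_total(o) for o in record.observations}
    total = room_total(record)
    averages = {f: factor_average(record, f) for f in Factor}
    return RoomScores(
        building_id=record.building_id,
        room_id=record.room_id,
        assessment_date=record.assessment_date.isoformat(),
        observer_id=record.observer_id,
        component_totals=totals,
        room_total=total,
        factor_averages=averages,
        room_average=room_average(record),
        odor_score=record.odor.score,
        n_components=len(record.observations),
        color_band=classify_room(total),
    )
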