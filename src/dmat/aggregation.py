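"""Building/school-level summaries over a campaign of room assessments.

A *campaign* is a set of room assessments within one building, school or
district survey.  The summaries here mirror the analyses an industrial
hygiene team runs after data entry: non-zero score frequencies by
component, component-specific school averages, school average scores
with median dichotomization for epidemiologic grouping, and color-band
tables for floor maps.

When the same room was assessed more than once within a campaign, the
latest assessment is used here; earlier visits remain available to the
longitudinal comparison.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .datamodel import Component, Factor, RoomAssessment, room_key
from .scoring import ColorBand, classify_room, component_total, room_total

__all__ = [
    "MOLD_ODOR",
    "CampaignSummary",
    "latest_assessments",
    "score_frequency",
    "component_school_average",
    "school_average_score",
    "dichotomize_by_median",
    "band_rooms",
    "factor_prevalence",
    "summarize_campaign",
]

#: Sentinel naming the room-level mold-odor "factor" in aggregate maps.
MOLD_ODOR = "mold_odor"

FactorLike = Factor | str


def latest_assessments(records: Iterable[RoomAssessment]) -> list[RoomAssessment]:
    """Keep the latest assessment of each room, sorted by room key.

    Ties on date (e.g. two observers on the same day) keep the record
    with the lexicographically greatest observer id, so the choice is
    deterministic.
    """
    best: dict[tuple[str, str], RoomAssessment] = {}
    for rec in records:
        key = room_key(rec)
        cur = best.get(key)
        if cur is None or (rec.assessment_date, rec.observer_id) >= (
            cur.assessment_date,
            cur.observer_id,
        ):
            best[key] = rec
    return [best[k] for k in sorted(best)]


def _room_factor_score(rec: RoomAssessment, factor: FactorLike) -> int:
    """Room-level score for a factor: max over components, or the odor score."""
    if factor == MOLD_ODOR:
        return rec.odor.score
    f = Factor(factor)
    return max((o.factor_score(f) for o in rec.observations), default=0)


def score_frequency(
    records: Sequence[RoomAssessment], factor: FactorLike
) -> dict[tuple[Component | None, int], int]:
    """Count rooms carrying each non-zero score of a factor, by component.

    For the three component-level factors the keys are
    ``(component, score)`` with score in 1-3.  Mold odor is judged at
    room level, so its counts are keyed ``(None, score)``.  Zero scores
    are never counted; components or scores with no occurrences are
    absent from the map.
    """
    rooms = latest_assessments(records)
    counts: dict[tuple[Component | None, int], int] = {}
    if factor == MOLD_ODOR:
        for rec in rooms:
            s = rec.odor.score
            if s > 0:
                counts[(None, s)] = counts.get((None, s), 0) + 1
        return counts
    f = Factor(factor)
    for rec in rooms:
        for obs in rec.observations:
            s = obs.factor_score(f)
            if s > 0:
                key = (obs.component, s)
                counts[key] = counts.get(key, 0) + 1
    return counts


def component_school_average(
    records: Sequence[RoomAssessment], component: Component
) -> float:
    """Component-specific school average score.

    The component totals are summed over *all* assessed rooms (a room
    lacking the component contributes 0) and divided by the number of
    rooms assessed.
    """
    rooms = latest_assessments(records)
    if not rooms:
        raise ValueError("component_school_average requires at least one assessed room")
    total = 0
    for rec in rooms:
        obs = rec.observation(component)
        if obs is not None:
            total += component_total(obs)
    return total / len(rooms)


def school_average_score(records: Sequence[RoomAssessment]) -> float:
    """Mean room total over the assessed rooms of a school."""
    rooms = latest_assessments(records)
    if not rooms:
        raise ValueError("school_average_score requires at least one assessed room")
    return sum(room_total(r) for r in rooms) / len(rooms)


def dichotomize_by_median(school_scores: Mapping[str, float]) -> dict[str, str]:
    """Split schools into exposure groups at the median average score.

    Schools strictly above the median are labelled ``"above"``; all
    others, including those exactly at the median, ``"at_or_below"``.
    The median is the midpoint of the two central order statistics when
    the number of schools is even.
    """
    if len(school_scores) < 2:
        raise ValueError("dichotomize_by_median requires at least two schools")
    med = statistics.median(school_scores.values())
    return {
        school: ("above" if score > med else "at_or_below")
        for school, score in school_scores.items()
    }


def band_rooms(
    records: Sequence[RoomAssessment],
) -> dict[tuple[str, str], ColorBand]:
    """Color-band each room's total for floor-map display."""
    rooms = latest_assessments(records)
    return {room_key(r): classify_room(room_total(r)) for r in rooms}


def factor_prevalence(
    records: Sequence[RoomAssessment], factor: FactorLike
) -> float:
    """Proportion of rooms with any non-zero score for the factor."""
    rooms = latest_assessments(records)
    if not rooms:
        raise ValueError("factor_prevalence requires at least one assessed room")
    affected = sum(1 for r in rooms if _room_factor_score(r, factor) > 0)
    return affected / len(rooms)


@dataclass(frozen=True)
class CampaignSummary:
    """All campaign-level aggregates for one school/building group."""

    group: str
    n_rooms: int
    component_school_averages: dict[Component, float]
    factor_score_frequencies: dict[tuple[str, Component | None, int], int]
    factor_prevalence: dict[str, float]
    school_average_score: float


def summarize_campaign(
    records: Sequence[RoomAssessment], group: str = ""
) -> CampaignSummary:
    """Compute every campaign aggregate in one pass-friendly structure.

    Frequency keys are ``(factor_name, component, score)`` with
    ``component=None`` for mold odor.
    """
    rooms = latest_assessments(records)
    if not rooms:
        raise ValueError("summarize_campaign requires at least one assessed room")
    freqs: dict[tuple[str, Component | None, int], int] = {}
    for factor in (*Factor, MOLD_ODOR):
        name = factor.value if isinstance(factor, Factor) else factor
        for (comp, score), n in score_frequency(rooms, factor).items():
            freqs[(name, comp, score)] = n
    return CampaignSummary(
        group=group,
        n_rooms=len(rooms),
        component_school_averages={
            c: component_school_average(rooms, c) for c in Component
        },
        factor_score_frequencies=freqs,
        factor_prevalence={
            (f.value if isinstance(f, Factor) else f): factor_prevalence(rooms, f)
            for f in (*Factor, MOLD_ODOR)
        },
        school_average_score=school_average_score(rooms),
    )
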