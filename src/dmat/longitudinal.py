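"""Compare repeat assessments of the same rooms across campaigns.

Buildings are reassessed on a regular cycle (typically twice a year, or
after extreme weather).  Comparing the current campaign against a
previous one shows whether damage is unchanged, getting worse, improved
or resolved, and reveals damage that did not exist before.  Worsening
or new damage signals a water source that needs to be found and
repaired; wet/damp materials, visible mold and mold odor represent
ongoing or recent water incursion and call for immediate action.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

from .datamodel import Component, Factor, RoomAssessment, room_key
from .scoring import ColorBand, classify_room, room_total
from .aggregation import MOLD_ODOR, latest_assessments

__all__ = [
    "ChangeStatus",
    "ChangeRecord",
    "RoomChangeSummary",
    "StructuralChange",
    "DiffResult",
    "classify_change",
    "diff_assessments",
    "flag_for_action",
]


class ChangeStatus(str, enum.Enum):
    NEW = "new"
    WORSENED = "worsened"
    UNCHANGED = "unchanged"
    IMPROVED = "improved"
    RESOLVED = "resolved"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_change(previous: int, current: int) -> ChangeStatus:
    """Status of one score transition; a pure function of the pair.

    0 -> >0 is new damage; an increase from a non-zero score is
    worsened; equal scores (including 0 -> 0) are unchanged; a decrease
    to a non-zero score is improved; >0 -> 0 is resolved.
    """
    if previous == current:
        return ChangeStatus.UNCHANGED
    if previous == 0:
        return ChangeStatus.NEW
    if current == 0:
        return ChangeStatus.RESOLVED
    return ChangeStatus.WORSENED if current > previous else ChangeStatus.IMPROVED


@dataclass(frozen=True)
class ChangeRecord:
    """One (room, component, factor) score transition between campaigns.

    ``component`` is ``None`` for the room-level mold-odor factor.
    """

    room: tuple[str, str]
    component: Component | None
    factor: str
    previous: int
    current: int
    status: ChangeStatus


@dataclass(frozen=True)
class RoomChangeSummary:
    """Room-level deltas between two campaigns."""

    room: tuple[str, str]
    previous_total: int
    current_total: int
    delta_total: int
    previous_band: ColorBand
    current_band: ColorBand


@dataclass(frozen=True)
class StructuralChange:
    """A component present in only one of the two campaigns.

    Structural changes (e.g. furniture removed) are reported but their
    scores are excluded from change records and room deltas.
    """

    room: tuple[str, str]
    component: Component
    change: str  # "component_added" | "component_removed"


@dataclass(frozen=True)
class DiffResult:
    changes: tuple[ChangeRecord, ...]
    room_summaries: tuple[RoomChangeSummary, ...]
    structural_changes: tuple[StructuralChange, ...]
    added_rooms: tuple[tuple[str, str], ...]
    removed_rooms: tuple[tuple[str, str], ...]

    def by_status(self, status: ChangeStatus) -> tuple[ChangeRecord, ...]:
        return tuple(c for c in self.changes if c.status is status)


def diff_assessments(
    previous: Sequence[RoomAssessment], current: Sequence[RoomAssessment]
) -> DiffResult:
    """Compare two campaigns room by room.

    Rooms are matched by (building, room) key; rooms present in only
    one campaign are listed as added/removed rather than diffed.  For
    each matched room one :class:`ChangeRecord` is emitted per
    (component, factor) the room has in both campaigns, plus one for
    mold odor.  All outputs are deterministically ordered.
    """
    prev_rooms = {room_key(r): r for r in latest_assessments(previous)}
    curr_rooms = {room_key(r): r for r in latest_assessments(current)}

    added = tuple(sorted(curr_rooms.keys() - prev_rooms.keys()))
    removed = tuple(sorted(prev_rooms.keys() - curr_rooms.keys()))

    changes: list[ChangeRecord] = []
    summaries: list[RoomChangeSummary] = []
    structural: list[StructuralChange] = []

    for key in sorted(prev_rooms.keys() & curr_rooms.keys()):
        p, c = prev_rooms[key], curr_rooms[key]
        changes.append(
            ChangeRecord(
                room=key,
                component=None,
                factor=MOLD_ODOR,
                previous=p.odor.score,
                current=c.odor.score,
                status=classify_change(p.odor.score, c.odor.score),
            )
        )
        p_comps = {o.component for o in p.observations}
        c_comps = {o.component for o in c.observations}
        for comp in Component:  # canonical order keeps output deterministic
            if comp in p_comps and comp in c_comps:
                po, co = p.observation(comp), c.observation(comp)
                assert po is not None and co is not None
                for f in Factor:
                    changes.append(
                        ChangeRecord(
                            room=key,
                            component=comp,
                            factor=f.value,
                            previous=po.factor_score(f),
                            current=co.factor_score(f),
                            status=classify_change(
                                po.factor_score(f), co.factor_score(f)
                            ),
                        )
                    )
            elif comp in c_comps:
                structural.append(StructuralChange(key, comp, "component_added"))
            elif comp in p_comps:
                structural.append(StructuralChange(key, comp, "component_removed"))

        pt, ct = room_total(p), room_total(c)
        summaries.append(
            RoomChangeSummary(
                room=key,
                previous_total=pt,
                current_total=ct,
                delta_total=ct - pt,
                previous_band=classify_room(pt),
                current_band=classify_room(ct),
            )
        )

    return DiffResult(
        changes=tuple(changes),
        room_summaries=tuple(summaries),
        structural_changes=tuple(structural),
        added_rooms=added,
        removed_rooms=removed,
    )


@dataclass(frozen=True)
class ActionItem:
    """One prioritized room in the remediation list."""

    room: tuple[str, str]
    immediate: bool
    n_new_or_worsened: int
    room_total: int
    reasons: tuple[str, ...] = field(default=())


def _immediate_reasons(rec: RoomAssessment) -> tuple[str, ...]:
    """Findings that indicate ongoing/recent damage needing prompt action."""
    reasons: list[str] = []
    if rec.odor.score > 0:
        reasons.append("mold odor present")
    if any(o.visible_mold > 0 for o in rec.observations):
        reasons.append("visible mold present")
    if any(o.wet_damp > 0 for o in rec.observations):
        reasons.append("wet/damp materials present")
    return tuple(reasons)


def flag_for_action(
    current: Sequence[RoomAssessment],
    diff: DiffResult | None = None,
) -> list[ActionItem]:
    """Rank rooms needing attention, most urgent first.

    Rooms with any current wet/damp materials, visible mold or mold
    odor form the immediate tier (these findings indicate ongoing or
    recent water incursion).  Within and below that tier, rooms sort by
    the count of new/worsened findings since the previous campaign
    (when a diff is supplied), then by current room total, with the
    room key as the final deterministic tie-break.  Rooms with no
    damage at all are omitted.
    """
    worsening: dict[tuple[str, str], int] = {}
    if diff is not None:
        for ch in diff.changes:
            if ch.status in (ChangeStatus.NEW, ChangeStatus.WORSENED):
                worsening[ch.room] = worsening.get(ch.room, 0) + 1

    items: list[ActionItem] = []
    for rec in latest_assessments(current):
        total = room_total(rec)
        if total == 0:
            continue
        reasons = _immediate_reasons(rec)
        items.append(
            ActionItem(
                room=room_key(rec),
                immediate=bool(reasons),
                n_new_or_worsened=worsening.get(room_key(rec), 0),
                room_total=total,
                reasons=reasons,
            )
        )
    items.sort(
        key=lambda it: (
            not it.immediate,
            -it.n_new_or_worsened,
            -it.room_total,
            it.room,
        )
    )
    return items
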