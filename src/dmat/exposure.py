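"""Exposure-assessment constructs built on top of room dampness scores.

Three constructs that make observational dampness scores usable in
epidemiologic analyses:

* **Time-weighted average (TWA) exposure** — a person's exposure index
  is the average of the dampness scores of the rooms they occupy,
  weighted by the time spent in each.

* **Mixed microbial exposure index (MMEI)** — dust samples are analysed
  for eight microbial agents (total culturable fungi, total culturable
  bacteria, Gram-positive and Gram-negative bacteria, endotoxin,
  ergosterol, (1→3)-β-D-glucan, muramic acid).  Each agent's
  concentrations are decile-ranked across samples, and a sample's MMEI
  is the sum of its eight decile ranks, giving a composite in [8, 80]
  that represents overall microbial contamination.

* **Inter-observer concordance** — the percent of rooms on which two
  observers agree about a factor's presence or absence, used to
  standardise observation methods before a campaign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import Factor, RoomAssessment, room_key

__all__ = [
    "MICROBIAL_AGENTS",
    "RoomTimeRecord",
    "MicrobialSample",
    "twa_exposure",
    "decile_ranks",
    "mmei",
    "concordance_rate",
    "read_room_times",
    "read_microbial",
]

#: The eight microbial agents entering the MMEI, in canonical order.
MICROBIAL_AGENTS: tuple[str, ...] = (
    "total_culturable_fungi",
    "total_culturable_bacteria",
    "gram_positive_bacteria",
    "gram_negative_bacteria",
    "endotoxin",
    "ergosterol",
    "beta_glucan",
    "muramic_acid",
)


@dataclass(frozen=True)
class RoomTimeRecord:
    """One person's room-time allocation.

    ``entries`` pairs a room key with a nonnegative time weight.  Any
    consistent unit works (hours per week, semester fractions); weights
    are normalised internally, so no convention is imposed.
    """

    person_id: str
    entries: tuple[tuple[tuple[str, str], float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((k, float(w)) for k, w in self.entries))


@dataclass(frozen=True)
class MicrobialSample:
    """Concentrations of the eight microbial agents for one room's sample."""

    room: tuple[str, str]
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in MICROBIAL_AGENTS if a not in self.concentrations]
        if missing:
            raise ValueError(f"sample for {self.room} is missing agent(s): {missing}")
        bad = {a: c for a, c in self.concentrations.items() if not (float(c) >= 0)}
        if bad:
            raise ValueError(f"concentrations must be >= 0, got {bad}")


def twa_exposure(
    rt: RoomTimeRecord, room_scores: Mapping[tuple[str, str], float]
) -> float:
    """Time-weighted average dampness score over a person's rooms.

    ``room_scores`` maps room keys to the room dampness score being used
    as the exposure metric (typically the room total or average score).
    """
    unknown = [k for k, _ in rt.entries if k not in room_scores]
    if unknown:
        raise KeyError(f"no score for room(s) {unknown} visited by {rt.person_id!r}")
    weights = [w for _, w in rt.entries]
    if any(w < 0 for w in weights):
        raise ValueError("time weights must be nonnegative")
    total = sum(weights)
    if total <= 0:
        raise ValueError(f"person {rt.person_id!r} has zero total time weight")
    return sum(room_scores[k] * w for k, w in rt.entries) / total


def decile_ranks(values: Sequence[float]) -> list[int]:
    """Decile rank (1-10) of each value within the input collection.

    Values are ranked ordinally with ties broken by stable input order;
    the decile of rank *r* among *n* values is ``ceil(10 * r / n)``.
    Output is in input order.  With n divisible by 10 and all values
    distinct, each decile holds exactly n/10 values.
    """
    if len(values) == 0:
        raise ValueError("decile_ranks requires at least one value")
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(len(arr), dtype=int)
    ranks[order] = np.arange(1, len(arr) + 1)
    n = len(arr)
    return [math.ceil(10 * int(r) / n) for r in ranks]


def mmei(samples: Sequence[MicrobialSample]) -> dict[tuple[str, str], int]:
    """Mixed microbial exposure index per sample.

    For each of the eight agents, concentrations are decile-ranked
    across all samples; a sample's MMEI is the sum of its agent-specific
    decile ranks, so it always lies in [8, 80].
    """
    if not samples:
        raise ValueError("mmei requires at least one sample")
    totals = [0] * len(samples)
    for agent in MICROBIAL_AGENTS:
        deciles = decile_ranks([float(s.concentrations[agent]) for s in samples])
        for i, d in enumerate(deciles):
            totals[i] += d
    return {s.room: t for s, t in zip(samples, totals)}


def _room_presence(rec: RoomAssessment, factor: Factor | str) -> bool:
    if factor == "mold_odor":
        return rec.odor.score > 0
    f = Factor(factor)
    return any(o.factor_score(f) > 0 for o in rec.observations)


def _room_factor_level(rec: RoomAssessment, factor: Factor | str) -> int:
    if factor == "mold_odor":
        return rec.odor.score
    f = Factor(factor)
    return max((o.factor_score(f) for o in rec.observations), default=0)


def concordance_rate(
    a: Sequence[RoomAssessment],
    b: Sequence[RoomAssessment],
    factor: Factor | str,
    mode: str = "presence",
) -> float:
    """Percent of rooms on which two observers agree about a factor.

    The two collections must cover the same set of rooms (matched by
    building and room id).  In the default ``"presence"`` mode agreement
    means both observers made the same presence/absence call at room
    level (any non-zero score counts as presence); ``"exact"`` mode
    requires the same room-level score.  Returned as a percentage in
    [0, 100].
    """
    if mode not in {"presence", "exact"}:
        raise ValueError(f"mode must be 'presence' or 'exact', got {mode!r}")
    rooms_a = {room_key(r): r for r in a}
    rooms_b = {room_key(r): r for r in b}
    if rooms_a.keys() != rooms_b.keys():
        only_a = sorted(rooms_a.keys() - rooms_b.keys())
        only_b = sorted(rooms_b.keys() - rooms_a.keys())
        raise ValueError(
            f"observers assessed different rooms (only first: {only_a}, "
            f"only second: {only_b})"
        )
    if not rooms_a:
        raise ValueError("concordance_rate requires at least one room")
    agree = 0
    for key, ra in rooms_a.items():
        rb = rooms_b[key]
        if mode == "presence":
            match = _room_presence(ra, factor) == _room_presence(rb, factor)
        else:
            match = _room_factor_level(ra, factor) == _room_factor_level(rb, factor)
        agree += int(match)
    return 100.0 * agree / len(rooms_a)


def read_room_times(path: str | Path) -> list[RoomTimeRecord]:
    """Read a person/room/time CSV (person_id, building_id, room_id, weight)."""
    import csv

    path = Path(path)
    entries: dict[str, list[tuple[tuple[str, str], float]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"person_id", "building_id", "room_id", "weight"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"missing columns in {path.name}: {sorted(missing)}")
        for row in reader:
            key = (row["building_id"].strip(), row["room_id"].strip())
            entries.setdefault(row["person_id"].strip(), []).append(
                (key, float(row["weight"]))
            )
    return [
        RoomTimeRecord(person_id=p, entries=tuple(e)) for p, e in sorted(entries.items())
    ]


def read_microbial(path: str | Path) -> list[MicrobialSample]:
    """Read a microbial measurement CSV (building_id, room_id, eight agents)."""
    import csv

    path = Path(path)
    samples: list[MicrobialSample] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"building_id", "room_id", *MICROBIAL_AGENTS}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"missing columns in {path.name}: {sorted(missing)}")
        for row in reader:
            samples.append(
                MicrobialSample(
                    room=(row["building_id"].strip(), row["room_id"].strip()),
                    concentrations={a: float(row[a]) for a in MICROBIAL_AGENTS},
                )
            )
    return samples
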