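"""Seeded generators for realistic synthetic assessment campaigns.

Nothing here is measured data: the generators emulate the *structure* of
multi-building observational campaigns — room rosters with partially
present components, room-level factor prevalence, ordinal severity,
paired observers with a controlled agreement probability, occupant
room-time tables, and microbial dust measurements whose levels rise
with room dampness — so that every part of the package can be exercised
and property-tested without any field data.

Default prevalences follow what school campaigns typically show:
water damage/stains is by far the most common finding (roughly half of
rooms), mold odor is occasional, and visible mold and wet/damp
materials are rare.  Severity is skewed low: most damage is smaller
than a sheet of paper.  Microbial concentrations are log-normal, the
standard model for environmental counts, with the log-location shifted
linearly by the room's dampness score.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aggregation import MOLD_ODOR, latest_assessments
from .datamodel import (
    Component,
    ComponentObservation,
    Factor,
    OdorIntensity,
    OdorObservation,
    RoomAssessment,
    room_key,
)
from .exposure import MICROBIAL_AGENTS, MicrobialSample, RoomTimeRecord
from .scoring import room_total

__all__ = [
    "CampaignSpec",
    "MicrobialSpec",
    "generate_campaign",
    "generate_observer_pair",
    "generate_microbial",
    "generate_room_times",
]

_ROOM_TYPES = (
    "classroom",
    "office",
    "library",
    "cafeteria",
    "gym",
    "storage",
    "restroom",
    "hallway",
)

_FLOORS = ("B", "1", "2")
_FLOOR_PROBS = (0.1, 0.5, 0.4)


def _default_presence() -> dict[Component, float]:
    return {
        Component.CEILING: 1.0,
        Component.WALLS: 1.0,
        Component.FLOOR: 1.0,
        Component.WINDOWS: 0.85,
        Component.FURNISHINGS: 0.9,
        Component.HVAC: 0.7,
        Component.SUPPLIES_MATERIALS: 0.6,
        Component.PIPES: 0.3,
    }


def _default_prevalence() -> dict[str, float]:
    # Room-level probability that a factor is observed at all; ordering
    # follows field campaigns (stains >> odor > mold ~ wetness).
    return {
        Factor.WATER_DAMAGE_STAINS.value: 0.52,
        Factor.VISIBLE_MOLD.value: 0.02,
        Factor.WET_DAMP.value: 0.02,
        MOLD_ODOR: 0.17,
    }


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of a synthetic multi-building assessment campaign.

    ``factor_prevalence`` is the *room-level* probability that each
    factor is present anywhere in a room; ``severity_distribution``
    gives the probabilities of scores 1/2/3 for an affected component;
    ``damage_correlation`` in [0, 1] mixes in a shared room-level
    "leak event" latent variable that correlates the factors without
    changing their marginal prevalence.
    """

    n_buildings: int = 5
    rooms_per_building: int = 20
    component_presence_probs: dict[Component, float] = field(
        default_factory=_default_presence
    )
    factor_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    severity_distribution: tuple[float, float, float] = (0.6, 0.3, 0.1)
    near_exterior_prob: float = 0.25
    odor_source_unknown_prob: float = 0.5
    within_room_spread: float = 0.4
    damage_correlation: float = 0.0
    assessment_date: _dt.date = _dt.date(2024, 5, 1)
    observer_id: str = "OBS1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_buildings < 1 or self.rooms_per_building < 1:
            raise ValueError("n_buildings and rooms_per_building must be >= 1")
        probs = {
            "near_exterior_prob": self.near_exterior_prob,
            "odor_source_unknown_prob": self.odor_source_unknown_prob,
            "within_room_spread": self.within_room_spread,
            "damage_correlation": self.damage_correlation,
            **{f"presence[{c.value}]": p for c, p in self.component_presence_probs.items()},
            **{f"prevalence[{k}]": p for k, p in self.factor_prevalence.items()},
        }
        bad = {k: p for k, p in probs.items() if not (0.0 <= p <= 1.0)}
        if bad:
            raise ValueError(f"probabilities must be in [0, 1]: {bad}")
        if abs(sum(self.severity_distribution) - 1.0) > 1e-9 or any(
            p < 0 for p in self.severity_distribution
        ):
            raise ValueError("severity_distribution must be a probability vector over 1-3")
        for c in (Component.CEILING, Component.WALLS, Component.FLOOR):
            if self.component_presence_probs.get(c, 1.0) != 1.0:
                raise ValueError(f"basic component {c.value} must have presence 1.0")


def _draw_severity(rng: np.random.Generator, spec: CampaignSpec) -> int:
    return int(rng.choice((1, 2, 3), p=spec.severity_distribution))


def generate_campaign(spec: CampaignSpec) -> list[RoomAssessment]:
    """Generate one campaign of room assessments.

    Reproducible given ``spec.seed``; every record satisfies the data
    model invariants; the empirical room-level prevalence of each factor
    converges to ``spec.factor_prevalence`` as the campaign grows.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[RoomAssessment] = []

    for b in range(spec.n_buildings):
        building_id = f"B{b + 1:02d}"
        for r in range(spec.rooms_per_building):
            room_id = f"R{r + 1:03d}"
            floor = str(rng.choice(_FLOORS, p=_FLOOR_PROBS))
            room_type = str(rng.choice(_ROOM_TYPES))

            present = [
                c
                for c in Component
                if rng.uniform() < spec.component_presence_probs.get(c, 0.0)
            ]

            # Room-level factor presence; a shared latent uniform induces
            # cross-factor correlation without changing the marginals.
            u_shared = rng.uniform()
            affected: dict[str, bool] = {}
            for name, prev in spec.factor_prevalence.items():
                u = u_shared if rng.uniform() < spec.damage_correlation else rng.uniform()
                affected[name] = u < prev

            scores: dict[Component, dict[Factor, int]] = {
                c: {f: 0 for f in Factor} for c in present
            }
            for f in Factor:
                if not affected.get(f.value, False):
                    continue
                hit = [c for c in present if rng.uniform() < spec.within_room_spread]
                if not hit:
                    hit = [present[int(rng.integers(len(present)))]]
                for c in hit:
                    scores[c][f] = _draw_severity(rng, spec)

            observations = []
            for c in present:
                any_damage = any(scores[c][f] > 0 for f in Factor)
                observations.append(
                    ComponentObservation(
                        component=c,
                        damage_stain=scores[c][Factor.WATER_DAMAGE_STAINS],
                        visible_mold=scores[c][Factor.VISIBLE_MOLD],
                        wet_damp=scores[c][Factor.WET_DAMP],
                        near_exterior_wall=bool(
                            any_damage and rng.uniform() < spec.near_exterior_prob
                        ),
                        nothing_found=not any_damage,
                    )
                )

            if affected.get(MOLD_ODOR, False):
                intensity = OdorIntensity.from_score(_draw_severity(rng, spec))
                unknown = bool(rng.uniform() < spec.odor_source_unknown_prob)
                odor = OdorObservation(
                    intensity=intensity,
                    source_description="" if unknown else "identified source",
                    source_unknown=unknown,
                )
            else:
                odor = OdorObservation()

            records.append(
                RoomAssessment(
                    building_id=building_id,
                    room_id=room_id,
                    assessment_date=spec.assessment_date,
                    observer_id=spec.observer_id,
                    floor_level=floor,
                    room_type=room_type,
                    odor=odor,
                    observations=tuple(observations),
                )
            )
    return records


def _zero_factor(obs: ComponentObservation, f: Factor) -> ComponentObservation:
    kwargs = {
        Factor.WATER_DAMAGE_STAINS: "damage_stain",
        Factor.VISIBLE_MOLD: "visible_mold",
        Factor.WET_DAMP: "wet_damp",
    }
    return replace(obs, **{kwargs[f]: 0})


def _set_factor(obs: ComponentObservation, f: Factor, score: int) -> ComponentObservation:
    kwargs = {
        Factor.WATER_DAMAGE_STAINS: "damage_stain",
        Factor.VISIBLE_MOLD: "visible_mold",
        Factor.WET_DAMP: "wet_damp",
    }
    return replace(obs, **{kwargs[f]: score})


def _tidy_flags(obs: ComponentObservation) -> ComponentObservation:
    any_damage = any(obs.factor_score(f) > 0 for f in Factor)
    return replace(
        obs,
        nothing_found=not any_damage,
        near_exterior_wall=obs.near_exterior_wall and any_damage,
    )


def generate_observer_pair(
    campaign: Sequence[RoomAssessment],
    agreement_prob: float,
    seed: int,
    observer_id: str = "OBS2",
) -> list[RoomAssessment]:
    """Simulate a second observer re-assessing the same rooms.

    Independently for every room and factor (the three component-level
    factors plus mold odor), the second observer reproduces the first
    observer's room-level presence/absence call with probability
    ``agreement_prob`` and contradicts it otherwise, so the expected
    concordance rate equals ``agreement_prob x 100``.
    """
    if not (0.0 <= agreement_prob <= 1.0):
        raise ValueError(f"agreement_prob must be in [0, 1], got {agreement_prob!r}")
    rng = np.random.default_rng(seed)
    second: list[RoomAssessment] = []

    for rec in campaign:
        observations = list(rec.observations)
        for f in Factor:
            present = any(o.factor_score(f) > 0 for o in observations)
            agrees = rng.uniform() < agreement_prob
            if agrees:
                continue
            if present:
                observations = [_zero_factor(o, f) for o in observations]
            else:
                idx = int(rng.integers(len(observations)))
                observations[idx] = _set_factor(observations[idx], f, 1)

        odor = rec.odor
        odor_agrees = rng.uniform() < agreement_prob
        if not odor_agrees:
            if odor.score > 0:
                odor = OdorObservation()
            else:
                odor = OdorObservation(intensity=OdorIntensity.MILD, source_unknown=True)

        second.append(
            replace(
                rec,
                observer_id=observer_id,
                odor=odor,
                observations=tuple(_tidy_flags(o) for o in observations),
            )
        )
    return second


def _default_agent_lognorm() -> dict[str, tuple[float, float]]:
    # (log-location, log-scale) per agent at dampness score 0; locations
    # are order-of-magnitude typical for floor-dust analyses (CFU/g,
    # EU/mg, ug/g), scales ~1 log as usual for environmental counts.
    return {
        "total_culturable_fungi": (10.8, 1.0),
        "total_culturable_bacteria": (11.5, 1.0),
        "gram_positive_bacteria": (10.9, 1.0),
        "gram_negative_bacteria": (9.2, 1.0),
        "endotoxin": (3.0, 0.8),
        "ergosterol": (1.6, 0.8),
        "beta_glucan": (3.9, 0.8),
        "muramic_acid": (2.3, 0.8),
    }


@dataclass(frozen=True)
class MicrobialSpec:
    """Log-normal microbial concentration model.

    ``score_effect`` is the additive shift of each agent's log-location
    per unit of room dampness score (room total); a positive value makes
    damper rooms more contaminated on every agent.
    """

    agent_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=_default_agent_lognorm
    )
    score_effect: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        missing = [a for a in MICROBIAL_AGENTS if a not in self.agent_lognorm]
        if missing:
            raise ValueError(f"agent_lognorm is missing agent(s): {missing}")
        bad = {a: s for a, (_, s) in self.agent_lognorm.items() if s <= 0}
        if bad:
            raise ValueError(f"log-scales must be > 0: {bad}")


def generate_microbial(
    campaign: Sequence[RoomAssessment], spec: MicrobialSpec
) -> list[MicrobialSample]:
    """Generate one dust sample per assessed room.

    Concentrations are log-normal with the log-location shifted by
    ``score_effect`` times the room total score, emulating the observed
    association between dampness scores and microbial measurements.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples: list[MicrobialSample] = []
    for rec in latest_assessments(campaign):
        score = room_total(rec)
        conc = {
            agent: float(
                np.exp(rng.normal(loc + spec.score_effect * score, scale))
            )
            for agent, (loc, scale) in (
                (a, spec.agent_lognorm[a]) for a in MICROBIAL_AGENTS
            )
        }
        samples.append(MicrobialSample(room=room_key(rec), concentrations=conc))
    return samples


def generate_room_times(
    campaign: Sequence[RoomAssessment],
    n_people: int,
    seed: int,
    max_rooms_per_person: int = 4,
) -> list[RoomTimeRecord]:
    """Generate occupant room-time tables over the campaign's rooms.

    Each person occupies 1 to ``max_rooms_per_person`` distinct rooms
    with Dirichlet-distributed time shares summing to one.
    """
    if n_people < 1:
        raise ValueError("n_people must be >= 1")
    rooms = sorted({room_key(r) for r in campaign})
    if not rooms:
        raise ValueError("campaign has no rooms")
    rng = np.random.default_rng(seed)
    people: list[RoomTimeRecord] = []
    for p in range(n_people):
        k = int(rng.integers(1, min(max_rooms_per_person, len(rooms)) + 1))
        idx = rng.choice(len(rooms), size=k, replace=False)
        shares = rng.dirichlet(np.ones(k))
        people.append(
            RoomTimeRecord(
                person_id=f"P{p + 1:04d}",
                entries=tuple(
                    (rooms[int(i)], float(s)) for i, s in zip(idx, shares)
                ),
            )
        )
    return people
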