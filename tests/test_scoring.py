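"""Scoring rules: size thresholds, summary-score formulas, color bands."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from dmat import (
    INTERIOR_DOOR_AREA_IN2,
    PAPER_SHEET_AREA_IN2,
    ColorBand,
    Component,
    ComponentObservation,
    Factor,
    OdorIntensity,
    OdorObservation,
    RoomAssessment,
    classify_room,
    component_total,
    factor_average,
    room_average,
    room_total,
    score_room,
    size_to_score,
)

from conftest import room_assessments


class TestSizeToScore:
    @pytest.mark.parametrize(
        "area, expected",
        [
            (0.0, 0),
            (1.0, 1),
            (60.0, 1),  # below a sheet of paper
            (93.5, 1),  # exactly a sheet of paper -> lower score
            (93.6, 2),
            (1000.0, 2),
            (2560.0, 2),  # exactly an interior door -> lower score
            (2560.1, 3),
            (3000.0, 3),  # larger than an interior door
        ],
    )
    def test_thresholds(self, area, expected):
        assert size_to_score(area) == expected

    def test_reference_object_areas(self):
        assert PAPER_SHEET_AREA_IN2 == pytest.approx(8.5 * 11)
        assert INTERIOR_DOOR_AREA_IN2 == pytest.approx(32 * 80)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            size_to_score(-1.0)

    @given(
        st.floats(min_value=0, max_value=5000, allow_nan=False),
        st.floats(min_value=0, max_value=5000, allow_nan=False),
    )
    def test_monotone_in_area(self, a, b):
        if a > b:
            a, b = b, a
        assert size_to_score(a) <= size_to_score(b)


class TestComponentTotal:
    @pytest.mark.parametrize(
        "scores, expected", [((2, 1, 0), 3), ((0, 0, 0), 0), ((3, 3, 3), 9)]
    )
    def test_sums_three_factor_scores(self, scores, expected):
        obs = ComponentObservation(
            Component.CEILING,
            damage_stain=scores[0],
            visible_mold=scores[1],
            wet_damp=scores[2],
        )
        assert component_total(obs) == expected


def _room(observations, odor=OdorIntensity.NONE):
    return RoomAssessment(
        building_id="B",
        room_id="R",
        assessment_date=dt.date(2024, 5, 1),
        odor=OdorObservation(intensity=odor),
        observations=tuple(observations),
    )


class TestRoomSummaries:
    def test_room_total_adds_component_totals_and_odor(self):
        rec = _room(
            [
                ComponentObservation(Component.CEILING, damage_stain=2, visible_mold=1),
                ComponentObservation(Component.WALLS, wet_damp=1),
            ],
            odor=OdorIntensity.MILD,
        )
        assert room_total(rec) == 3 + 1 + 1

    def test_maximal_room_total_is_75(self):
        # Brute-force: all 8 components at (3,3,3) plus strong odor.
        rec = _room(
            [
                ComponentObservation(c, damage_stain=3, visible_mold=3, wet_damp=3)
                for c in Component
            ],
            odor=OdorIntensity.STRONG,
        )
        brute = sum(
            o.factor_score(f) for o in rec.observations for f in Factor
        ) + rec.odor.score
        assert room_total(rec) == brute == 8 * 9 + 3 == 75

    def test_factor_average_over_existing_components_only(self):
        rec = _room(
            [
                ComponentObservation(Component.CEILING, damage_stain=2),
                ComponentObservation(Component.WALLS, damage_stain=1),
                ComponentObservation(Component.FLOOR),
            ]
        )
        assert factor_average(rec, Factor.WATER_DAMAGE_STAINS) == pytest.approx(1.0)
        assert factor_average(rec, Factor.VISIBLE_MOLD) == 0.0

    def test_factor_average_single_component(self):
        rec = _room([ComponentObservation(Component.CEILING, wet_damp=3)])
        assert factor_average(rec, Factor.WET_DAMP) == 3.0

    def test_factor_average_requires_components(self):
        with pytest.raises(ValueError):
            factor_average(_room([]), Factor.WET_DAMP)

    def test_room_average_adds_factor_averages_and_odor(self):
        rec = _room(
            [
                ComponentObservation(Component.CEILING, damage_stain=2, visible_mold=1),
                ComponentObservation(Component.WALLS, damage_stain=2, wet_damp=0),
            ],
            odor=OdorIntensity.MODERATE,
        )
        # averages: stains 2.0, mold 0.5, wet 0.0; odor 2
        assert room_average(rec) == pytest.approx(2.0 + 0.5 + 0.0 + 2)

    @pytest.mark.parametrize("s", [0, 1, 2, 3])
    def test_uniform_score_gives_room_average_3s(self, s):
        rec = _room(
            [
                ComponentObservation(c, damage_stain=s, visible_mold=s, wet_damp=s)
                for c in (Component.CEILING, Component.WALLS, Component.FLOOR)
            ]
        )
        assert room_average(rec) == pytest.approx(3 * s)


class TestClassifyRoom:
    @pytest.mark.parametrize(
        "total, band",
        [
            (0, ColorBand.NONE),
            (1, ColorBand.GREEN),
            (2, ColorBand.GREEN),
            (3, ColorBand.YELLOW),
            (6, ColorBand.YELLOW),
            (7, ColorBand.RED),
            (75, ColorBand.RED),
        ],
    )
    def test_bands(self, total, band):
        assert classify_room(total) is band

    def test_monotone_over_attainable_totals(self):
        order = [ColorBand.NONE, ColorBand.GREEN, ColorBand.YELLOW, ColorBand.RED]
        ranks = [order.index(classify_room(t)) for t in range(76)]
        assert ranks == sorted(ranks)

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            classify_room(-1)


def naive_score_room(rec: RoomAssessment):
    """Independent recomputation of every summary, written naively."""
    totals = {}
    for o in rec.observations:
        t = 0
        for f in Factor:
            t = t + o.factor_score(f)
        totals[o.component] = t
    total = rec.odor.score
    for t in totals.values():
        total += t
    n = len(rec.observations)
    averages = {}
    for f in Factor:
        s = 0
        for o in rec.observations:
            s += o.factor_score(f)
        averages[f] = s / n
    avg = rec.odor.score
    for a in averages.values():
        avg += a
    return totals, total, averages, avg


class TestScoreRoom:
    def test_two_room_worked_example(self, two_room_records):
        s1, s2 = (score_room(r) for r in two_room_records)
        assert s1.component_totals == {
            Component.CEILING: 2,
            Component.WALLS: 2,
            Component.FLOOR: 0,
            Component.WINDOWS: 1,
        }
        assert s1.room_total == 6
        assert s1.factor_averages == pytest.approx(
            {
                Factor.WATER_DAMAGE_STAINS: 0.75,
                Factor.VISIBLE_MOLD: 0.25,
                Factor.WET_DAMP: 0.25,
            }
        )
        assert s1.room_average == pytest.approx(2.25)
        assert s1.color_band is ColorBand.YELLOW
        assert s2.room_total == 0
        assert s2.room_average == 0.0
        assert s2.color_band is ColorBand.NONE

    @given(room_assessments())
    def test_invariants_hold_on_random_records(self, rec):
        s = score_room(rec)
        assert s.room_total == sum(s.component_totals.values()) + s.odor_score
        assert s.room_average == pytest.approx(
            sum(s.factor_averages.values()) + s.odor_score, abs=1e-9
        )
        assert s.room_average - s.odor_score == pytest.approx(
            (s.room_total - s.odor_score) / s.n_components, abs=1e-9
        )
        for f, a in s.factor_averages.items():
            assert a * s.n_components == pytest.approx(
                sum(o.factor_score(f) for o in rec.observations), abs=1e-9
            )
        assert 0 <= s.room_total <= 75
        assert 0 <= s.room_average <= 12

    @given(room_assessments(), st.randoms(use_true_random=False))
    def test_observation_order_never_changes_scores(self, rec, rnd):
        shuffled = list(rec.observations)
        rnd.shuffle(shuffled)
        permuted = RoomAssessment(
            building_id=rec.building_id,
            room_id=rec.room_id,
            assessment_date=rec.assessment_date,
            observer_id=rec.observer_id,
            odor=rec.odor,
            observations=tuple(shuffled),
        )
        a, b = score_room(rec), score_room(permuted)
        assert a.component_totals == b.component_totals
        assert a.room_total == b.room_total
        assert a.room_average == pytest.approx(b.room_average, abs=1e-12)

    @given(room_assessments())
    def test_matches_naive_oracle(self, rec):
        totals, total, averages, avg = naive_score_room(rec)
        s = score_room(rec)
        assert s.component_totals == totals
        assert s.room_total == total
        assert s.factor_averages == pytest.approx(averages, abs=1e-12)
        assert s.room_average == pytest.approx(avg, abs=1e-12)
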