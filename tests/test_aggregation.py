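"""Campaign-level aggregates and their brute-force oracles."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given

from dmat import (
    ColorBand,
    Component,
    ComponentObservation,
    Factor,
    MOLD_ODOR,
    OdorIntensity,
    OdorObservation,
    RoomAssessment,
    band_rooms,
    component_school_average,
    component_total,
    dichotomize_by_median,
    factor_prevalence,
    latest_assessments,
    room_total,
    school_average_score,
    score_frequency,
    summarize_campaign,
)

from conftest import campaigns


def _room(room_id, observations, odor=OdorIntensity.NONE, date=dt.date(2024, 5, 1)):
    return RoomAssessment(
        building_id="B01",
        room_id=room_id,
        assessment_date=date,
        odor=OdorObservation(intensity=odor),
        observations=tuple(observations),
    )


def _basic(component_scores):
    """Rooms with ceiling/walls/floor; ceiling visible_mold per given score."""
    return [
        _room(
            f"R{i}",
            [
                ComponentObservation(Component.CEILING, visible_mold=s),
                ComponentObservation(Component.WALLS),
                ComponentObservation(Component.FLOOR),
            ],
        )
        for i, s in enumerate(component_scores)
    ]


class TestScoreFrequency:
    def test_counts_nonzero_ceiling_scores(self):
        rooms = _basic([1, 1, 3])
        assert score_frequency(rooms, Factor.VISIBLE_MOLD) == {
            (Component.CEILING, 1): 2,
            (Component.CEILING, 3): 1,
        }

    def test_all_zero_campaign_gives_empty_map(self):
        rooms = _basic([0, 0])
        assert score_frequency(rooms, Factor.VISIBLE_MOLD) == {}

    def test_odor_counted_at_room_level(self):
        rooms = _basic([0, 0, 0])
        rooms[1] = _room("R1", rooms[1].observations, odor=OdorIntensity.STRONG)
        assert score_frequency(rooms, MOLD_ODOR) == {(None, 3): 1}

    @given(campaigns(max_rooms=12))
    def test_matches_brute_force_filter(self, camp):
        for f in Factor:
            counts = score_frequency(camp, f)
            for comp in Component:
                for s in (1, 2, 3):
                    brute = sum(
                        1
                        for r in camp
                        if (o := r.observation(comp)) is not None
                        and o.factor_score(f) == s
                    )
                    assert counts.get((comp, s), 0) == brute


class TestSchoolAverages:
    def test_component_school_average_over_all_rooms(self):
        rooms = [
            _room(
                f"R{i}",
                [
                    ComponentObservation(
                        Component.CEILING,
                        damage_stain=min(t, 3),
                        visible_mold=max(t - 3, 0),
                    ),
                    ComponentObservation(Component.WALLS),
                    ComponentObservation(Component.FLOOR),
                ],
            )
            for i, t in enumerate([4, 0, 2])
        ]
        assert component_school_average(rooms, Component.CEILING) == pytest.approx(2.0)

    def test_rooms_lacking_the_component_stay_in_denominator(self):
        rooms = _basic([3, 0])
        assert component_school_average(rooms, Component.PIPES) == 0.0

    def test_school_average_score_is_mean_room_total(self):
        rooms = _basic([3, 0])
        rooms[1] = _room("R1", rooms[1].observations, odor=OdorIntensity.MILD)
        assert school_average_score(rooms) == pytest.approx((3 + 1) / 2)

    def test_single_room_school_average_is_its_total(self):
        rooms = _basic([2])
        assert school_average_score(rooms) == room_total(rooms[0])

    def test_zero_rooms_is_an_error(self):
        with pytest.raises(ValueError):
            school_average_score([])
        with pytest.raises(ValueError):
            component_school_average([], Component.CEILING)

    @given(campaigns(max_rooms=12))
    def test_matches_brute_force_means(self, camp):
        n = len({(r.building_id, r.room_id) for r in camp})
        rooms = latest_assessments(camp)
        assert school_average_score(camp) == pytest.approx(
            sum(room_total(r) for r in rooms) / n, abs=1e-9
        )
        for comp in Component:
            brute = (
                sum(
                    component_total(o)
                    for r in rooms
                    if (o := r.observation(comp)) is not None
                )
                / n
            )
            assert component_school_average(camp, comp) == pytest.approx(brute, abs=1e-9)


class TestDichotomize:
    def test_three_schools_split_at_median(self):
        assert dichotomize_by_median({"A": 1.0, "B": 2.0, "C": 3.0}) == {
            "A": "at_or_below",
            "B": "at_or_below",
            "C": "above",
        }

    def test_all_equal_scores_all_at_or_below(self):
        assert set(dichotomize_by_median({"A": 2.0, "B": 2.0}).values()) == {
            "at_or_below"
        }

    def test_even_count_uses_midpoint_median(self):
        groups = dichotomize_by_median({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert groups == {
            "A": "at_or_below",
            "B": "at_or_below",
            "C": "above",
            "D": "above",
        }

    def test_fewer_than_two_schools_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_by_median({"A": 1.0})

    def test_agreement_with_sort_based_oracle(self):
        scores = {f"S{i}": float((i * 7) % 13) for i in range(9)}
        med = sorted(scores.values())[len(scores) // 2]  # odd count
        groups = dichotomize_by_median(scores)
        for school, score in scores.items():
            assert (groups[school] == "above") == (score > med)


class TestBandsAndPrevalence:
    def test_band_rooms_maps_totals_to_bands(self):
        rooms = []
        for i, total in enumerate([0, 2, 5, 9]):
            scores = [min(total, 3), min(max(total - 3, 0), 3), max(total - 6, 0)]
            rooms.append(
                _room(
                    f"R{i}",
                    [
                        ComponentObservation(
                            Component.CEILING,
                            damage_stain=scores[0],
                            visible_mold=scores[1],
                            wet_damp=scores[2],
                        ),
                        ComponentObservation(Component.WALLS),
                        ComponentObservation(Component.FLOOR),
                    ],
                )
            )
        bands = band_rooms(rooms)
        assert [bands[("B01", f"R{i}")] for i in range(4)] == [
            ColorBand.NONE,
            ColorBand.GREEN,
            ColorBand.YELLOW,
            ColorBand.RED,
        ]

    def test_empty_campaign_gives_empty_table(self):
        assert band_rooms([]) == {}

    def test_prevalence_counts_affected_rooms(self):
        rooms = _basic([1, 0, 2, 0])
        assert factor_prevalence(rooms, Factor.VISIBLE_MOLD) == pytest.approx(0.5)
        assert factor_prevalence(rooms, MOLD_ODOR) == 0.0


class TestCampaignSummary:
    @given(campaigns(max_rooms=10))
    def test_aggregates_invariant_to_room_order(self, camp):
        forward = summarize_campaign(camp)
        backward = summarize_campaign(list(reversed(camp)))
        assert forward == backward

    @given(campaigns(max_rooms=10))
    def test_component_averages_sum_to_school_average_minus_odor(self, camp):
        s = summarize_campaign(camp)
        rooms = latest_assessments(camp)
        mean_odor = sum(r.odor.score for r in rooms) / len(rooms)
        assert sum(s.component_school_averages.values()) == pytest.approx(
            s.school_average_score - mean_odor, abs=1e-9
        )

    def test_latest_assessment_wins_within_campaign(self):
        early = _room(
            "R0",
            [
                ComponentObservation(Component.CEILING, damage_stain=3),
                ComponentObservation(Component.WALLS),
                ComponentObservation(Component.FLOOR),
            ],
            date=dt.date(2024, 1, 1),
        )
        late = _room(
            "R0",
            [
                ComponentObservation(Component.CEILING),
                ComponentObservation(Component.WALLS),
                ComponentObservation(Component.FLOOR),
            ],
            date=dt.date(2024, 6, 1),
        )
        assert school_average_score([early, late]) == 0.0
        assert len(latest_assessments([early, late])) == 1
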