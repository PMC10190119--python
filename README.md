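# dmat

Semi-quantitative scoring and analysis of observational dampness and mold
assessments, implementing the NIOSH Dampness and Mold Assessment Tool
(DMAT) workflow for facility managers, industrial hygienists and
exposure epidemiologists.

Indoor dampness and mold are assessed without environmental sampling:
an observer smells for **mold odor** (none/mild/moderate/strong) and
visually scores **water damage/stains**, **visible mold** and **wet or
damp materials** on each of eight room components (ceiling, walls,
floor, windows, furnishings, HVAC system, supplies/materials, pipes).
Component-level factors are scored 0–3 by combined damaged area:

| score | combined damaged area |
|------:|-----------------------|
| 0 | none |
| 1 | ≤ a sheet of paper (8.5 × 11 in = 93.5 in²) |
| 2 | ≤ a standard interior door (32 × 80 in = 2560 in²) |
| 3 | larger than an interior door |

From the raw scores the package derives, for each room with existing
components *C* and odor score *m*:

- component total: `T_c = stain_c + mold_c + wet_c` (0–9)
- room total: `T = Σ_c T_c + m`
- factor average: `A_f = Σ_c s_fc / |C|`
- room average: `A = Σ_f A_f + m`
- floor-map color band: 1–2 green, 3–6 yellow, ≥ 7 red (0 ⇒ none)

plus campaign-level aggregates (non-zero score frequencies,
component-specific school averages, school average scores with median
dichotomization), exposure indices (time-weighted average room score
per person; the mixed microbial exposure index, MMEI = sum of
agent-specific decile ranks over eight microbial agents, range 8–80;
inter-observer concordance rates), and longitudinal change tracking
(new / worsened / unchanged / improved / resolved, with a prioritized
action list).

## Worked example

Two rooms: a classroom with a ceiling stain larger than a sheet of
paper (score 2, near an exterior wall), small wall stain and wall mold
(1 each), window condensation (wet/damp 1) and mild mold odor of
unknown source; and a clean office.

```python
import datetime as dt
from dmat import *

room = RoomAssessment(
    building_id="B01", room_id="R101",
    assessment_date=dt.date(2024, 5, 1), observer_id="OBS1",
    odor=OdorObservation(intensity=OdorIntensity.MILD, source_unknown=True),
    observations=(
        ComponentObservation(Component.CEILING, damage_stain=2, near_exterior_wall=True),
        ComponentObservation(Component.WALLS, damage_stain=1, visible_mold=1),
        ComponentObservation(Component.FLOOR, nothing_found=True),
        ComponentObservation(Component.WINDOWS, wet_damp=1),
    ),
)
s = score_room(room)
print(s.room_total, round(s.room_average, 2), s.color_band.value)
```

prints

```
6 2.25 yellow
```

The room total 6 is the four component totals (2 + 2 + 0 + 1) plus the
odor score 1; the room average 2.25 is the three factor averages over
the four existing components (0.75 + 0.25 + 0.25) plus the odor score;
a total of 6 falls in the yellow (medium, 3–6) band.

The same pipeline runs from the shell:

```sh
dmat simulate --seed 1 --out-dir scratch/sim       # synthetic campaign
dmat validate scratch/sim/campaign.csv
dmat score    scratch/sim/campaign.csv --out-dir scratch/out
dmat aggregate scratch/sim/campaign.csv --out-dir scratch/out
dmat compare  previous.csv current.csv --out-dir scratch/out
```

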