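# Methods

## The assessment model

An assessment record captures one observer's visit to one room or area:
room-level mold odor plus, for every room component that exists in the
room, three visually judged factors (water damage/stains, visible mold,
wet/damp materials) on an ordinal 0–3 scale. Eight components are
recognised; ceiling, walls and floor are treated as basic components
expected in every enclosed room (their absence is reported as a warning,
not an error, since unusual spaces exist). Two checkbox flags qualify a
component observation: *nothing found* (shorthand for all three factors
zero) and *near exterior wall* (damage within ~3 ft of an exterior
wall, meaningful only when something was found). Validation returns
violations as data rather than raising, so a batch import can report
every problem in a file at once; each model invariant has a dedicated
violation code.

The 0–3 size scale is anchored to everyday reference objects: score 1
up to a sheet of standard paper (93.5 in²), score 2 up to a standard
interior door (2560 in²), score 3 beyond. The wording of the scale
("less than" a sheet / "greater than" a sheet) leaves exact equality
unassigned; this package fixes the closed-lower-interval convention
(areas exactly at a threshold take the lower score). `size_to_score`
is a helper for training and synthetic data — observers normally judge
the category directly, and the recorded ordinal score is authoritative.

### Summary scores

With existing components *C*, factor scores `s_fc` and odor score *m*:

- component total `T_c = Σ_f s_fc` ∈ [0, 9]
- room total `T = Σ_c T_c + m` ∈ [0, 75]
- factor average `A_f = Σ_c s_fc / |C|` (non-existing components are
  excluded from numerator *and* denominator)
- room average `A = Σ_f A_f + m` ∈ [0, 12]

The odor score is added undivided to both the total and the average:
odor is a room-level judgment, so dividing it by the component count
would dilute it arbitrarily. These definitions imply the identity
`A − m = (T − m)/|C|`, which the test suite checks to 1e−9 on random
records, alongside an independent naive recomputation. Averages are
carried at full floating precision; fixed-point formatting (6 decimals)
happens only in CSV reports.

Room totals are banded for floor-map display: green 1–2, yellow 3–6,
red ≥ 7. A total of 0 lies below the printed green band; it is emitted
as an explicit `none` band rather than stretching green, so "no damage"
and "minor damage" stay distinguishable on a map.

## Tabular I/O

The CSV layout flattens the data-entry workbook's two-level headers to
one snake_case row (a convenience Excel writer reproduces the two-level
look). Read conventions follow the entry sheet: a blank
`<component>_present` cell means the component does not exist; a blank
factor cell on a present component means "assessed as 0"; the odor
score cell must never be blank (no odor is an explicit 0). On write the
package always emits explicit zeros, so a written file never depends on
the blank-means-zero rule, and rows are sorted by (building, room,
date, observer), making output byte-deterministic. Unknown columns are
tolerated and ignored on read; they are not carried through a
write. Dates are ISO-8601. Free-text cells are carried verbatim;
structured cells are whitespace-stripped.

## Aggregation

Campaign summaries operate on the latest assessment of each room
(earlier visits stay available to the longitudinal comparison; date
ties resolve to the lexicographically larger observer id so the choice
is deterministic). The component-specific school average divides the
component's total summed over **all** assessed rooms by the number of
rooms assessed — rooms lacking the component count 0 in the numerator
but stay in the denominator, so the average reflects the building, not
just rooms that happen to have the component. School average scores
(mean room total) are dichotomized at the median across schools;
schools exactly at the median go to the lower ("at_or_below") group —
with ~50 schools ties are unlikely but must be deterministic. Room-level
prevalence counts a room as affected if any component carries a
non-zero score for the factor.

## Exposure indices

**TWA exposure.** A person's index is `Σ w_r · score_r / Σ w_r` over
the rooms they occupy. Weights are arbitrary nonnegative quantities
(hours, semester shares); no normalisation convention is imposed, and a
zero total weight is an error.

**MMEI.** For each of the eight agents (total culturable fungi and
bacteria, Gram-positive and Gram-negative bacteria, endotoxin,
ergosterol, (1→3)-β-D-glucan, muramic acid), concentrations are ranked
ordinally across samples with ties broken by stable input order, and
the decile of rank *r* among *n* is `ceil(10·r/n)` ∈ 1..10. A sample's
MMEI is the sum of its eight decile ranks, range [8, 80]. The tie rule
matters only for tied data; the stable-ordinal-plus-ceiling convention
was fixed because it is reproducible, permutation-equivariant up to
ties, and gives exactly n/10 samples per decile when n is divisible by
10 with distinct values. MMEI is invariant to monotone rescaling of any
single agent, since only ranks enter.

**Concordance.** The percent of rooms on which two observers make the
same room-level presence/absence call for a factor (any non-zero score
counts as presence). Presence/absence is the default because crosscheck
exercises predate score-scale harmonisation between observers; an
`exact` mode requiring equal room-level scores is offered separately.
Room level (not room-component level) was chosen as the unit of
agreement. Unmatched room sets are an error, not silently intersected.

## Longitudinal comparison

For rooms present in both campaigns, each (component, factor) held in
common — plus room-level odor — yields a transition classified by a
pure function of (previous, current): `new` (0→>0), `worsened`
(increase from non-zero), `unchanged`, `improved` (decrease to
non-zero), `resolved` (>0→0). Components present in only one campaign
are reported as structural changes and excluded from score deltas, so a
removed mold-covered cabinet does not masquerade as remediation. The
action list puts rooms with any current wet/damp materials, visible
mold or mold odor in a single immediate tier (these indicate ongoing or
recent water incursion; the sources should be investigated promptly),
then sorts by count of new/worsened findings, then current room total,
with the room key as a final deterministic tie-break. Band transitions
are reported but do not affect tiering.

## Synthetic campaigns

The generator emulates the *structure* of a multi-building campaign,
not building physics. Per room: components are present independently
(ceiling/walls/floor always; windows 0.85, furnishings 0.9, HVAC 0.7,
supplies/materials 0.6, pipes 0.3 — typical of school rooms); each
factor is present at room level with its specified prevalence; an
affected factor hits each present component with probability 0.4 (at
least one guaranteed), with severity drawn from (0.6, 0.3, 0.1) over
scores 1–3 — most real damage is smaller than a sheet of paper.
Default room-level prevalences follow a school campaign profile:
water damage/stains 0.52, mold odor 0.17, visible mold 0.02, wet/damp
0.02. An optional `damage_correlation` parameter mixes a shared
room-level "leak event" uniform into the per-factor presence draws,
inducing cross-factor correlation without changing marginal
prevalences (at 0, factors are independent). Because an affected
factor always scores at least one component, empirical room-level
prevalence is exactly binomial around the specified value — the basis
of the 3-standard-error recovery checks.

The observer-pair generator reproduces each room-level presence call
with the given agreement probability, independently per factor and
room, and contradicts it otherwise (zeroing the factor, or adding a
score-1 finding on one component), so expected concordance equals the
agreement probability exactly. Microbial concentrations are log-normal
— the standard model for environmental counts — with agent-specific
log-locations typical of floor-dust analyses and the location shifted
by `score_effect` per unit room total (default 0.15 log units),
emulating the association between dampness scores and measured
contamination. All generators use numpy's integer-seeded PCG64
generator; the same seed reproduces identical output bit-for-bit.

What passing tests show — and do not show. Synthetic campaigns have
independent rooms, stationary prevalence, no spatial structure within
buildings and no observer drift; recovery of prevalence, agreement and
score–MMEI association under these conditions validates the *formulas
and plumbing*, not field performance of observational assessment.

## Problem sizes and numerical choices

Property tests run on hypothesis-generated records (derandomised, 60
examples per property); stochastic recovery checks use 1000-room
campaigns for binomial recovery (3 SE), 500 rooms for the null
score-effect check (|ρ| < 0.2) and 200 rooms for the positive-effect
check (ρ > 0) — sizes at which the checks are stable across seeds.
Floating-point identities are asserted to 1e−9; equality-sensitive
boundaries (93.5 and 2560 in²) are exercised exactly. The acceptance
script uses a 1000-room campaign, a 200-room microbial subset and 100
simulated occupants, and derives every stream from the single `--seed`.

## Known limitations

- No modelling of latent "true damage" behind observed scores, and no
  health-outcome regression; the package stops at exposure indices.
- Concordance is percent agreement only (no chance-corrected kappa).
- The CSV reader targets the package's own versioned layout, not
  arbitrary user-modified spreadsheets.
- Floor-map rendering is out of scope; bands are emitted as data.
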