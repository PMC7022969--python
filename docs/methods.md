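# Methods

## Scope and data model

The package analyzes herd-level event logs from dairy management
information systems. The exchange format is deliberately minimal: one
CSV of events (`herd_id, animal_id, event_date, event_type, value,
parity`) and one of herd metadata (`herd_id, zone, breed_group,
first_followup_year`). Identifiers are opaque strings, dates ISO-8601,
and empty cells are empty strings (never 0, which would read as a valid
milk weight). Seven event types are recognized — BIRTH, CALVING,
CONCEPTION, MILK_WEIGH, MASTITIS, LAMENESS, CULL — grouped into three
record-keeping categories: reproductive (BIRTH, CALVING, CONCEPTION),
productive (MILK_WEIGH, CULL — culling sits here because productive
life is derived from it), and health (MASTITIS, LAMENESS).

## Adoption-level classification

A calendar year counts as "covered" for a category when it contains at
least one record of that category (the threshold is configurable; no
minimum-records-per-year rule is imposed by default). A herd is HIGH
when all three categories share at least five *common consecutive*
covered years, MEDIUM when reproductive and productive (but not all
three) do, LOW when only the reproductive category reaches a five-year
run, and EXCLUDED otherwise. Requiring the category runs to *overlap*
is a deliberate choice: it guarantees the same herd-years are
analyzable across domains. When several runs qualify, the earliest is
taken — follow-up year 1 is the first year of that run ("first
implementation"), and follow-up is capped at 10 years.

## Trait derivation

Six traits per herd and calendar year, each an average over the
animals/lactations/weighings involved:

| trait | unit | definition | indexed by |
|---|---|---|---|
| AFC | months | birth → first calving, 30.4375 d/month | first-calving year |
| DO | days | calving → confirmed conception | conception year |
| DMY | kg | mean of all individual daily weighings | weighing year |
| PL | years | first calving → culling, 365.25 d/year | cull year |
| MAST | % | lactations started with ≥1 mastitis case | calving year |
| LAM | % | lactations started with ≥1 lameness case | calving year |

A lactation starts at a CALVING; a health event belongs to the lactation
whose calving most recently precedes it for the same animal. Month and
year lengths are fixed conventions (Julian year / 12 and Julian year);
no source for the study region defines them, and any consistent choice
shifts AFC/PL by far less than their SDs. Herd size per year is the
number of distinct cows with a calving, conception or weighing that
year, binned into classes 1–5 at 20/40/70/100 cows — the 40 and 70
interior edges are package defaults, as only the 5–20, 20–40 and ≥100
bounds are established. Calendar periods are five-year bins (≤1990,
1991–1995, …, 2006–2010, ≥2011).

Outlier cut-offs: each trait is trimmed to a configurable [min, max]
window, defaulting to the pooled baseline mean ± 4 SD (floored at zero,
incidences capped at 100 %). ±4 SD removes ≈ 0.006 % of genuinely
normal data, so the filter only acts on recording errors; the removal
log keeps every dropped row with its reason.

## Trend model

Per trait, the herd-year panel is modelled as

    y_hj = x_hj' β + b_h + e_hj

with reference-coded categorical fixed effects (zone, breed group,
herd-size class, calendar period, adoption level, follow-up year,
adoption × year interaction), a herd random intercept
b_h ~ N(0, σ²_between), and a within-herd AR(1) process with marginal
variance σ²_within and correlation ρ^|Δyear| (gaps decay correlation by
elapsed years, not row distance). MAST and LAM are log-transformed
first — a lognormal model on the incidence scale — with a configurable
offset (default 0.5 percentage points) added only when zeros are
present.

Three random terms (between-herd, within-herd serial, iid residual)
cannot all be separated at yearly spacing with ≤10 observations per
herd, so the serial term and the residual are merged into a single
AR(1) process; the reported "residual" variance is its innovation
variance σ²_within(1 − ρ²). Estimation is REML: the within-herd scale
is profiled out analytically and a quasi-Newton search runs over
(log variance ratio, atanh ρ), with three starting points to avoid
local optima. Per-herd likelihood contributions are batched over herds
sharing the same year pattern, so balanced panels cost one small
Cholesky per evaluation.

Inference: joint Wald chi-square tests per fixed factor (no
denominator-df correction — herd counts in the intended applications
are in the hundreds, and the parameter-recovery experiment below
confirms near-nominal coverage at that size); Wald Z tests for the
variance components from a central-difference Hessian of the unprofiled
REML criterion (one-sided for variances, two-sided for ρ; at a boundary
estimate such as σ²_between = 0 the Z test is conservative and the SE
may be undefined). Marginal means average the linear predictor with
equal weight over every nuisance-factor level (the classical
least-squares-means convention; the data's level frequencies do not
enter), and lognormal cells are back-transformed by exponentiation —
geometric means — with delta-method standard errors, subtracting any
zero-handling offset.

Aliased design columns (small datasets may not span all factor
combinations) either raise (default) or are dropped by QR pivoting
(`on_singular="drop"`, used by the pipeline), matching how standard
mixed-model software treats non-estimable levels.

## Synthetic herd generator

The generator emulates the structure the analysis assumes, at the
population scale of the motivating studies: 389/343/180 herds at
LOW/MEDIUM/HIGH adoption, up to 10 follow-up years, lognormal herd
sizes with mean 34 cows (SD 30, truncated at 5 — the size spread is a
package choice; only the mean and range of the reference population are
established). Trait baselines are the published pooled herd-year
means/SDs: AFC 31.3 ± 4.8 months, DO 100.6 ± 16.1 days, DMY 16.7 ± 4.5
kg, PL 4.02 ± 1.45 years, MAST 10.9 ± 10.7 %, LAM 17.9 ± 17.4 %. The
total variance splits evenly between and within herds by default
(herd-year panels of production traits typically show intraclass
correlations near one half); both SDs are directly configurable.
Within-herd deviations follow an AR(1) with default ρ = 0.5. MAST/LAM
are generated multiplicatively: the additive machinery runs on the log
scale (variances from the coefficient of variation), so values are
strictly positive and their herd-year means are lognormal.

Trends are linear ramps per adoption level over a configurable span,
encoding the reported approximate total changes: AFC −2 months over 4
years (MEDIUM), −1 month (HIGH), rising ≈ +2 months over the decade for
LOW; DO −5 days over the period (MEDIUM/HIGH) and −7 (LOW), with a −4
day LOW baseline offset; DMY +1 kg over the period (LOW/MEDIUM) and +2
kg (HIGH); PL +1 year over years 1–8; LAM declining for the levels that
would record it. Zone and breed offsets are expressed in multiples of
each trait's between-herd SD (one number per level, shared across
traits — a simplification; real breed effects differ by trait) and are
mean-zero by default.

`simulate_traits` emits the herd-year mean directly (fixed part + herd
intercept + serial deviation; normal traits truncated at zero).
`simulate_events` dresses the same latent means in animal-level events:
per herd-year, first-calvers (25 % of the herd) carry BIRTH + CALVING
pairs whose age difference is drawn around the AFC mean; conceiving
cows (80 %) carry CALVING + CONCEPTION with the days-open gap;
this year's calvers carry ~10 MILK_WEIGH records each around a
per-cow mean; culled cows (18 %) carry a backdated first CALVING + CULL
spanning the productive-life draw; and every lactation in a
health-recording (HIGH) herd is flagged MASTITIS/LAMENESS with the
herd-year incidence as Bernoulli probability. Each HIGH herd-year is
guaranteed at least one dated health event per type — a herd classified
as health-recording has, by definition, records every year — which
biases small-herd incidences upward by at most one lactation's worth.
Deriving traits from these events recovers the latent herd-year means
up to sampling noise that shrinks as 1/√cows (verified at 10/50/200
cows per herd).

What the generator does *not* emulate: herds entering or leaving
mid-study, reporting gaps beyond the adoption pattern, multi-lactation
cow careers (each synthetic animal serves one trait purpose), seasonal
calving patterns, and trait-specific breed effects. Passing tests
therefore demonstrate correctness of the pipeline's logic and
calibration of the estimator under the assumed structure — not
robustness to every messiness of field data. One structural consequence:
because first-calvers carry retroactive BIRTH records, a
reproductive-only herd's availability run can begin up to ~3 years
before its first adult event year, so LOW-herd follow-up windows open
early; MEDIUM/HIGH windows are anchored by the productive records and
start exactly at the configured first year.

## Partial budget

Base scenario: 100 cows in production, 5-year horizon, efficiency gains
of a medium-adoption herd. Costs: $700 hardware and $700 software, each
straight-line amortized over 5 years ($140 + $140 per year, independent
of herd size); labor of 7.6 days/year (collection) and 15.2 days/year
(entry and analysis) per 100 cows at $24.7/day, scaling linearly and
continuously with herd size. Income: each trait contributes annual
change × economic value × cows, once per year of the horizon
(non-cumulative accrual — the single most consequential reading of such
budget tables, fixed here because 0.31 kg/yr × $64.6 × 100 cows × 5
years ≈ $10k matches the reference arithmetic, where a cumulative ramp
would give roughly triple). Default changes: DO −1.02 d/yr at −$2.15
per day; DMY +0.31 kg/yr at $64.6 per kg (economic values are inputs
from an external bio-economic model; they are not re-derived here).
Annual changes can instead be estimated as the OLS slope of fitted
marginal means over the first five follow-up years.

All arithmetic stays unrounded internally; whole-dollar rounding is
applied only when formatting reports. GM = ΔI − ΔC and MRR = 100·GM/ΔC
hold as exact identities of the result object. The break-even herd size
is the smallest integer n with GM(n) ≥ 0, computed in closed form
(⌈fixed costs / per-cow margin⌉) and cross-checked by exhaustive sweep;
with the defaults it is 17 cows.

## Sensitivity analysis

The scenario table re-evaluates the budget one input at a time at ±10 %:
the two trait changes, herd size, the two labor day-rates, and the
combined hardware+software investment. For days open — an improvement
by *reduction* — the "−10 %" label strengthens the improvement
(−1.02 → −1.12 d/yr), keeping the table's direction semantics uniform.
Since GM is affine in every varied input, the +/− deltas are exactly
antisymmetric, which the tests assert to machine precision. The
combined hardware+software perturbation moves the 5-year margin by $140;
published counterparts of this row are internally inconsistent (a $70
effect against a "$630" base), so it is reported but treated as
qualitative only.

The Monte-Carlo analysis draws all inputs jointly and independently —
by default uniform on ±10 % around base, n = 10,000, fixed seed — and
reports Pearson correlations of each input with GM and MRR. The
sampling distributions behind any published correlation magnitudes are
not recoverable, so only the sign/rank pattern is meaningful: the
milk-yield change dominates, herd size is second, all cost inputs
correlate negatively. Degenerate (zero-variance) inputs report an
undefined correlation rather than 0.

## Problem sizes and numerical choices

The calibration experiments run at deliberately compact sizes chosen to
give stable statistics: parameter recovery uses 100 replicates of 300
herds × 8 years (coverage of each generating quantity — zone contrasts,
level offsets, per-level slopes via linear contrasts, σ²_between, ρ —
counted against 95 % Wald intervals), null calibration 100 replicates
of 150 herds × 6 years, and the generator-deriver consistency check 20
herds × 5 years at 10/50/200 cows. REML optimization works on
unconstrained transforms with three starts; convergence failures are
flagged on the results object, never silent. Ties or gaps in follow-up
years enter the AR(1) correlation at the power of the actual year gap.

## Known limitations

* No denominator-df (Kenward–Roger/Satterthwaite) corrections; small
  herd counts (tens of herds) will show mildly anticonservative fixed-
  effect tests.
* The lognormal zero-offset makes geometric means offset-dependent when
  zeros occur; the offset is reported alongside the fit.
* Marginal means after aliased-column dropping are means of the
  constrained model, not of the full factorial.
* The generator's one-purpose-per-animal design cannot exercise
  multi-lactation attribution logic beyond one health event per
  lactation.
* Economic conclusions inherit the partial-budget frame: no discounting,
  no financing, no risk aversion, and trait changes assumed constant
  over the horizon.
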