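# Methods

## Model overview

`sprayrisk` chains three deterministic stages on a daily grid of
1..`days_of_year` (up to 3 × 365 days):

1. **Exposure.** For each application event the crop interception factor
   (CIF, %) is read from the croptab row whose BBCH range contains the
   event's stage — a pure table lookup, no interpolation, and a stage not
   covered by any range is an error rather than an extrapolation. The
   initial concentration is
   `PIEC = AR · (1 − CIF/100) / (100 · d · p)` with AR in g a.i./ha
   (the scenario table carries kg a.i./ha; the ×1000 conversion happens when
   the exposure parameters are assembled, never inside the formula), d the
   mixing depth in cm and p the bulk density in g/cm³. The denominator's
   factor 100 is the unit conversion: 1 ha mixed to d cm at density p is
   100·d·p tonnes of soil, so the formula is the only dimensionally
   consistent reading that yields mg/kg and the documented 2.5× ratio
   between the 1 cm and 2.5 cm depths.
2. **Degradation.** Single first-order kinetics with
   `k = ln2 / DT50s` and `DT50s = DT50soil · F · exp(Ea/R · (1/T − 1/Ts))`.
   The exponent's sign is the one that follows from
   `k = A·exp(−Ea/(RT))`: cold months *lengthen* the half-life. k is
   piecewise constant per calendar month; the step from day t−1 to day t
   uses the month of day t−1 (the day the residue actually sat in soil).
   Within a month this choice is invisible — consecutive daily ratios are
   constant — and only month-boundary steps depend on it.
3. **Mixture risk.** Per day and event, ETR = PEC/endpoint (LC50 acute,
   NOEC chronic) and TER = endpoint/PEC; ETRmix is the daily toxic-unit sum
   and TERmix = (Σ 1/TER)⁻¹, algebraically 1/ETRmix wherever exposure is
   non-zero. Zero-exposure days carry TER = +∞ (they drop out of the
   mixture sum and clip cleanly on log-scale plots). Exceedance intervals
   are the maximal runs of days with TERmix strictly below the threshold;
   equality counts as compliant because TER ≥ threshold is the regulatory
   acceptability condition.

Events — not substances — index the result columns: the same active
ingredient applied on two dates occupies two columns, and the cumulative
series is the plain row sum (so tank mixtures need no special casing; the
per-event column holds exactly the PIEC on the application day and the
pre-existing residue lives in its own column). Decay of a fresh pulse
begins the day after application.

## Parameters and defaults

| parameter | unit | default | why |
|---|---|---|---|
| bulk density p | g/cm³ | 1.5 | standard dry-soil value of screening-level persistence models |
| activation energy Ea | J/mol | 54 000 | conventional average for pesticide soil degradation |
| gas constant R | J/(mol·K) | 8.314 | physical constant |
| reference temperature Ts | °C | 20 | the temperature soil half-lives are conventionally reported at; configurable |
| Kfoc depth switch | L/kg | > 500 (strict) | "above 500" read strictly: exactly 500 takes the 2.5 cm default |
| acute TER threshold | – | 10 | EU uniform-principles convention; configurable, echoed in every report |
| chronic TER threshold | – | 5 | idem |
| degradation factor F | – | 1 | per-application half-life multiplier; 1 = use the database value |

The calendar is a fixed 365-day non-leap year, recycled for multi-year
horizons; julian application days are cross-checked against the declared
application month at load time. Monthly temperatures may be one recycled
12-value set or one set per simulated year.

## Numerical choices

* Concentrations are never rounded, floored or clipped: the decay tail is
  meaningful at arbitrarily small magnitudes and result CSVs are written
  with shortest-round-trip floats (read back with
  `float_precision="round_trip"` for lossless recovery).
* Imputation of a missing substance property uses the arithmetic mean of
  all *other* substances sharing the chemical class, falling back to the
  agricultural use; no donor at either level is a hard error, and each
  imputation is logged with its provenance ("class-mean"/"use-mean").
  Kfoc is imputed by default as well — the variable-depth rule needs it —
  but `--no-impute-kfoc` restricts the routine to degradation and toxicity
  values. The imputed mean always lies within the donor range.
* NOEC > LC50 is unusual but not forbidden; it raises a warning, never an
  error.
* Sub-zero months: the Arrhenius correction is applied as-is by default;
  the optional `--freeze-stop` flag sets k = 0 at T ≤ 0 °C for users who
  prefer the frozen-soil convention.
* Same-day events are ordered as listed; reordering them cannot change any
  reported quantity (columns are independent, the cumulative sum is
  commutative).
* Scaling every application rate scales every concentration linearly; this
  is bit-exact in the normal IEEE range and only drifts by ulps in the
  subnormal tail (< 1e-290 mg/kg, far below any physical meaning).

## The synthetic-data generator

`sprayrisk.fixtures` produces complete, self-consistent table trios so the
whole pipeline is testable without external data.

* `make_fixture(FixtureSpec(...))` draws substances (DT50 5–60 d, Kfoc
  50–1500 L/kg, LC50 50–1500 and NOEC 1–50 mg/kg dw), a five-range apple
  interception table, and a spray series of uniformly drawn days between
  day 60 and day 300 with rates of 0.2–3 kg a.i./ha under a temperate
  north-German monthly temperature profile. Identical specs (including the
  seed) yield byte-identical files. A ground-truth sidecar stores each
  event's intended PIEC, its per-month rate constants and the analytic
  series computed via the closed form c₀·exp(−Σk) — an independent path
  against which the daily stepping engine is verified to 1e-10 relative.
  Optional missing-value injection blanks substance properties to exercise
  the imputation route, but never removes the last same-class holder of a
  field, so every generated gap is recoverable; corruption flags
  (`month-mismatch`, `count-mismatch`, `unknown-compound`, `blank-cell`)
  produce deliberately invalid scenario tables for negative tests.
* `make_reference_apple_scenario()` rebuilds a six-application apple series
  whose output matches a published example excerpt: half-lives are
  *back-solved* from consecutive printed concentrations (fast substance
  DT50s ≈ 0.124 d, slow ≈ 135.9 d) rather than guessed from property
  databases, temperatures are pinned at the reference temperature (the
  excerpt's constant day-over-day ratios show a constant rate constant),
  and rates/interception reproduce the printed initial values (5.33333333
  and 0.4 mg/kg). The ecotoxicological endpoints of the two substances are
  representative synthetic values — the printed example does not disclose
  its endpoints, so this scenario's risk courses (e.g. its first exceedance
  day) are illustrative, not a reconstruction.

What the generator does **not** emulate: real application calendars and
product-specific rate recommendations, spatial variability of soil and
temperature, official crop-interception value sets (users supply their
own croptab), measured field residues. Passing tests therefore demonstrate
the model's internal correctness — formula implementation, calendar logic,
mixture algebra, file fidelity — not agreement with field data, for which
no validation set exists at this screening level.

## Problem sizes

The bundled scenarios run 2–6 applications over 60–730 days; the oracle
suite checks fifty seeded scenarios of six applications over a full year,
which completes in seconds. The engine is O(events × days) and handles the
maximum three-year horizon without any special treatment.

## Known limitations

* Soil only, earthworm endpoints only; no leaching, runoff, plant uptake or
  porewater partitioning (Kfoc enters solely through the mixing-depth
  switch).
* Single first-order kinetics; no bi-phasic models, no moisture correction,
  no metabolites.
* Concentration addition only; no independent action or synergy models.
* Interception is a step function of BBCH; no within-stage interpolation.
* A liquid spray formulation is assumed throughout.
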