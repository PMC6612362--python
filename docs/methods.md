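# Methods

## Conversion model

All conversions route through the oral-morphine-equivalent (OME) hub: each
preparation (drug, route) carries one positive factor `f` = mg of oral
morphine per 24 h equivalent to one unit dose, anchored by the invariant
`f(morphine, oral) = 1`. A conversion is `d · f_index / f_target`. The hub
was chosen over a dense pairwise ratio matrix because it makes identity,
inversion and transitivity exact by construction; the pairwise formulation
survives only as the independent test oracle, which recomputes every
conversion as a single ratio expression and re-implements patch selection
as a scan over band upper bounds.

Units are fixed by route — mg/24 h for oral and subcutaneous, µg/h for
transdermal — so a unit mix-up cannot be expressed in a request, which is
the error class the tool exists to prevent. Dose arithmetic uses
`decimal.Decimal` throughout: factors, doses and band bounds are exact
decimals, and band-border comparisons are exact equality on the decimal
representation, never epsilon comparisons on binary floats. The border
case is clinically meaningful and must not depend on representation.

## Patch bands and the tie rule

A patch table is an ordered list of inclusive OME ranges mapped to
strengths; adjacent bands may share a border (`ome_high` of one equal to
`ome_low` of the next). The selection rule is: the band containing the
OME, with shared borders resolved to the **lower** strength. Rounding up
at a border is a real defect observed in a deployed converter of this
kind, where it produced every mismatch in an accuracy audit; the defect is
retained behind `TieBreak.UP` purely as a mutation harness so tests can
show that enabling it breaks exactly the border-exact requests and nothing
else. Below the smallest band no patch is recommended (warning
`below_smallest_patch`); above the largest band the largest strength is
returned with `above_largest_patch` rather than an error, since
combination patches are real practice — the warning keeps the tool honest
without guessing.

Transdermal preparations as the *index* of a conversion require an
explicit patch→OME factor in the formulary; F1 deliberately ships none, so
patch-as-index requests surface `no_guideline_equivalence` rather than an
invented midpoint of the band range.

## Rounding, breakthrough, warnings

Practical rounding floors to the route's increment (safety direction,
consistent with the patch tie rule), with one exception: a positive dose
is never rounded to zero. If flooring would erase the dose, the minimum
increment is returned and a `large_dose` warning flags the large upward
relative change. The same warning code fires when the OME exceeds an
optional formulary threshold (`large_dose_ome_threshold`, absent in F1).

Breakthrough dose = regular 24-h dose ÷ divisor. The divisor is formulary
data, default 6 (the conventional one-sixth of the daily dose in
palliative practice). Transdermal routes are refused with a directive to
convert the patch to its 24-h oral equivalent first.

Renal caution fires only when an eGFR is supplied, is below the formulary
threshold (default 30 mL/min, the usual severe-impairment boundary), and
the drug is flagged `renal_risk`. An absent eGFR produces no warning: the
tool reports what the data shows and does not nag on missing data; this is
a deliberate open choice, documented rather than hidden.

Conversion ratios, patch tables, divisors and thresholds live exclusively
in the formulary file — guideline revisions must never require code
changes. The fixture formulary F1 uses round numbers (factors 0.1–30,
patch bands 30–270 mg OME at strengths 12/25/50/75/100 µg/h) chosen so
every hand check is mental arithmetic and so the values cannot be mistaken
for clinical guidance.

## Audit log and analytics

The log is append-only JSON-lines with a closed schema: unknown fields are
rejected by name, the only categorical context field (`indication`) is
drawn from a fixed list, and record ids are gapless positive integers. A
local file replaces a cloud capture database — the same data contract with
no infrastructure dependency. Corrupt lines are quarantined and counted,
never silently dropped.

Usage analytics tally index and target opioids over drug-to-drug records
(breakthrough separately) and maintain the conservation law that both
tallies sum to the drug-to-drug count. Accuracy analytics exclude every
record whose status is not `ok` (endpoints without guideline equivalence
cannot have a gold answer), then compare each remaining record's final
practical dose — post-rounding, since rounding is where deployed tools
have actually diverged from guidelines — against an independent
gold-standard oracle. The match rate is `100 · matched / analysed`,
rounded half-up to one decimal; with nothing analysed it is reported as
absent, never 0.

## Trend test

`cochran_armitage_trend` computes the linear trend statistic for a 2×k
ordered table, `T = Σ s_i · b_i` over the post row, standardised by the
exact conditional (hypergeometric, N−1 denominator) mean and variance, so
Z is measured against the permutation-on-margins null. Positive Z means
the post row shifts toward higher scores. Two p-values are offered:

* `p_method="normal"` (default): two-sided, uncorrected normal
  approximation — the convention whose Z/p pairs survey reports print;
* `p_method="exact"`: full enumeration of the conditional null and the
  two-sided mid-p, `P(|T−E| > |t|) + ½·P(|T−E| = |t|)`, computed in exact
  integer arithmetic. The mid-p is the discrete quantity the uncorrected
  normal approximation estimates.

The distinction matters for testing: on 2×4 tables with ~60 subjects the
normal approximation deviates from the discrete permutation null by up to
a few hundredths — orders of magnitude beyond the Monte-Carlo error of a
10⁵-resample oracle — so oracle agreement is asserted for the exact mid-p
(enumeration vs an independent multivariate-hypergeometric resampler) and
for Z (analytic moments vs brute-force moment estimates), while the normal
p remains the default reporting convention.

## Synthetic data

The request generator (`FixtureSpec` / `generate_requests`) draws from
F1's preparations with doses on practical grids (oral 10–240 mg/24 h in
5 mg steps; subcutaneous 5–120 mg/24 h in 2.5 mg steps), inserting exact
rounded counts of no-equivalence pairs, methadone requests, border-exact
patch conversions and breakthrough calculations. It uses Python's
`random.Random` (Mersenne Twister), a named PRNG stable across platforms.

The pilot replay (`generate_pilot_accuracy_log`,
`generate_pilot_usage_log`) reproduces the *structure* of a five-month
prescribing audit: 210 drug-to-drug + 76 breakthrough calculations, 18
conversions lacking equivalents, 10 border-exact patch conversions, and
per-drug index/target tallies summing to 210 on both sides. What is
emulated is the arithmetic surface — counts, exclusions, the defect
mechanism — not the clinical case mix: real dose distributions, prescriber
behaviour and the actual guideline ratios are not modelled, so passing
tests validate the engine's and analytics' correctness, not any clinical
accuracy claim about real data. Problem sizes used by the tests and
acceptance script (1,000-request property batches; 286-record replays;
20 trend tables at 10⁵ resamples) were chosen to exercise every code path
while keeping the whole suite under a few seconds.

## Numerical and degenerate-input choices

* Exact Decimal equality for band borders and oracle agreement; the
  algebraic property tests use a 10⁻⁹ relative tolerance only because
  Decimal division is finite-precision (28 significant digits).
* `round_practical` never returns zero for positive input (see above).
* Empty patch table, non-positive doses, negative eGFR, single-category or
  zero-variance trend tables are contract errors, raised not coerced.
* Percentages are rounded half-up (not banker's rounding) to one decimal,
  matching audit-report convention.

## Known limitations

* No cross-tolerance reduction on rotation: conversion is not simply a
  mathematical exercise and dose reduction on switching is a clinical
  decision; the tool deliberately does not auto-reduce.
* No patient factors (tolerance, frailty, hepatic function, sequencing);
  no methadone; no paediatric or acute-pain dosing.
* The formulary schema supports direction-specific factor overrides only
  insofar as a deployment encodes separate preparations; true asymmetric
  dosing advice is out of scope.
* F1 is a test fixture. Nothing in this repository encodes verified
  clinical conversion values.
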