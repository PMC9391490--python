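# Methods

## Chronology model

One von Ebner line per day is the identity the whole package rests on:
the age of a tooth in days equals its increment count from the pulp
cavity to the exterior, and the replacement rate of a tooth family is the
difference of two such counts. This holds when dentine deposition is
continuous (no metabolic shutdowns) and the section crosses every lamina
once; both assumptions are taken as given for the subadult/adult material
the method targets.

### Readable runs and gap extrapolation

Transects store boundary positions in µm, pulp cavity → exterior, 0-based
at the pulp-cavity edge. Unreadable intervals are recorded as open gaps
that contain no boundary. The mean daily width is measured on the longest
gap-free run (span divided by increments in the run); among equally long
runs the pulp-proximal one is used — an arbitrary but deterministic
tie-break. Each gap then contributes `round_half_up(gap_length / w̄)`
extrapolated lines. The published protocol does not state how unreadable
stretches entered the reported totals; extrapolation by mean width is
this package's reconstruction of intent, and extrapolated counts are
carried separately and flagged in every downstream table rather than
merged into observed counts.

Widths outside the 1–30 µm plausibility band for amniote daily increments
are flagged via `out_of_range_fraction` but never dropped: an out-of-band
width is usually evidence about the section (obliquity, missed lines),
not about the tooth. One source table prints the band's upper bound in mm;
it is treated as a typographical slip for µm. Oblique sectioning inflates
apparent widths by `1/cos(angle)`; `deoblique_width` inverts this exactly,
and the correction is validated by round-trip against the simulator's
obliquity noise.

### Replacement-rate estimators

Dispatch order for a family: preserved replacement tooth → direct
subtraction against the *oldest* (immediate successor) replacement, the
definition-consistent choice when two replacement teeth are present;
otherwise resorption pit + apex profile → the ⅔-height overlay estimator;
otherwise a minimum-rate lower bound equal to the functional tooth's age,
with `is_minimum` propagated through every summary (minima are excluded
from group means, kept in ranges with a lower-bound annotation, and
excluded from rate ASR).

The RP estimator counts profile entries with cumulative height ≤ the
estimated crown height, inclusive at exact equality ("the last line
within" the overlay) — a deterministic boundary convention. The
dentine-extent estimator is implemented as *radial* dentine extent ÷ mean
line width; the literal 2-D-area reading is rejected because the units
only balance for a linear extent.

All reported rates are integer days, rounded half-up; fractional
intermediates are kept internally. `functional_period` (shed-tooth age
minus mean attachment-stage age) rounds the same way, which is how a
227-day shed tooth against attachment ages {106, 135} gives 107 days
while the single-baseline reading 227 − 135 gives 92; both baselines are
exposed, neither privileged.

### Known fixture discrepancies

The packaged count table carries two rows whose published rate is
inconsistent with its own published inputs (one subtraction off by six
days; one family attribution that contradicts the arithmetic). These rows
carry an `expected_discrepancy` flag; regression tests assert the
recomputed value and the published value separately and never force
agreement. Taxon-level averages whose underlying family counts were never
published are stored as overrides and not asserted against recomputation.

## Comparative layer

**Diet summaries** report n, mean, min, max per diet category and trait,
with minima handled as above.

**Mass association**: Pearson correlation of log₁₀ body mass against
replacement rate. Masses span four orders of magnitude and n ≈ 11, so
significance comes from a permutation null: exhaustive over all n!
orderings when n ≤ 7 (p is then exact), else Monte Carlo with a seeded
generator and the add-one estimator `(1 + hits)/(1 + B)`. Two-sided via
|r|. Degenerate variance raises rather than returning NaN. The packaged
body masses are package-estimated inputs (order-of-magnitude placements
consistent with skeletal size), not published measurements; the
non-significance regression is a fixture property, not a claim about the
published masses.

**Ancestral states**: maximum-likelihood states under Brownian motion by
two passes of Gaussian message passing (tip-to-root conditional means and
variances; root-to-tip combination with the rest-of-tree message). The BM
rate σ² cancels from the state estimates and is not reported. The
implementation is checked in the test suite against an independent GLS
closed form (re-rooted covariance algebra by direct `numpy.linalg.solve`)
to 1e-9 on random ≤ 8-tip trees, and agrees with R's
`phytools::fastAnc` on spot checks. Node states of a BM ML
reconstruction always lie within the tip range; branch gradients are
linear interpolations at interior fractions i/(k+1), endpoint-free, for
contMap-style rendering.

**Packaged tree**: `synthetic_amniote_tree.nwk` is a synthetic,
topology-faithful reconstruction of early-amniote relationships
(parareptile + eureptile reptiles with nested varanids; caseid,
edaphosaurid, sphenacodontid and varanopid synapsids; a seymouriamorph
outgroup) with branch lengths in Ma set from stratigraphic first
appearances. It is a stand-in for a figure-level tree whose branch
lengths were never published numerically; no analysis asserts against it
numerically, and ancestral-state outputs on it are illustrative.

## Synthetic dentine generator

Defaults define the study conditions: lognormal daily widths with mean
12 µm/day (mid-band; a large-predator regime of 10–16 µm is "thick" by
comparison) and cv 0.2; a constant 8 µm crown-height contribution per
line, making the apex profile linear — no quantitative crown geometry was
published, so the simplest monotone model is the default, with a
decelerating alternative (`decelerating_height`) for mis-specification
tests; a true replacement interval of 105 days; resorption-pit growth
linear at 1.5 × the per-line height, which makes the ⅔ rule exactly
calibrated under the default geometry (so the estimator's intended logic
is testable in isolation), with `rp_miscalibration` to break the
calibration deliberately. Measurement noise is separate and composable:
per-boundary dropout probability (merging adjacent increments), obliquity
scaling, order-preserving position jitter, and gap masking whose gap
endpoints sit on the flanking retained boundaries (so extrapolation is
testable for bias). All randomness flows through one seeded numpy
generator; identical parameters + seed give bit-identical output. The
replacement-wave schedule (odd/even positions offset by half the
interval) is deterministic by construction; its seed argument exists only
for interface uniformity.

What the simulator does *not* emulate — and hence what passing recovery
tests do not show about real fossils: ontogenetic and seasonal rate
variation, curved or tapering crown geometry beyond the two height
models, spatially correlated preservation damage (dropout is i.i.d.), and
any real resorption-pit geometry (the linear model is a stand-in; all
recovery tolerances refer to it).

## Problem sizes and numerical choices

Recovery experiments default to 50–200 replicates per condition with
functional ages between interval+30 and interval+230 days — enough for
stable bias/RMSE medians while keeping the full suite and the acceptance
script in the seconds range. Half-up rounding everywhere a day count is
reported; inclusive overlay boundary; pulp-proximal run tie-break;
permutation ties counted with a 1e-12 guard so the observed labelling
always counts itself. Degenerate inputs (single-boundary runs, empty
attachment lists, zero-variance correlations, missing tip values,
non-positive branch lengths) raise typed errors rather than propagating
NaN.

## Known limitations

Line counts are taken as exact day counts; observer miscounting is
representable only through the dropout/jitter noise model. The RP
estimator's accuracy statement is conditional on the simulator's pit
geometry. The comparative analyses inherit the packaged masses and tree,
both package-constructed; conclusions drawn from them are regression
anchors for the code, not biological inference.
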