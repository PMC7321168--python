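# Methods

This note records the statistical machinery the package implements, the
defaults and why, and the design choices made where more than one
convention was defensible.

## Designs and coding

All models are fitted on *coded* factors: the affine map sending a
factor's studied range [low, high] to [−1, +1] (midpoint → 0).  Coefficient
magnitudes are then directly comparable across factors regardless of units,
which is what makes a coefficient plot meaningful.  Natural-unit values are
a view derived through the factor specs; round-trip coding is exact to
floating precision and is property-tested.

The fractional-factorial generator builds the full factorial in the first
k − g factors (standard Yates order) and defines each remaining factor as a
product of base factors.  For the 6-factor, 2-generator case the catalogue
uses x5 = x1·x2·x3, x6 = x2·x3·x4 — a standard minimum-aberration,
resolution-IV choice: no main effect is aliased with any two-factor
interaction, verified exhaustively over all signed column products.  The
published screening table is shipped verbatim and is the fixture of record
for all fitting; the generator serves new studies and simulations.  Centre
points are appended after the factorial rows; run randomisation is a
bench-execution concern that does not affect least squares and is not
modelled.

The CCF generator emits the 2^k cube, the 2k face-centre axial points and
the requested centre replicates; every coordinate is in {−1, 0, +1}, so the
design never leaves the already-studied cube.  Rows are classified as
centre/axial/cube with a |coded| < 1e−6 tolerance.

## Model fitting and reduction

Each response is fitted independently by ordinary least squares on the
polynomial model matrix (statsmodels OLS under the hood).  A rank-deficient
matrix — e.g. quadratic terms requested on a two-level design — is rejected
with the inestimable terms named, by greedy rank inspection of columns in
spec order.  A saturated fit (runs = terms) is allowed: it interpolates,
its residual scale is zero, and leave-one-out statistics are refused via
the leverage-1 guard.

Backward elimination removes one term per refit — the highest p-value above
α (default 0.05) — never the intercept and, with hierarchy preserved (the
default), never a parent of a retained higher-order term (a quadratic
requires its linear term; an n-way interaction requires all lower-order
sub-products).  The removal sequence with p-values is recorded on the
reduced results object.  Note the statistical fact that at α = 0.05 each
spurious term still survives a step with probability ≈ α no matter how
strong the true signal is, so exact recovery of a true model with two
spurious terms happens in about (1 − α)² ≈ 90% of replicates — the property
suite asserts that rate, not an idealised one.

## Diagnostics

* R² = 1 − SSE/SST and adjusted R² with mean-corrected SST.
* Q² (predicted R²) = 1 − PRESS/SST, with PRESS from the leverage shortcut
  Σ(eᵢ/(1 − hᵢ))².  The shortcut is asserted identical (|Δ| < 1e−8) to
  explicitly refitting with each run deleted, on every bundled fit, and
  cross-checked against statsmodels' influence measures.  Q² is not floored
  at zero: worse-than-mean prediction is reported as negative.
* Regression ANOVA: overall F against the intercept-only model.
* Lack of fit: SSE is decomposed into pure error (within groups of runs
  with identical coded settings, detected after rounding to 1e−6 so centre
  replicates form one group) and lack-of-fit remainder;
  F = MS_lof/MS_pe.  Without replicates, or when the model saturates the
  distinct settings, the test is reported unavailable rather than invented.
* Method-validation summaries: percent RSD (100·s/mean, sample sd) and
  percent recovery (100·found/added, two decimals).  The bundled recovery
  table keeps the originally reported recovery column alongside the
  concentration pairs; recomputation from the rounded pairs can differ from
  that column by up to ±0.03 because the original values were evidently
  computed from unrounded concentrations.

Diagnostics on the bundled screening table reproduce the study's reported
R²/adjusted-R²/Q² for all six responses within ±0.005 (printed rounding).
For the response-surface stage the published values belong to reduced
models whose retained terms were not disclosed; the full 11-term fits bound
them from above by nesting, which is what the tests assert.

## Criteria, branches and the sweet spot

Criteria are NMT (≤), NLT (≥) or branched; boundary equality passes ("not
less than 1.8" includes 1.8).  The branched criterion models a peak pair
that can swap elution order: the attribute is signed, and the requirement
is |value| ≥ 1.8 *with a consistent sign*.  Each grid point's branch is
fixed by the sign of the nominal prediction; a nominal prediction of
exactly zero (below 1e−12) fails both branches.

The sweet spot overlays the nominal predictions of all responses on a
rectangular grid (free axes in natural units, remaining factors clamped —
the plotting default is a 101 × 101 2-D slice, and the bundled-study tests
use a 57 × 61 slice chosen so the reported optimum is a grid node).
Overlay classes (all met / exactly one failed / two or more failed) mirror
the conventional green / light-blue rendering.

## Monte-Carlo design space (MODR)

At each grid point the probability that *all* criteria are met is estimated
from seeded draws with two uncertainty sources, individually switchable and
both on by default:

* coefficient vectors ~ N(b̂, s²(XᵀX)⁻¹), one realisation per draw per
  response (responses are independently fitted; no cross-response
  covariance is available, so none is imposed);
* observation noise ~ N(0, s²) per draw — each draw is a new predicted
  observation, which is the question an analyst runs the method under.

Optional setpoint jitter (uniform or normal per factor, shared across
responses within a draw) is off by default since no setpoint tolerance is
part of the bundled study.  Draws use one coefficient ensemble per map,
shared across grid points and processed in memory-bounded chunks; identical
seed and settings reproduce the map bitwise.  The default is the *joint*
probability over all six attributes (a per-attribute-minimum mode exists
for comparison); a draw of a branched response that lands on the wrong side
of zero counts as a failure, because a flipped elution order is a failed
run regardless of magnitude.  The MODR is the region with probability ≥ the
threshold (default 0.99, 10 000 draws; the binomial standard error
√(p(1−p)/n) is reported per point).

The recommended setpoint maximises estimated probability; ties — routine
once the probability plateaus at 1 — are broken by maximising the minimum
*standardised* margin of the nominal predictions, each margin divided by
the prediction standard error for a new observation.  Standardising is
deliberate: raw margins would let the attribute with the largest numeric
scale dominate, and the resulting "optimum" drifts toward regions that are
comfortable on an easy attribute while near-marginal on uncertain ones.
Robust ranges are maximal contiguous 1-D intervals through the setpoint
along each free grid axis, staying inside the MODR with the other factors
clamped — matching the per-factor "robust from … to …" reporting
convention; clamped factors get a degenerate interval.

## Synthetic data

The generator emulates what the regression analysis assumes the instrument
produces: a low-order polynomial truth surface in coded factors plus
independent homoscedastic Gaussian replicate noise.  Default truths are
full-model fits to the bundled tables, so simulations inherit the study's
structure, including the sign-flipping R5 surface; the default noise sd per
response is the pooled centre-replicate standard deviation of the
corresponding table — the study's own replicate-error estimate.  What the
generator does *not* emulate: retention physics, peak-shape distortion,
heteroscedastic or drifting noise, and correlated errors across responses
measured on the same injection.  Passing simulation-based tests therefore
demonstrates correctness of the statistical machinery under its own
assumptions, not robustness to real chromatographic pathologies.

A handful of bundled response entries are exactly 0.10 — a
"no measurable separation" floor, not a measurement.  They are kept as
numeric values (as the original analysis evidently did) and flagged by
`floor_mask`.

## Problem sizes and numerical choices

Bundled-study computations are small (19- and 17-run OLS fits).  The
design-space tests use a 57 × 61 slice × 10 000 draws (seconds on one CPU);
simulation-based property tests use 200–500 replicates.  Tolerances:
printed-table reproduction ±0.005 (one rounding unit); oracle equivalences
1e−8 to 1e−12; Monte-Carlo comparisons within 3–4 binomial standard errors.
Ties in elimination p-values are broken by pandas' stable argmax (first of
equals in spec order); this only matters for exactly equal p-values, which
do not arise on the bundled data.

## Known limitations

* The original study's reduced-model term sets, Monte-Carlo draw counts and
  uncertainty internals are not public; its printed optima and robust
  ranges are therefore validated by containment (our optimum falls inside
  its printed robust ranges; its optimum falls inside our design space),
  not by exact reproduction.
* Responses are modelled independently; a joint design space under
  cross-response error correlation would be tighter or looser depending on
  the correlation sign.
* Robust ranges are axis-aligned slices, not the largest inscribed box.
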