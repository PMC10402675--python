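# Methods

## Model

The MLC is modelled as a zero-height 2D transmission array in the isocenter
plane (100 cm from the source, perpendicular to the beam axis). Coordinates
follow the IEC 61217 beam's-eye view: x along leaf travel, y across leaves,
everything in cm projected to the isocenter plane. Bank A leaves occupy
`x ≤ tip`, bank B `x ≥ tip`; the classification grid is bounded by the jaw
rectangle of each control point.

For each leaf pair the nominal tips `A, B` are calibrated to
`A′ = A − shift(A)`, `B′ = B + shift(B)` with
`shift(p) = offset + gain·p + curvature·p²`. A positive shift retracts the
leaf. The exact form and sign convention of the vendor's calibration function
are not public; the quadratic-in-position polynomial with retraction for
positive offset is this package's own choice and is isolated in
`calibration_shift` should it need revision.

Per (x, row) the coverage state is:

- `OPEN_NOW` if `A′ < x < B′` **and** `A < x < B`;
- `OPEN_ONLY_AFTER_CAL` if only the calibrated inequality holds;
- `TIP` if `x ∈ [A′ − w, A′]` or `x ∈ [B′, B′ + w]` (tip width `w`);
- `BODY` otherwise.

Open intervals are open and tip intervals closed, so ties resolve
deterministically (a point exactly on a calibrated tip is TIP).

Tongue-and-groove strips of full width `2·tg_width` straddle every *interior*
leaf boundary (the outermost edges of pairs 1 and 60 generate no strip).
A strip point is labelled from the coverage states of **both** adjacent rows
at the same x: both open-type → the own row's open label (OPEN or
CALIBRATION); both covered → PAIRED; open + body → EXPOSED; open + tip →
NEGLECTED. The neighbor-based rule governs the whole strip — the alternative
of freezing open/tip points before strip resolution would make the NEGLECTED
zone unreachable, contradicting its stated transmission of 1. Neighbor states
use the unclipped leaf geometry; only the grid itself is clipped by the jaws.

## Sampling and numerics

Samples sit at cell centers `x_k = jaw_low + (k + ½)·spacing` (default
spacing 0.01 cm), so no sample lies on a jaw edge and the zone partition is
exact: the seven counts always sum to `n_x·n_y`. Zone fractions carry an
O(spacing) boundary error (verified empirically by halving the spacing on
the validation beams); jaw widths are assumed to be integer multiples of the
spacing, which the synthetic generators guarantee by rounding jaws to
0.1 cm and leaf tips to 0.01 cm. The classifier is vectorized: a
(pairs × n_x) coverage-state matrix is expanded to the full grid by row
lookup, with strip rows patched by the neighbor rule; a 30 × 30 cm² field at
0.01 cm spacing (9 × 10⁶ points) classifies in well under a second.

The independent oracle (`analytic_gpf_oracle`) never scans a 2D grid: per
leaf row and strip it builds the exact x-breakpoint decomposition
(`{A, B, A′, B′, A′−w, B′+w}` clipped to the jaws), assigns each elementary
interval its zone by a midpoint predicate, and counts the cell centers inside
by binary search; y bands (row cores and strips, with the open/closed edges
implied by the strict strip inequality) are counted the same way. Because
both paths compare the identical floating-point center coordinates against
the identical breakpoint expressions, agreement is limited only by floating
point — the validation suite reproduces bit-identical fractions, comfortably
inside the 1 × 10⁻⁶ acceptance bound. An area-based variant
(`analytic_area_fractions`) replaces counts by interval lengths and serves
only for convergence studies. The oracle requires static, axis-aligned
apertures and `2·tg_width` below the narrowest leaf row.

## MU weighting

Cumulative meterset weights map to per-control-point MU by forward
difference: the fluence between shapes i and i+1 is attributed to shape i and
the terminal control point carries zero MU (matching step-and-shoot
semantics, where the segment shape is the earlier control point). The
convention is switchable (`forward | backward | midpoint`); all three
conserve the beam meterset. Zero-MU control points are classified and
reported but contribute nothing to the averages; consequently it is
immaterial whether the terminal control point is "included" in the average.
Plan-level averages pool all control points directly rather than averaging
per-beam averages, which matters only when beams have unequal metersets and
is the form the weighted sum naturally takes. A control point with a fully
closed aperture (zero open fraction) but nonzero MU makes the normalized
average undefined; this raises by default and is downgraded to
warning-and-exclusion by `skip_closed`, because silently dropping control
points changes the effective N.

## QA statistics

MDD uses the measured distribution for the 50 %-of-maximum mask (the
reference is switchable to the calculation), takes the median of pointwise
ratios (mean of the two central values for even counts), and reports
percent. The slope test is simple OLS with residual-variance standard error,
`t = slope/SE` on n − 2 degrees of freedom, two-sided p; `scipy`'s
`linregress` provides the engine and an independent closed-form
implementation cross-checks it in the tests to 1 × 10⁻¹⁰ relative. Raw
p-values are reported across the 7-zone × 2-metric grid without
multiple-testing correction, and this is documented rather than corrected
because the per-zone regressions are exploratory, not a joint test.

## Synthetic data

`make_validation_plan` reconstructs the hand-checkable suite: a 30 × 30 cm²
jaw field with all pairs closed at the field center and the bank-A leaf of
an innermost 0.5 cm pair retracted by 0.5 cm (which leaf is retracted is not
uniquely determined by the construction; the pair spanning [0, 0.5] cm is
used), plus centered MLC squares of 1–28 cm with jaws fixed at 30 × 30 cm²
for every beam (fixed jaws are assumed for the whole suite; only the first
beam's jaws are forced by the construction). For odd side lengths the
retracted rows overshoot the square in y, since leaf edges sit on a 0.5 cm
raster; both classifier and oracle see the same geometry, so validation is
unaffected.

`make_random_vmat_plan` emulates a clinical VMAT arc only in the respects
the metrics consume: random jaw rectangles, leaves random-walking smoothly
between control points (closed pairs allowed, no interdigitation or
leaf-speed constraints), strictly increasing cumulative weights. It does not
emulate deliverability, gantry dynamics or realistic fluence modulation, so
tests passing on these plans demonstrate correctness of the decomposition
and statistics, not clinical realism of the cohort.

`simulate_dqa_cohort` draws `MDD = intercept + Σ_z slope_z·GPF_z + N(0, σ)`
with defaults σ = 0.5 % and intercept 0 (the observed clinical MDD range is
roughly −2 % to +1 %), and gamma pass % from a normal (mean 96, SD 3)
truncated to [0, 100] and independent of the metrics — mirroring the null
relationship between gamma and aperture metrics. The closed loop
(simulate → correlate) recovers slopes exactly at σ = 0 and with nominal 95 %
CI coverage at σ > 0.

## Problem sizes

The test suite runs the full 29-beam validation comparison at 0.02 cm
spacing and a 3-beam subset at the production 0.01 cm spacing; statistical
calibration uses a 24-plan design (1 beam × 6 control points each, 0.05 cm
spacing) with 100 coverage replicates and 1000 null replicates. The
acceptance script classifies 60 control points at 0.02 cm spacing. These
sizes keep the whole suite in the seconds-to-a-minute range while exercising
every code path at the production spacing at least once.

## Known limitations

- The calibration polynomial's form/sign is an assumption (above).
- Leaf divergence, finite leaf height, source size and rounded-tip physics
  are outside the zero-height model by construction.
- Only the RayStation-style seven-zone scheme is implemented; other TPS
  schemes would slot in at the `coverage_state`/strip-rule layer.
- Gamma pass % is consumed as an input; computing it from dose grids is out
  of scope.
- The oracle does not support dynamic (per-control-point-varying) apertures;
  it exists to validate the grid classifier on static fields.
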