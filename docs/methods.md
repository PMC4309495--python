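# Methods

## NO-release kinetics

The kinetic stage models the NO concentration in the medium of an open
tissue-culture well after adding a NONOate donor. Assumptions:

* The donor decomposes first-order with rate constant k₁ = ln 2 / t½; each
  molecule releases n NO (n = 2 by default). Temperature and pH dependence
  of the decomposition are folded into the supplied half-life.
* NO is removed by (a) autoxidation, rate f·k₂·[NO]²·[O₂] with k₂ =
  1.36×10⁷ M⁻² s⁻¹ and f the stoichiometric factor (default 4, for
  4NO + O₂ → products); (b) first-order mass transfer into the NO-free
  headspace, k_out = k_L·A/V; and optionally (c) first-order cellular
  consumption k_c (default 0). With k_c = 0 the predicted concentrations are
  upper bounds when consuming cells are present.
* O₂ is held constant at 0.21 mM (air-equilibrated reservoir); O₂ depletion
  is not modelled. At picomolar NO the autoxidation term is ~10³-fold below
  the mass-transfer term, so predictions are insensitive to f; f is exposed
  as a parameter rather than hard-coded so the sensitivity can be probed.

Key parameters and defaults (units): O₂ 2.1×10⁻⁴ M; k₂ 1.36×10⁷ M⁻² s⁻¹;
f 4 (dimensionless); k_L 5.6×10⁻⁴ cm s⁻¹ (minimally agitated aqueous medium
at 37 °C); well volume in cm³ (≡ mL), area in cm², concentrations molar,
time seconds. `VesselSpec` accepts either an explicit area or a well
diameter (A = π(d/2)²), and k_out may be overridden directly for
sensitivity studies; the provenance record notes which path was used.

Numerics: the donor equation is linear and decoupled, so the donor trace is
emitted from the exact exponential. Only [NO] is integrated, with LSODA at
rtol 10⁻¹⁰ and atol 10⁻¹⁸ M — concentrations sit at 10⁻¹¹–10⁻⁸ M, far below
generic default absolute tolerances — with dense output retained for
off-grid queries. With autoxidation and consumption switched off the
integrator agrees with the closed-form solution of the linear system,

    [NO](t) = n k₁ D₀ (e^(−k₁t) − e^(−k_out t)) / (k_out − k₁),

to better than 10⁻⁶ relative at every grid point; this dual route
(integrator vs closed form) is asserted in the test suite. The degenerate
case k_out = k₁ is rejected rather than handled by the t·e^(−k₁t) limit.
Negative solver excursions beyond ~10³·atol raise an error; smaller ones are
clipped to zero.

Peak reporting: the NO crest is very flat (for 10 nM DETA/NO the linearized
model puts the true maximum near 42 min, with the 50 min value within 0.2%
of it), so the summary reports both the refined peak — grid argmax plus a
local quadratic through the three bracketing points, evaluated on the dense
output — and the concentration at explicit query times. Quantities pinned
at specific times (50 min, 24 h) are preferred over the argmax time, which
is ill-conditioned on a flat crest. Cumulative exposure is the trapezoidal
integral of [NO] over the simulated span.

Standard runs use a 2001-point grid over 24 h (43 s spacing); with the
dense-output interpolation the reported quantities are insensitive to the
grid well below the 0.1% level.

## Colocalization

Manders' M1 = Σ A·[B > T_B] / Σ A is computed on the average z-projection
of each channel, matching common ImageJ/JACoP practice; M2 is the same call
with channels swapped. Thresholding is strictly greater-than, thresholds
are explicit inputs (default 0 for M1's B channel), and no background
subtraction is applied. M1 is undefined (None) when channel A carries no
intensity. Floating-point summation order can push the ratio a few ulps
past 1, so the result is clamped to [0, 1].

AND-overlap counting binarizes both channels at fixed thresholds, combines
them with a logical AND and counts coincident pixels. Because the
acquisition it models works directly on z-stacks, the default mode
binarizes and counts per z-slice and sums; a projection mode is provided
and the mode used is recorded in the result.

## Morphometry

A cell's "overall diameter" is operationalized as the diameter of the
minimal enclosing circle of its above-threshold pixel centers. Manual
practice draws an enclosing circle by eye; the minimal circle is the
reproducible choice and is never smaller than any valid hand-drawn
enclosing circle. Segmentation uses 8-connectivity (thin processes must
stay attached across diagonal steps) and a min_pixels debris filter
(default 20 px). Pixel (row, col) maps to physical µm as
(x, y) = origin + (col, row)·pixel_size.

The enclosing circle is computed with Welzl's randomized incremental
algorithm (expected linear time; inputs over 50 points are first reduced to
their convex hull). The shuffle is seeded from the input size, so identical
inputs give identical output. Every input point lies within the returned
circle to 10⁻⁹ of the length unit. Degenerate three-point subsets
(collinear beyond tolerance) fall back to the widest two-point circle. The
test suite checks the implementation against an O(n³) enumeration of all
pair- and triple-defined circles and against an independent
minimum-bounding-radius routine.

Classification at the cutoff (default 70 µm) is strict: a diameter exactly
equal to the cutoff counts as not above. Cells whose pixels touch the field
border have truncated territories; they are flagged and excluded from
classification by default, with an option to include them. Coverslip
sampling follows the five-field design: one field at the center and four
two field-widths out along perpendicular axes; field positions are
validated to fit inside the coverslip.

## Synthetic data

The colocalization generator builds a two-channel stack from disk-shaped
objects replicated through z (columnar structures — it emulates the
intensity bookkeeping of dual-label stacks, not 3-D object shape). A target
fraction ρ of the channel-A objects is placed inside larger channel-B
disks, the rest well clear of any B signal, plus a few B-only disks so the
B channel is not just the colocalized set. The realized intensity-weighted
overlap is recomputed from the noiseless scene and recorded in the ground
truth, so ρ is exact by construction, before any blur or noise is applied.

Noise is signal-proportional Gaussian (sd = noise_sd·I/signal_level,
clipped at zero): at full signal the sd equals `noise_sd`, and the dark
background stays dark, as photon-shot-noise-dominated fluorescence does.
A frame-wide additive noise floor is deliberately not modelled: with a
mostly-dark field it contributes a half-normal background offset that
biases M1 through the denominator, which is a property of camera noise plus
the absence of background subtraction, not of the estimator under test.
Blur is a truncated Gaussian applied after ground-truth capture; object
spacing scales with blur so blurred A tails do not cross B boundaries.

The arborization generator drops non-overlapping territory circles into a
1 mm² field (rejection sampling, largest first; an overcrowded request
raises an error rather than silently packing less). Each cell is a soma
disk plus k radial one-pixel-wide processes (default 6) whose tips lie
exactly on the territory circle, so the minimal enclosing circle of the
rasterized cell recovers the sampled diameter to within ~2 pixels.
Diameters come from a compact/arborized mixture: fraction `frac_large`
(default 0.28, the control-culture regime) uniform on 75–120 µm, the rest
uniform on 25–60 µm; both ranges sit strictly away from the 70 µm cutoff so
rasterization error cannot flip a cell's class. Because ~67% of a single
1 mm² field would be covered at 200 cells, multi-hundred-cell conditions
are realized as several 40-cell fields aggregated in the five-field
pattern, which is also how real coverslips are sampled. Arbor fields use
plain additive clipped Gaussian noise; threshold segmentation is
insensitive to it at the 5% level.

Both generators are pure functions of their spec including the seed
(bit-for-bit reproducible); seeds are recorded in the ground truth. What
passing recovery tests show: the measurement pipeline is unbiased and exact
on scenes that satisfy its assumptions (separated cells, tips defining the
territory, uniform labeling). What they do not show: robustness to touching
cells, uneven staining, out-of-focus haze or anisotropic PSFs, which real
cultures exhibit and which would require manual curation or richer optics
modelling.

## I/O and CLI

TIFF is the only image format; channel labels and pixel calibration travel
in a `<stem>.meta.json` sidecar rather than TIFF tags. Axis declarations
(subsets of CZYX) are normalized to (channel, z, y, x) on read. Time
courses are CSV (`time_s,donor_M,no_M`, 9 significant digits); scenario
configs are JSON validated against a closed key set (unknown keys are
errors, not warnings). Every CLI run writes a provenance JSON (config echo
plus package version) next to its outputs. Exit codes: 0 success, 2
validation error, 3 numerical failure.

## Known limitations

* No downstream cGMP synthesis/degradation model; the kinetic stage stops
  at [NO](t).
* O₂ depletion, NO electrode calibration and pH/temperature effects on
  donor decomposition are out of scope.
* The morphometry stage does not do Sholl analysis, branch counting or
  process tracing; the territory circle is the only shape statistic.
* Manual circle demarcation by eye cannot be reproduced exactly; the
  minimal enclosing circle is a reproducible surrogate, not a re-creation
  of any particular observer's judgement.
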