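# Methods

## Scattering model and geometry

A flat detector of square pixels sits a distance `L` behind the specimen. A
periodicity `d` scatters at `sin θ = λ/(2d)` into a Debye–Scherrer ring of
radius `r = L·tan 2θ`; per pixel, `q = (4π/λ)·sin(½·arctan(r/L))`. The exact
`2θ` relation is used everywhere — no small-angle approximation — so one code
path serves both the collagen SAXS regime (q ≈ 0.0094 Å⁻¹) and the mineral
WAXD regime (q ≈ 1.83 Å⁻¹). Azimuth χ is counterclockwise from the detector
+x axis in [−180°, 180°), with the tensile axis along χ = 0 unless
configured. Pixels are point-sampled at their centers; the sampling error is
far below the ring width at these scales.

Both rings cannot land usefully on one Pilatus-class detector at 10 keV
(the collagen ring radius is ~43 px at 4 m, while the mineral ring needs
~0.2 m), so SAXS and WAXD are modeled as separate acquisitions with their own
geometries — matching practice, where the two phases are measured on
contralateral bones. A simulated bundle therefore contains the ring(s) that
its geometry resolves.

## Synthetic acquisition (the study conditions)

`TensileTruth` defaults encode the emulated protocol: 0.5 s exposures every
5 s at 10 keV; a fixed per-exposure dose (default 0.5 kGy — beamline flux is
not modeled, so dose-per-exposure is a free parameter) accumulating to the
30 kGy cap, which limits a run to 60 frames; tissue strain held at zero for
5 preload frames (the unloaded reference) and then ramping at 4×10⁻⁵ s⁻¹
toward a 1.5 % failure strain, so acquisition is dose-capped in the default
conditions. Linear phase coupling: the collagen ring sits at
`d₀(1 + s_c·ε_tissue)` and mineral at `d₀(1 + s_m·ε_tissue)`; default slopes
(0.7482, 0.3561) are at the scale reported for healthy young cortical bone.
Unloaded spacings default to literature values, d₀ = 670 Å (collagen
first-order) and 3.44 Å (hydroxyapatite (002)), both configurable.

Detector constants (1475×1679 pixels of 172 µm) are Pilatus-class
implementation choices exposed in `Geometry`. Noise is Poisson on the
expected per-pixel counts; rings are Gaussian in q (σ = 4 % of q₀) over a
flat background (3 counts/px) with peak amplitude `noise_level`
(50 counts/px by default — a realistic photon budget for a 0.5 s exposure of
hydrated bone). Azimuthal anisotropy is `I(χ) ∝ exp(κ·cos 2χ)`: smooth,
normalizable, single-parameter; κ is solved by Brent's method (Gauss–Legendre
quadrature for the P2 integral) so the pattern's P2 equals the programmed
`p2_initial + p2_rate·ε_tissue`. Marker tables encode the strain ramp
analytically (two markers, 400 px gauge, 1 Hz), so the tissue-strain channel
is exact by construction and all recovery error is attributable to the X-ray
channel.

What the generator does **not** emulate: beamline flux and detector gaps,
polarization/solid-angle corrections, specimen-to-specimen biological
variability in the coupling slopes, drift of the beam center, background
scatter structure, or post-yield nonlinearity in the tissue-strain channel.
Passing recovery tests therefore demonstrate that the analysis chain is
unbiased and correctly calibrated under the stated acquisition physics, not
that it is robust to every artifact of real beamline data.

## Calibration and reduction

Beam-center refinement thresholds ring pixels (median + 6·√median), groups
them by a radius histogram, and minimizes the weighted within-ring radial
variance with Nelder–Mead (one relabel pass); synthetic truth is recovered to
≲0.01 px, and the test contract is 0.5 px. The distance comes from the
innermost calibrant ring (silver behenate d₀₀₁ = 58.38 Å by default) via
`L = r/tan 2θ`, with the ring radius refined by an intensity centroid.
A distance or wavelength bias scales all q values by a common factor and
cancels in the strain ratio — which is why ~0.1 % calibration error does not
bias slopes.

Cake integration maps pixels to (q, χ) and averages counts per linear q bin
(800-bin default; the strain pipeline uses 300 bins over a ±15 % window
around the nominal ring). Bins with no pixels are flagged NaN, never
zero-filled; count conservation (`Σ intensity·n_pixels = Σ counts`) is exact
on the selected pixels. The strain sector is ±20° about the tensile axis,
mirrored to the opposite side of the ring (the sector width used in the
emulated experiments is unreported; it is a configurable parameter here).

## Peak fitting and strain

Peaks are fit by nonlinear least squares (Gaussian default, Lorentzian
selectable) plus a linear background, with the position SE from the
covariance. A fit is `converged=False` — never an exception — when the
optimizer fails, the amplitude is indistinguishable from zero (≤ 2 SE or
below a 10⁻⁶-of-scale floor), or the center leaves the window. `d₀` is the
mean over the preload frames; unconverged frames propagate NaN rather than
being interpolated. The collagen phase uses the first-order 67 nm
reflection; higher harmonics can be selected by passing their `d0_nominal`.

## P2 orientation

P2 is the intensity-weighted mean of the second Legendre polynomial with the
sin χ weight of three-dimensional isotropy:
`P2 = Σ I_k ∫(3cos²χ−1)/2·sin χ dχ / Σ I_k ∫ sin χ dχ`, integrated in closed
form over each χ bin (the intensity treated as piecewise constant). This
makes the isotropic anchor exact to machine precision and bounds P2 in
[−0.5, 1] for any nonnegative profile, rather than leaving both at the mercy
of quadrature error. A diffuse isotropic background dilutes P2 toward 0, so
the per-frame orientation pipeline subtracts the mean of two flanking q bands
(clipped at zero) before integrating.

## Pairing, dose, exclusions

Tissue strain is linearly interpolated onto frame timestamps; frames beyond
the CCD record are matched to the nearest sample when within one median CCD
interval and otherwise dropped and counted. Material strains are carried
bit-exactly. The dose ledger excludes frames after the cumulative dose
crosses the cap; specimen exclusion removes any record flagged as slipped,
de-potted, or non-diaphyseal fracture, reports per-reason counts, and is
idempotent.

## Regression and the slope F test

Group slopes pool all specimens' points into one scatter (a per-specimen
averaging mode is deliberately not the default, matching how such scatters
are reported); OLS gives the slope and its SE from residual variance. The
extra sum-of-squares F test compares a common-slope model (separate
intercepts, one shared slope — the hypothesis concerns slopes only) to a
separate-slopes model: `F = (SSE_c − SSE_s)/(SSE_s/(n−4))` on (1, n−4)
degrees of freedom. With noiseless groups of different slopes SSE_s = 0; the
limit is reported as F = ∞, p = 0 rather than an error. On equal designs the
test reduces to the squared two-sample slope t statistic (verified
numerically), and its type-I error at α = 0.0125 is calibrated by
simulation. The slope sum propagates SE in quadrature and classifies the
composite as deficient/balanced/oversumming at ±2 SE around 1; it always
carries a caveat flag because the two phases are typically measured on
contralateral limbs.

## Three-point bending

Stiffness is the maximum slope of a sliding linear fit (window = 20 % of the
record, slid over the region below half the ultimate force — the window is
deliberately as wide as the linear region, since a narrow window's
max-of-noise is biased upward). Yield is a convention, not a measurement:
the default is the offset criterion (the curve's first crossing below a line
at the measured stiffness displaced by 0.2 % of the span), with a 10 %
secant-stiffness-loss alternative; a record that never crosses (brittle) puts
yield at fracture and postyield displacement at 0. Ultimate force is the
maximum load ("fracture force" in some reports names the same quantity);
fracture is the last point before the load collapses below 10 % of ultimate,
and a record that never drops below half of ultimate raises "no fracture
detected". Work is the trapezoidal area to fracture. Material properties use
the hollow-ellipse section: `I = (π/64)(w_o h_o³ − w_i h_i³)`,
`E = kL³/(48I)`, `σ = FLc/(4I)` with `c = h_o/2`.

## Group statistics

Two-way fixed-effects ANOVA with interaction uses Type I sums of squares on
balanced designs (all types coincide there) and Type II on unbalanced ones —
the natural choice when testing main effects in unbalanced factorial data.
Underpopulated cells raise an error naming the cell. Fisher's LSD uses the
ANOVA residual mean square and degrees of freedom; with a single comparison
it equals the pooled two-sample t test. Bonferroni alphas are reported exact
and rounded half-even to three decimals (the convention that prints 0.007
for a 7-way and 0.008 for a 6-way family); the comparison family behind each
m is specified by the user, never inferred from the design.

## Problem sizes and determinism

Every generator is deterministic given its seed, and multi-specimen runs
derive child seeds from a `SeedSequence`. The package's own recovery checks
run three specimens of 60 frames at full detector scale (as in the emulated
protocol); the test suite's coverage property (the fitted 95 % CI covers the
generating slope in ≥90 % of replicates) runs on a 256×256 scaled-down
geometry, which preserves the ring-to-pixel resolution regime while keeping
replication cheap.

## Known limitations

- Per-exposure dose is an input, not derived from flux; only the cumulative
  cap is physical.
- Two-marker gauge strain, not full-field DIC; marker tables are the
  interchange format so real DIC output can be substituted.
- No mixed-effects (per-specimen random slope) regression; pooled OLS
  understates between-animal variance when specimens differ biologically.
- No detector distortion maps, gaps, polarization or solid-angle
  corrections; a rectangular mask is the only masking option.
- The offset-yield convention on structural curves is an approximation;
  yield-dependent quantities (postyield displacement) inherit its bias,
  bounded by the offset displacement itself.
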