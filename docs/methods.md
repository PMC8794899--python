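# Methods

This note documents the models, conventions and numerical choices behind
cdltools, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or the acceptance script
does not itself compute.

## Units and conventions

Lengths are mm, angles degrees, throughout. Angles along the cochlear
spiral are *unwrapped*: 0 at the round window (RW), increasing toward the
apex, typically up to ~900° (2.5 turns). 900° is treated as 100 %
cochlear coverage; it is a configuration constant (`theta_full_deg`), not
a hard-coded number. The Escudé constant 235 is degree-valued — feeding
radians silently inflates CDL by ~50 %, which is why the estimator
signatures name the unit.

## Canonical modiolar frame

All geometry operates in a canonical frame: the modiolar (spiral) axis is
z, the RW sits at polar angle 0, and the trajectory winds
counter-clockwise in xy. Two published conventions — "axis through the
modiolus" and "basal turn in the xy-plane" — are *incompatible* for a
pitched spiral: the best-fit plane of one helix turn is genuinely tilted
relative to the helix axis. cdltools resolves the conflict in favour of
the axis: after alignment the axis is exactly z, and the basal-turn plane
is within the pitch-induced tilt (~2° for 1 mm rise per basal turn) of
xy. The alternative (basal plane exactly in xy) distorts unwrapped
angles; a 2.5-turn spiral then unwraps to ~950° instead of 900°.

Alignment is a fixed-point iteration:

1. total-least-squares plane of all points seeds the axis direction;
2. the axis position in-plane is a Gauss–Newton fit of a smooth
   (cubic-in-angle) radius profile, updated along radial residuals. A
   centre offset ε appears in the radius as −ε·cos(θ−φ), exactly the
   component the update resolves. Averaging per-turn circle-fit centres —
   the obvious alternative — is biased ≈ 0.5 mm for decaying spirals,
   because every turn's circle centre is offset the same way;
3. the axis direction is refined by a *detrended-tilt regression*: z is
   regressed on a piecewise-linear (hinge) trend in the unwrapped angle
   plus x and y; the x/y coefficients are residual tilt and are rotated
   out. The hinge basis represents piecewise-linear pitch profiles
   exactly and cannot absorb the period-360° tilt signature;
4. the frame is rotated about z so the RW has angle 0, and shifted so the
   basal-turn mean height is z = 0.

The iteration is idempotent to ~1e-9 on clean data and equivariant under
rigid motions to machine precision (tested). Input points must be in
trajectory order (the order a rater clicks them; the generator and the
CSV convention provide this). Left ears wind clockwise anatomically; the
aligner flips the z-sign so the unwrapped angle always increases
apically, and `side` is carried as metadata. Collinear or
single-turn clouds raise alignment errors.

## Spline and arc length

The lateral-wall curve is an interpolating cubic spline on cumulative
chordal parameterisation, with a monotone (PCHIP) map between curve
parameter and unwrapped angle. No smoothing parameter exists on this
path. Arc length integrates |C′(t)| with 8-node Gauss–Legendre quadrature
per spline piece — additive to ~1e-12 and far below the 1e-6 mm
tolerance asserted in tests.

**Dense noisy clouds** (hundreds of points, jitter comparable to point
spacing) would make an interpolating spline chase noise and inflate the
arc length severely (the chord between two noisy points exceeds the true
arc by ≈ 3σ²/L per segment). `fit_lateral_wall_spline(...,
denoise_window_mm=1.0)` therefore:

* averages points in windows of ~1 mm of projected arc length (windows
  widen angularly toward the small-radius apex, where angular noise is
  largest);
* re-expands each window mean radially by the exact discrete
  arc-to-chord factor m/|Σⱼ e^{iθⱼ}| (the mean of points on an arc lies
  inside the arc);
* estimates the curve endpoints by local-linear regression *in
  trajectory order* (near the apex, angular noise exceeds the angular
  point spacing, so sorting by angle scrambles the sequence);
* subtracts the residual noise inflation 3·var/L per segment, with the
  per-point noise variance estimated from within-window quadratic-fit
  residuals.

All four steps are analytic corrections with no tuned constants; the
window width (1 mm ≈ 1/40 of a typical duct) trades noise suppression
against curvature resolution and is fixed a priori. On the default
synthetic cochlea with 0.1 mm jitter this recovers the true CDL with
≈ 0.3 % standard deviation over 50 seeds (asserted at 1.5 % per seed).

## Landmarks

A is the xy-projected distance from the RW to the far lateral wall along
the ray through the modiolar axis (polar angle 180°); B the wall-to-wall
chord on the perpendicular (90°/270°); both are found by root-finding the
polar angle on the fitted spline. H is the axial extent (max z − min z)
of the trajectory, warned when the cloud spans < 1.5 turns.

## Formula estimators

Implemented exactly as published: the Escudé angular-length relation, its
truncated full-insertion short form (available as `printed_constant` mode
solely to reproduce the published 1.57; exact mode is the default and the
two differ by ~0.13 mm at A = 10), and the elliptic-circular bracket.
The pBTL profile the clinical software uses is proprietary; the default
reuses the Escudé angular shape normalised to 1 at 360°,
`ln(1 + θ/235)/ln(1 + 360/235)`, flagged `approximation=True`, and any
callable can be injected. The ×0.9 organ-of-Corti and ×10/9 resolution
corrections are idempotence-guarded and recorded on the estimate, and an
estimate's reference surface travels with it, so lateral-wall and
organ-of-Corti numbers cannot be silently mixed. Because all factors are
scalar products, application order is irrelevant; corrections are applied
last by convention.

## Insertion simulation

The array is laid along the lateral-wall spline inset radially by
`wall_offset_mm` (default 0.5 mm — the electrode sits inside the scala).
Two insertion-angle conventions are always computed: `contact_span`
(between the most apical and most basal contacts, the radiographic
convention and the default fed to the reference formula) and
`tip_from_rw` (angle reached by the tip; always ≥ the span). The default
contact layout spreads 12 contacts from 0.5 mm behind the tip to 2 mm
short of the basal end. This is deliberately *not* a vendor datasheet
layout: commercial arrays keep a multi-mm passive basal lead, which makes
the radiographic contact span miss ~50° of basal turn; the idealized
layout keeps the span representative of the intracochlear course while
explicit `contact_positions_mm` reproduce any real device. No bending
mechanics, friction or scalar translocation is modelled. Arrays longer
than the available trajectory yield a `full_insertion=False` result with
outside contacts parked at θ = 0, not an exception.

## Synthetic cochleas

The spiral family is `r(θ) = r0(1 − d·θ)` with optional basal cos 2θ
ellipticity blended out by 360°, and a piecewise-linear axial rise with
steeper apical pitch. Defaults (r0 = 4.7 mm, d = 9.5e-4 per degree,
4 mm total rise, 900° extent) put the single default specimen at
CDL ≈ 42.8 mm, A ≈ 8.6 mm — inside the anatomically reported ranges —
without claiming anatomical fidelity beyond these summary dimensions.
Cohorts vary r0 (sd 0.45 mm, truncated) and height (sd 0.3 mm), giving a
reference-CDL spread of ~4 mm as reported for human temporal bones.
Ground truth integrates the analytic speed with composite Simpson at
0.01° steps (refining 10× changes the result < 1e-6 mm, tested).

The voxel phantom rasterises the duct as a fluid tube (HU ≈ 0) whose
*outer* surface traces the lateral wall, inside a 0.5 mm bone shell
(+700) on air (−1000), at 0.2 mm default spacing. The apical lumen
radius tapers to 0.25 mm so the duct never crosses the modiolar axis (an
axis-crossing duct has no well-defined lateral wall in projection).
Threshold segmentation keeps voxels in the fluid window (default −1024
to +280); because the air background also falls in that window, the
manual "select the cochlear fluid region" step of clinical software is
emulated by an optional connected-component selection
(`select_lumen=True`, used by the pipeline). Boundary voxels are
exported at voxel centres *on purpose*: they sit inside the true wall,
reproducing the resolution-dependent underestimation that motivates the
10/9 correction. The loop phantom → segmentation → wall extraction →
spline shows a negative CDL bias at 0.2 mm spacing whose magnitude
shrinks at 0.1 mm (asserted in the acceptance suite).

Wall extraction from boundary clouds bins points by wrapped polar angle,
separates the turns crossing each angular half-plane by single-linkage
clustering in the (radius, z) section, takes the near-outermost points
of each crossing, and chains candidates by spatial continuity from the
RW. It assumes canonical pose and a monotonically rising spiral.

The measurement error model is additive per method (bias + Gaussian
noise on CDL, jitter on landmarks, per rater). Default biases follow the
underestimation pattern reported for clinical CT workflows (5–8 mm below
the insertion-angle reference); default noise (1 mm sd) and rater jitter
(0.3 mm sd) are plausible round numbers, stated once and not calibrated
against any output. What a green end-to-end test establishes is that the
*pipeline machinery* (geometry, formulas, statistics, I/O) is correct on
a known world — not that the synthetic world reproduces cadaver anatomy.

## Statistics

* **ANOVA**: standard one-way decomposition (df k−1, N−k); the
  degenerate all-identical case returns F = 0, p = 1 by convention.
* **Dunnett**: many-to-one t statistics share the control mean and the
  pooled sd, giving the one-factor correlation structure
  ρᵢⱼ = λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)) — exact for balanced and unbalanced
  designs. Family probabilities integrate the shared normal factor with
  80-node Gauss–Hermite and the chi factor with adaptive quadrature
  (deterministic, ~1e-8), the critical point by root-finding; adjusted
  p-values and simultaneous CIs follow. With one comparison this reduces
  to the two-sample t-test to < 1e-6 (tested), and it matches
  scipy.stats.dunnett to that routine's QMC noise (tested). Mean
  differences are reported as control − group, so a *positive* value
  means the method underestimates the reference.
* **Dependent correlations**: Hotelling–Williams t with n−3 df for two
  correlations sharing the reference variable. Monte-Carlo calibration
  at n = 20 keeps the type-I error within 5 % ± 1.5 points (tested). A
  bootstrap alternative is not offered because the operation receives
  correlations, not raw data.
* **ICC**: two-way random effects, absolute agreement, single
  measurement — ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC−MSE)/n) —
  chosen because absolute CDL values are compared across raters; it
  matches pingouin's ICC(A,1) to 1e-9 (tested). Banding: < 0.40 poor,
  0.40–0.59 fair, 0.60–0.74 good, ≥ 0.75 excellent (configurable).
* p-values are rendered "< 0.001" below that threshold in the Markdown
  report; exact values stay in the JSON.

## Known limitations

* The spiral family is a summary-statistics phantom; it has no scala
  structure, no hook region, and linear radial decay only.
* Wall extraction presumes a monotonically rising, non-axis-crossing
  duct in canonical pose; malformed anatomies are out of scope.
* The pBTL default is a shape-preserving stand-in, not the proprietary
  clinical profile; full-insertion (θ = 900°) results are unaffected by
  its shape only through the bracket normalisation pBTL(360°) = 1.
* PLY support is ASCII, vertex-only.
* The insertion simulator has no mechanical model; its two angle
  conventions bracket, but do not resolve, the difference between a
  radiographic contact-span measurement and the tip's angular depth.
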