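# Methods

## The shape-mode representation

A crawling cell's outline at time t is reduced to the radial profile
R(θ, t): the distance from the area centroid to the rim along the ray at
angle θ (counterclockwise from +x). Profiles are sampled on a uniform
1° grid (360 samples; configurable) and smoothed by averaging over
θ ± 6°, then expanded in circular Fourier modes

    R(θ, t) = R0(t) + Σ_{n≥2} [ C_n(t) e^{-inθ} + conj(C_n(t)) e^{inθ} ],
    C_n(t)  = ⟨ R(θ, t) e^{+inθ} ⟩_θ .

|C_n| is the magnitude of the n-fold deformation; φ_n = arg(C_n)/n, on
the branch [0, 2π/n), is the direction of maximum deformation. With the
e^{+inθ} analysis sign an order-n quantity transforms as
C_n → C_n e^{inθ0} under a rotation by θ0, which is the covariance the
model's coupling-term selection rule (n = l + m for any product of
factors of orders l, m; conjugates count negative, the velocity counts
as order 1) is built on. Mode n = 1 encodes centroid displacement;
because the centroid is recomputed per frame as the polygon's area
centroid, C_1 nearly vanishes and is kept only as a QC diagnostic.

For non-star-convex outlines the profile takes the outermost ray
crossing, preserving protrusion signal; if the centroid falls outside
the contour the frame is rejected with an explicit error.

Derivatives follow the tracking convention: a 3-point centered moving
average of x(t) and C_n(t) (ends shrink the window symmetrically), then
a forward difference over the 5-min sampling interval, expressed per
hour. The derivative series is one sample shorter and aligned to the
left sample time.

## The migration law

The centroid velocity, as the complex number v1 = v_x + i v_y (μm/h), is
modeled as

    v1 = β1 conj(Ċ2) C3 − β2 conj(C2) Ċ3,

with mobilities β1, β2 in 1/μm. The law is rotationally equivariant and
time-reverse symmetric: contraction retraces extension, which is what
produces back-and-forth motion. A general form adds the
shape-determined term β_c conj(C2) C3 (a cell that keeps a fixed
polarized shape and moves steadily — the keratocyte limit β1 = β2 = 0).

β1, β2 are estimated by linear least squares on the stacked real and
imaginary parts of the observed velocity against the two bilinear
regressors, pooled over all cells (population-level fit). 95% intervals
come from the standard linear-model covariance with residual variance
S/(2n − k). Samples where both regressors vanish are dropped as
uninformative. Model variants are compared by the Gaussian-residual
AIC, n·ln(RSS/n) + 2k, on the stacked residuals.

Diagnostics mirror the validation plots used with tracking data: joint
phase histograms of arg(v1) against the phase of each law term (24×24
bins by default, with the mean resultant length of the phase difference
as a scalar summary), and observed velocity binned by predicted
velocity in γ = 12 μm/h windows centered on integer multiples of γ.

## The PRD model

The persistent random deformation model closes the loop by evolving the
deformations themselves:

    Ċ2 = −κ2 C2 − α2 conj(v1) C3 + F2
    Ċ3 = −K3 C3 − α3 v1 C2 + β3 conj(C3) F6 + F3,  K3 = κ3 + γ3 |C3|²
    Γv v1 = αv conj(v1) C2 + β1 conj(Ċ2) C3 − β2 conj(C2) Ċ3,
    Γv = 1 + γv |C2|²

driven by red-noise force multipoles (dipole F2, quadrupole F3, and F6)
with cutoff κf:

    Ḟi = κf (−Fi + σi ξi),   ξi complex unit white noise,

integrated with Euler–Maruyama: ΔFi = −κf Fi Δt + κf σi ξi √Δt, giving
a stationary per-component sd of σi √(κf/2). κ2 C2 and K3 C3 restore
circularity; αv > 0 steers motion along the elongation axis;
β3 conj(C3) F6 is multiplicative noise producing the exponential tail
of the C3 distribution, bounded by γ3 |C3|².

Because Ċ2 and Ċ3 contain v1, the velocity satisfies the
conjugate-linear system A v1 − αv C2 conj(v1) = b with
A = Γv + β1 α2 |C3|² − β2 α3 |C2|² and b collecting the force and
relaxation terms. Each step solves it in closed form,

    v1 = (A b + αv C2 conj(b)) / (A² − αv² |C2|²),

verified in tests against a brute-force real 2×2 solve. A `lagged`
scheme that reuses the previous step's velocity is provided; the two
agree as dt → 0. The closed-form solve is the default because it is
well-defined at any step size and introduces no scheme lag.

Stability: the denominator stays positive for all states iff
γv > β2 α3 and 2√(γv − β2 α3) > αv. The shipped defaults keep the
minimum of A − αv|C2| at ≈ 0.20 for the softest-substrate parameter set
(larger for stiffer substrates, whose β2 is smaller), so the solve is
uniformly bounded — velocity bursts near the most-elongated states are
finite by construction.

Integration uses forward Euler at dt = 0.5 min (first-order convergence
verified on frozen noise paths). Trajectories start from the zero state
and discard a 5-h burn-in to reach stationarity. Observation sampling
every 5 min adds independent Gaussian noise (sd σ0 = 1 μm, the scale of
segmentation error in phase-contrast imaging) to x, y and to Re/Im of
each sampled mode; the sampled series then pass through the same
moving-average/differencing pipeline as tracking data. Random numbers
come from one master seed with per-cell spawned substreams, consumed in
a fixed order (per step: F2, F3, F6; then per sample: x, y, Re/Im C2,
Re/Im C3), so any run is bitwise reproducible and a prefix of a larger
ensemble equals the smaller one.

### Parameters

Per-substrate presets (`table2_35kPa`, `table2_120kPa`, `table2_410kPa`)
carry the published mobilities β1, β2 (1/μm), relaxation rates κ2, κ3
(1/h), mean radius R0 (μm), and noise amplitudes σ2, σ3 (μm/h)
back-computed from the non-dimensional forces σ_n/(R0 κ_n).

The remaining coupling coefficients are shared package defaults,
calibrated once (script: `scripts/calibrate_defaults.py`) so the
soft-gel ensemble reproduces the qualitative signatures of fibroblast
crawling — mean speed ≈ 30 μm/h, velocity decorrelating in ~20 min
while C2 persists for hours, positive excess kurtosis of velocity
components, a modal rotation angle of 180°, and a short-lag MSD
exponent of 1.6–1.7:

| coefficient | default | units | role |
|---|---|---|---|
| αv | 0.11 | 1/μm | motion–elongation alignment |
| γv | 0.005 | 1/μm² | saturation of the alignment gain |
| α2 | 0.01 | 1/μm | shape change caused by motion (C2) |
| α3 | 0.005 | 1/μm | shape change caused by motion (C3) |
| γ3 | 0.1 | 1/(μm² h) | nonlinear damping of C3 |
| β3 | 1.0 | 1/μm | multiplicative F6 drive of C3 |
| κf | 2.4 | 1/h | force-noise cutoff (≈ 25 min memory) |
| σ6 | 3 σ3 | μm/h | F6 amplitude |
| σ0 | 1.0 | μm | observation noise |

σ6 must be a multiple of σ3 large enough that β3 conj(C3) F6 competes
intermittently with κ3 C3; at small σ6 the term is inert, the C3 tail
stays Gaussian and simulated cells are several-fold slower than real
ones. The units of the coupling constants follow from requiring each
term of its equation to carry the units of that equation's left side.

The calibration trades off two signatures: a long force memory (small
κf) lengthens velocity persistence (raising the short-lag MSD
exponent) but lets interrupted runs resume in the same direction
(feeding the 0° rotation bin), while a short memory does the opposite.
κf = 2.4 1/h sits where both the 180° modal bin and an exponent ≥ 1.6
hold with margin across seeds.

## Trajectory statistics

Tracks shorter than 8.3 h are excluded (the inclusion filter used for
soft substrates). MSD is time-averaged per cell over all start points,
then ensemble-averaged with equal weight per track; it is computed on
the smoothed positions, consistent with the velocity pipeline. The
short-time exponent is the log-log slope over 10–60 min (configurable);
"short" here means lags well below the velocity persistence time scale
crossover. ACFs are computed per track after mean subtraction,
normalized at lag 0, and ensemble-averaged with equal weight. Component
PDFs pool real and imaginary parts (spatial isotropy).

Persistence segmentation thresholds the short-lag velocity correlation
CV(t) = v(t+Δt)·v(t) with Δt = 10 min at 2/3 of its per-track median.
A maximal run of supra-threshold samples [i, j] certifies the position
stretch i .. j+1+Δt/τ (the samples entering its velocities); segments
span that full stretch, which makes the segmentation exactly covariant
under time reversal of a track. The persistent length is the path
length of the smoothed trajectory across the segment. Rotation angles
between the net-displacement vectors of successive segments are
reported in [0°, 360°) (arg of the complex ratio), so a reversal maps
to 180°; histograms use 20° bins centered on multiples of 20°, putting
180° at a bin center. Segment pairs with a zero net displacement are
skipped and logged.

## Fitting

The PRD model is fitted to summary statistics, not trajectories:
ERR = Σ_i (1 − R_i²) over (i) quantile–quantile R² of the symmetrized
distributions of velocity, C2, C3 and of the two phase differences
arg(v1) − arg(conj(Ċ2)C3) and arg(v1) − arg(conj(C2)Ċ3), matched at 99
interior percentiles against the identity line, and (ii) curve R² of
the v1, C2, C3 autocorrelation functions on the common lag grid. ERR is
itemized per component, non-negative, and zero only when every
component matches.

Minimization is multistart Nelder–Mead on log-parameters: a seeded
coarse multiplicative scan (±50% around the initial point) replaces
manual exploration, then 20 restarts from jittered starts. Every ERR
evaluation simulates a fresh ensemble with a fixed per-fit seed (common
random numbers), making the whole fit deterministic given its seed; the
restart spread is reported as the parameter uncertainty. Simulation
budget per evaluation is configurable; the shipped tests use small
ensembles (8–20 cells, 8–12 h) so a restricted two-parameter fit runs
in minutes — recovery was verified at that budget, and larger budgets
tighten the restart spread.

The PRW baseline fits the two-dimensional Fürth MSD with an
observation-noise offset, MSD(t) = 4D(t − P(1 − e^{−t/P})) + 4σ0², by
weighted least squares with weights 1/n_pairs(lag), optimizing log D
and log P. Note the Fürth curve is convex in t (ballistic → diffusive),
with curvature (4D/P)e^{−t/P}.

## What the synthetic data does and does not emulate

Contour movies are rendered from prescribed mode programs plus
vertex-wise radial noise and re-analyzed exactly like segmented
contours, so they exercise centroid recomputation, ray sampling, the
±6° window and the differencing chain. They do not emulate segmentation
artifacts with spatial structure (halos, merged neighbors), pixelation,
or mode content above the programmed band. PRD ensembles emulate the
sampling cadence, observation noise and population size of a tracking
experiment, but all cells share one parameter set (no cell-to-cell
parameter heterogeneity) and collisions/divisions do not occur, so
passing tests demonstrate pipeline correctness and model behavior, not
biological generality.

Two geometric facts matter when interpreting contour fixtures: a
polygonal chord undercuts a circumscribed curve by ~R(π/n_vertices)²/2,
and for strongly deformed shapes the area centroid genuinely shifts
away from the construction origin, so re-measured modes differ from the
programmed ones at second order in amplitude. Tests therefore compare
at moderate deformation or against exact ray-geometry oracles.

## Numerical choices and degenerate inputs

- Velocity-solve singularity tolerance 1e-10 on the denominator; hit
  only if parameters violate the stability condition, and reported with
  the state and time.
- Rank-deficient mobility fits (collinear or all-zero regressors) raise
  rather than return pseudo-inverse estimates.
- A vanishing mode has no phase: phase_decomposition returns NaN, never
  an arbitrary angle.
- Zero-variance series are rejected by the ACF; empty phase samples and
  degenerate (constant) Q-Q inputs raise named errors.
- Non-uniform time grids are rejected naming the first offending gap.
- Ray–polygon intersection uses an 1e-9 slack on the edge parameter so
  rays through shared vertices cannot slip between adjacent edges.

## Known limitations

- The simulator truncates the mode hierarchy at n = 3 (the evolution
  equations for C4–C6 are not part of the model here); reconstructed
  simulated shapes are mode-2/3 silhouettes. The integrator accepts
  extended state vectors through its noise interface, which is the
  intended extension point.
- The coupling-coefficient defaults are calibration-derived package
  choices, not measured values; conclusions about their magnitudes
  should not be read as biology.
- ERR components are equally weighted; with few cells the ACF
  components dominate the stochastic fluctuation of the objective.
- The Euler scheme is first-order; halving dt changes end states on a
  frozen path at O(dt). dt = 0.5 min keeps κ·dt ≤ 0.02 for all shipped
  rates.
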