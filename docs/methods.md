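# Methods

This note documents the models, numerical choices and synthetic-data design
behind `petquant`, in the spirit of a package methods appendix.  Units are
minutes, kBq·mL⁻¹, min⁻¹ and mL·cm⁻³ throughout; all stored activities are
assumed decay-corrected (the scanner convention), and the simulator emits
decay-corrected data.

## Input function

Whole-blood and total-plasma activity are each fitted with a
tri-exponential from the empirical peak sample onward,
`C(t) = Σᵢ Aᵢ e^(−λᵢ(t−t_peak))`, with linear interpolation through the
measured samples on the rising limb and a (0, 0) anchor.  Fitting the
exponentials only past the peak avoids forcing them through the ascending
bolus.  Amplitudes are constrained non-negative and solved by NNLS for
every decay-rate candidate (variable projection); the three rates are
optimised in log space from four fixed starting triples.  Note the
amplitudes are parameterised at the peak, so they are comparable across
fits only jointly with `t_peak`.

The plasma parent fraction is fitted with a Hill function

    pf(t) = 1 − (1 − a)·t^b / (t^b + c^b),

which enforces pf(0) = 1 and decays monotonically to the plateau `a`; `c`
is the half-transition time and `b` the steepness.  The metabolite-corrected
input is the product Cp(t) = plasma(t) × pf(t).  Blood fits use uniform
weights: the samples are few and of similar magnitude.  No dispersion
correction is applied.

The artery-to-brain arrival delay Δ is estimated separately, not as a free
parameter of the tissue fits: a one-tissue model (with the fixed 5%
vascular term) is fitted to the first 5 min of the whole-brain TAC for each
candidate shift on a uniform grid Δ ∈ [−2, +2] min, step 0.05 min, and the
residual-minimising shift wins.  The one-tissue approximation is adequate
over the first minutes, and the grid search avoids local minima.  All
subsequent evaluations read the input curves at t − Δ.

## Compartmental gold standard

The reversible two-tissue compartment model has impulse response

    h(t) = K₁/(θ₁−θ₂)·[(θ₁−k₃−k₄) e^(−θ₁t) + (k₃+k₄−θ₂) e^(−θ₂t)],

with θ₁,₂ the roots of θ² − (k₂+k₃+k₄)θ + k₂k₄, and the measured signal is
C_PET = (1 − V_b)(h ⊛ Cp) + V_b·C_wb with V_b fixed at 0.05 (not
estimated).  Convolutions are evaluated on a uniform 0.05-min grid with a
causal trapezoidal recursion (an IIR filter — exact for piecewise-linear
integrands), and frame values are exact sub-grid duration averages, not
mid-point samples.  The forward model agrees with a stiff ODE integration
of the compartment system to better than 0.1%.

The fit minimises duration-weighted least squares (weights ∝ √duration,
i.e. uniform variance per unit scan time) over (K₁, k₂, k₃, k₄) in log
space, bounded to (10⁻⁶, 10) min⁻¹ with boundary hits flagged, from 8 fixed
deterministic starting points (a half-fraction of the 2⁴ corners of
K₁∈{0.1, 0.4}, k₂∈{0.05, 0.2}, k₃∈{0.01, 0.1}, k₄∈{0.01, 0.05}).  Only the
first 120 min of PET and blood data enter any kinetic fit; a frame
straddling the cut is dropped, so no later data leak in.  Parameter
standard errors come from the Gauss–Newton covariance in log space (hence
directly relative).  The noiseless fit∘simulate round trip recovers rates
to ≪1% across V_T 10–18.

## Graphical analyses and t*

Logan: ∫₀ᵀC_T/C_T(T) regressed on ∫₀ᵀCp/C_T(T); the slope is V_T.
MA1: C_T(T) regressed on [∫₀ᵀCp, ∫₀ᵀC_T]; V_T = −β₁/β₂.  Tissue integrals
use the trapezoid over frame mid-time samples with a (0, 0) anchor; plasma
integrals use the fine grid.  t* is the smallest frame mid-time whose Logan
regression over all later frames has maximum |relative residual| ≤ 10% (a
common convention; fallback t* = 30 min with a warning when the criterion
is never met), selected once from the whole-brain TAC and reused for every
region and voxel of that session.

Because no statement is available on vascular handling for the simplified
methods, the measured TAC is pre-corrected before Logan/MA1/SA:
C_T = (C_PET − V_b·C_wb)/(1 − V_b) with the same fixed V_b — so every
estimator targets the same tissue V_T as the 2TCM.  The correction is
switchable (`vb=0` disables it).

Graphical estimators carry a residual negative bias on noiseless data when
the slow eigenvalue θ₂ has not decayed by t* (≈ −1 to −2% for the default
cohort kinetics, where 1/θ₂ ≈ 45–80 min); this is a property of the
method, not of the implementation, and it deepens under noise (Logan more
than MA1).  A doubled TAC yields a doubled Logan V_T — the slope is linear
in the TAC scale and invariant only under joint TAC + input rescaling.

## Spectral analysis

Standard nonnegative spectral analysis: C_T ≈ Σⱼ αⱼ·(Cp ⊛ e^(−βⱼt)) with
αⱼ ≥ 0 solved by NNLS, basis functions frame-averaged exactly like the
data.  The β grid holds 100 logarithmically spaced values from
1/(4·120) ≈ 0.0021 min⁻¹ (the slowest washout resolvable in a 120-min
acquisition) to 6 min⁻¹.  No β = 0 trapping component is included (the
tracer is reversible) and no separate blood-volume basis term (vascular
correction is inherited from the pre-correction above).  Macro-parameters:
V_T = Σ αⱼ/βⱼ; IRF(t) = Σ αⱼ e^(−βⱼt), with IRF(0) ≈ K₁ and IRF₁₂₀ defined
as the impulse response at t = 120 min from the 120-min fit.  NNLS's
positivity constraint rectifies noise, which is why SA overestimates V_T on
noisy data while being nearly exact on noiseless TACs.

## Parametric maps, SUV and SUVR

Voxelwise Logan and MA1 are closed-form per-voxel regressions (vectorised,
arithmetic identical to the regional estimators); spectral V_T and IRF₁₂₀
maps come from one NNLS pass per voxel.  All voxels share the whole-brain
t*.  Validity policy: non-positive late-frame tissue activity (Logan),
singular designs (MA1) and solver failures (SA) are masked, excluded from
region means, and reported as per-region masked fractions; an all-zero
voxel is a legitimate zero for SA.  Region means are unweighted voxel
means, matching the unweighted combination of voxels into regions used
throughout (volume weighting across sub-regions is not modelled).

SUV uses body-weight normalisation, SUV = C̄·weight/dose, over a late
window (60–80, 80–100 or 100–120 min; default 100–120, the window that
correlates best with compartmental V_T).  SUVR divides each region's SUV by
the corpus callosum's — a pseudo-reference with the lowest V_T, not a true
reference region, since the target enzyme is ubiquitous.

## Reliability statistics

TRV = 100·(retest − test)/mean, aTRV = |TRV|;
ICC = (BSMSS − WSMSS)/(BSMSS + WSMSS) from the one-way subject-factor
ANOVA (equivalently ICC(1,1) for two sessions), with bands 0.50–0.75
moderate, 0.75–0.90 good, > 0.9 excellent.  Percentage bias between methods
is implemented under both printed conventions — relative to the pair
average (default, antisymmetric) and relative to the reference — selectable
by flag.  The repeated-measures ANOVA treats subjects as blocks and tests
the method effect against the subject×method residual, reporting the
standard within-subject error degrees of freedom (k−1, (n−1)(k−1)); Fisher
LSD pairwise t-tests (pooled MS_error) run only when the omnibus test is
significant at 0.05 unless forced.  The arteriovenous difference is
100·(arterial − venous)/arterial on plasma-parent concentrations at 30, 60,
120 and 180 min, the sign convention under which the early difference is
positive.

## Synthetic cohort

The generator emulates a 10-subject test–retest study at the region level
and on toy 20×20×20 images.  Defaults, chosen once:

- **Regions**: 16 consolidated regions; V_T targets for whole brain (13.2),
  temporal (15.0), frontal (14.1), striatum (15.6), cerebellum (14.1) and
  brainstem (12.2) mL·cm⁻³ follow the emulated cohort's means, the
  remaining targets are plausible interpolations, and the corpus callosum
  sits below all others at 8.0 (only "lowest" is known).  Voxel counts make
  the voxel-weighted mean of the targets ≈ 13.2.
- **Kinetics**: K₁ ~ U(0.25, 0.35), k₃ ~ U(0.03, 0.07), k₄ ~ U(0.02, 0.04);
  k₂ is derived so each region hits its V_T target exactly.  Between-subject
  spread is a lognormal V_T scale (σ = 0.17, matching ≈18% between-subject
  CV), centred to a unit cohort mean so the cohort-average whole-brain V_T
  equals the target by construction; small per-region jitter (σ = 0.03) is
  added on top.
- **Retest effect**: multiplicative on K₁ (propagating to V_T while
  preserving curve shape); round(0.9·n) subjects are shifted up with median
  +10% (σ = 0.05 in log), the rest down with median −7%.  This reproduces
  ≈10% aTRV and moderate-to-good ICC.
- **Noise**: Gaussian frame noise with SD ∝ √(value/duration), scaled so a
  frame at the curve's mean value and mean duration has relative SD equal
  to the level — 5% for regional TACs, 10% extra at the voxel level, 2%
  multiplicative on blood samples.  This captures the short-early-frame
  noise structure without modelling counts explicitly.
- **Blood**: tri-exponential plasma (peak snapped to a sampling time so
  zero-noise round trips are exactly recoverable), whole blood at 85% of
  plasma, Hill parent fraction (a = 0.12, b = 1.8, c = 35 min), arrival
  delay U(−0.5, 0.5) min.
- **Arteriovenous profile**: venous parent concentration is arterial ×
  (1 − p(t)/100) with cohort-mean profile (+14.3, −1.5, −5.5, −25.0)% at
  (30, 60, 120, 180) min and per-subject jitter with SDs (12.2, 5.9, 14.0,
  21.0); venous tables exist for the first 4 subjects.

All draws flow from one seed; identical seeds give bit-identical cohorts
(NumPy PCG64).  What the generator does **not** emulate: anatomy and
partial-volume effects, scanner PSF, attenuation/scatter, radioactive-decay
bookkeeping, motion, dispersion in blood sampling, and between-region
kinetic correlations beyond the shared subject scale.  Passing tests
therefore demonstrate correctness and the qualitative noise behaviour of
the estimators, not performance on real scanner data.

## Problem sizes and runtime

The default test and acceptance runs use the full 10-subject cohort with
toy 20×20×20 images (≈5,800 labelled voxels), 200-replicate noise studies,
and a 20-point parameter grid for the round trip; the complete pipeline
runs in about a minute on one CPU.  Full-resolution images are supported by
the same code paths.

## Known limitations

- The finite-t* transient bias of Logan/MA1 (above) means "noiseless"
  graphical estimates sit ≈1–2% low for slowly equilibrating kinetics.
- The Hill form and the pre-peak interpolation are fixed conventions; other
  parent-fraction models (e.g. power or sigmoid variants) are not provided.
- The one-way ICC is the only reliability model; mixed-effects or two-way
  ICC variants are out of scope.
- SUVR is computed but deliberately excluded from the correlation analysis
  by default: against a pseudo-reference with specific binding it does not
  track V_T, and the pipeline reports it separately.
- Voxel-level 2TCM is intentionally unsupported (computationally fragile
  voxelwise); requesting it raises an error.
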