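# Methods

## Scope

`petkin` implements the kinetic-analysis chain for 90-min total-body
dynamic PET with an image-derived whole-blood input: compartment-model
fitting with joint time-delay estimation and AICc model selection,
input-function tail extrapolation, macroparameter and Logan graphical
quantification, Monte-Carlo practical-identifiability analysis, and the
small-sample group statistics — exercised end to end on synthetic
time–activity curves (TACs) with known ground truth.

## Measurement model

A region's measured concentration is

    C_m(t) = v_b · C_wb(t − t_d) + (1 − v_b) · C_t(t)

with fractional blood volume `v_b`, arrival delay `t_d` (min) and tissue
concentration `C_t` given by the 1-tissue or serial 2-tissue compartment
ODEs with rates `K_1` (mL/min/mL), `k_2, k_3, k_4` (1/min). Model kinds are
named by fitted-parameter count: 1T4P (`v_b, K_1, k_2, t_d`), 2T5P (+`k_3`,
irreversible), 2T6P (+`k_4`, reversible). The same delayed input drives both
the vascular and the extraction term (one `t_d` per region). The
right-ventricle blood pool supplies lungs and lung-tumor subregions; the
descending aorta supplies everything else.

Because the system is linear, `C_t` is the convolution of the input with a
sum of at most two exponentials whose rates are the eigenvalues
`a_{1,2} = (s ± sqrt(s² − 4 k_2 k_4))/2`, `s = k_2+k_3+k_4`. The input is
represented piecewise-linearly (frame-midpoint knots, anchored at (0, 0)),
so the convolution — and the per-frame *time average* the scanner records —
have closed forms per segment (`petkin._conv`). Frame averaging (rather
than midpoint sampling) matters for the 2-s early frames. With nonnegative
rates the eigenvalues coincide only at `k_3 = 0, k_2 = k_4`, where the
response degenerates to a single exponential (implemented as that analytic
limit; the second compartment never fills). An independent adaptive-ODE
oracle (`ode_oracle`, LSODA at rtol 1e-10 with an integrated-signal state
for exact frame averages) verifies the analytic model to < 0.1% in tests;
observed agreement is ~1e-9 relative.

## Input function

Evaluation is linear interpolation between frame midpoints, ramping from
zero at injection to the first midpoint. The washout tail is fitted as
`A1·exp(−λ1 t) + A2·exp(−λ2 t)` on frame midpoints inside a 14–90 min
window (midpoint-inclusion rule), by bound-constrained least squares with
six log-spaced rate initializations, and used beyond the measured support —
out to a 600-min (10-h) horizon for equilibrium analysis. Delay shifts
clamp to zero before time zero. Biologic half-lives are `ln 2 / λ`.

## Fitting and model selection

Weighted nonlinear least squares (scipy `least_squares`, TRF,
bound-constrained) with uniform weights by default; `framevar` weights
`w_i = Δt_i / C̄_i` (the inverse of the count-statistics variance model) are
available. Bounds: `v_b ∈ [0,1]`, `K_1 ∈ [0,5]` mL/min/mL,
`k_2,k_3,k_4 ∈ [0,5]` /min, `t_d ∈ [−1,1]` min; boundary-pinned estimates
are flagged. Multi-start: one physiologic default start plus scrambled
Sobol starts within bounds (10 total by default), deterministic given the
seed; an optional RSS early-stop skips remaining starts once a fit is
essentially exact (used on noiseless data). `t_d` is fitted continuously
through the interpolated input, or held fixed.

Selection uses the small-sample-corrected Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)

with `k` counting all fitted parameters including `t_d` (4/5/6 for the
three kinds; one fewer when the delay is fixed), so Δk = 1 between adjacent
models. The lowest AICc wins; ties within 1e-9 go to the smaller model.

## Macroparameters

- `K_i = K_1 k_3 / (k_2 + k_3)` (2-tissue models; equals the asymptotic
  Patlak slope when `k_4 = 0`).
- `V_T = K_1/k_2` (1T) or `(K_1/k_2)(1 + k_3/k_4)` (reversible 2T);
  undefined for 2T5P.
- `V_T(v_b) = v_b + (1 − v_b) V_T` — the exact equilibrium limit of the
  measured tissue-to-blood ratio under the measurement equation, which is
  why extrapolated SUVR curves are compared against it.
- SUVR: per-frame `C_T/C_P`; window SUVR uses duration-weighted means of
  numerator and denominator over frames whose midpoints fall in the window
  (default 60–90 min).
- Logan plot: cumulative integrals by zero-anchored trapezoid on frame
  midpoints; ordinary least squares over points with midpoint ≥ t*
  (default 30 min); the slope `K_Logan` estimates `V_T(v_b)` for reversible
  kinetics when the measured TAC (including the blood fraction) is used.

## Synthetic study

The generator emulates the study's statistical structure: 65-frame 90-min
schedule (30×2 s, 12×10 s, 7×60 s, 16×300 s — a typical high-temporal-
resolution total-body protocol; the exact clinical framing is not fixed by
the analysis), aorta and right-ventricle inputs, 15 organ presets, a
tumor-like preset with 7 jittered subregions (CV 20%), 4 mediastinal nodes
(2 enlarged), axillary/pelvic nodes, 4 healthy subjects with between-
subject lognormal kinetic jitter (CV 15%), and a paired pre/post-therapy
patient in which therapy multiplies tumor `k_3` by 1.5 and `k_4` by 0.7
(trapping up, efflux down); enlarged vs non-enlarged mediastinal nodes
receive opposite-signed V_T shifts.

The blood input is a gamma-variate bolus (peak ≈ 40 SUV at ~25 s) plus a
biexponential washout with a fast distribution phase (t½ ≈ 2.8 min) and a
very slow terminal phase (2e-4 /min). The terminal rate and the preset
`k_4` values (0.02–0.026 /min, slow tissue eigenvalues ~0.016–0.022 /min)
were chosen together so that the synthetic organs reproduce the qualitative
equilibrium behavior the method targets: tissue–blood equilibrium is
reached hours after the scan, Logan plots are linear after 30 min in every
region (slope within 3% of `V_T(v_b)`), and extrapolated SUVR curves
approach `V_T(v_b)` monotonically between 90 min and 10 h. Faster tissue
efflux (e.g. `k_4 ≈ 0.03`) equilibrates inside the scan and destroys the
approach-from-below pattern; faster blood clearance makes the equilibrium
SUVR overshoot `V_T(v_b)` by more than a few percent.

Noise: independent Gaussian per frame with
`σ_i = noise_scale · sqrt(C̄_i · e^{λ_decay t_i} / Δt_i)`
(`λ_decay = ln2/109.77` min⁻¹ for ¹⁸F) — the standard count-statistics
model for decay-corrected framed data. A region's `noise_scale` defaults to
`0.045 · sqrt(C̄_late)`, making late-frame fractional noise uptake-
independent (emulating VOI averaging); the 0.045 anchor is calibrated so
the tumor region's V_T estimate has ≈5% Monte-Carlo SD over 100 refits of
the 90-min study. The generator is a pure function of (spec, schedule,
seed); ground-truth tables accompany every cohort.

What the generator does *not* emulate: spatially correlated noise, motion,
partial-volume and spillover effects, metabolites, plasma-to-whole-blood
partitioning, or dual-input liver supply. Passing tests therefore
demonstrate correctness of the estimation chain under the stated noise
model, not robustness to those real-data effects.

## Practical identifiability

Sensitivity curves are amplitude-normalized parameter-scaled derivatives
`S_θ(t) = θ · ∂C_m(t)/∂θ / max_t C_m`, by central finite differences
(relative step 1e-4) on the frame-midpoint grid. Under this definition the
delivery-phase parameters `v_b` and `K_1` peak during the bolus passage
(< 2 min) and `k_4` sensitivity keeps growing through the scan. (A
per-time-point normalization by `C_m(t)` was considered and rejected: it
makes `S_K1 = (1−v_b)·C_t/C_m`, which is structurally monotone increasing
for accumulating kinetics and cannot show the early delivery peak.)

Monte-Carlo identifiability is a parametric bootstrap: 100 noisy TACs are
drawn from the forward model at the reference parameters and refit (starts:
the truth plus a short Sobol ladder, isolating identifiability from
optimizer failure, which is counted separately and errors above 20%).
Bias% is relative to truth; SD uses the sample (n−1) convention; RMSE the
population mean square, so `RMSE² = bias² + SD²(n−1)/n` exactly. Variants
fix the delay at truth or truncate to the first 60 min (same noise draws on
overlapping frames, for paired comparison). The default panel is 10 regions
spanning both inputs, low/high blood volume and 1T/2T kinetics. At the
calibrated noise, V_T bias stays within ±3% and SD within 3–7% across the
panel (seed-dependent in the ±1–2% / ±0.5% range); `v_b` shows by far the
highest variability, and fixing the delay collapses it (SD −11 to −16
percentage points) while leaving V_T essentially unchanged. Two caveats
worth stating. First, fixing the delay does *not* uniformly shrink every
rate constant's SD — `k_3`/`k_4` SD rises by up to ~1 percentage point in
most seed configurations tested; with nonnegativity bounds and noisy 2-s
bolus frames, the free delay absorbs noise patterns that otherwise
propagate into the slow-exchange parameters. Second, with the slow-efflux presets
required for the equilibrium behavior above, most `k_4` information
arrives late in the scan, so truncating to 60 min costs the tumor region
roughly 6–10 percentage points of V_T RMSE (k_4 SD +~14 points) — a
faster-equilibrating tissue would lose much less.

## Group statistics

Spearman correlations use midranks; the two-sided p-value is the exact
permutation null for n ≤ 9 (full n! enumeration, vectorized) and the
t-approximation otherwise. The paired Wilcoxon signed-rank test drops zero
differences, uses midranks for tied magnitudes, and computes the exact
two-sided p `P(W⁺ ≤ w) + P(W⁺ ≥ n(n+1)/2 − w)` by full enumeration of the
2ⁿ sign assignments (dynamic program on doubled ranks; n ≤ 20). Seven
concordant pairs give p = 2/128 = 0.015625 (printed 0.016); a single
discordant pair carrying rank 2 gives 6/128 = 0.046875 (printed 0.047).
No multiple-comparison correction is applied. The surrogacy analysis
computes the fixed 7-pair set (SUV/SUVR/K_Logan against V_T and V_T(v_b),
and both K_i variants against SUVR).

## Numerical choices and degenerate inputs

- Convolution closed forms use expm1-stable `φ` functions with Taylor
  fallbacks below z = 1e-10/1e-6; eigenvalues below 1e-8 /min are treated
  as zero (double-integral branch), keeping the 2T6P→2T5P limit continuous
  to ~1e-6.
- TAC tables round-trip bit-exactly (`%.17g` write, round-trip float
  parsing on read).
- Zero-blood frames are excluded from SUVR with a warning; Logan requires
  ≥ 3 usable points after t*; AICc requires n > k+1 and RSS > 0.
- Problem sizes: identifiability runs 100 replicates × 10 regions;
  end-to-end recovery checks use one noiseless scan and a 5-region subset;
  the forward-model oracle grid covers all 17 presets.

## Known limitations

Single whole-blood input (no metabolite or plasma correction); no
voxelwise fitting; t* fixed rather than optimized; the exact clinical frame
schedule and reconstruction chain are not modeled; Gaussian frame noise
only. The fixed-delay caveat above is the one place where the pipeline's
behavior under the synthetic conditions deviates from the idealized
expectation that constraining a nuisance parameter can only help.
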