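# Methods

## Scope and model family

`refkin` quantifies dynamic PET time–activity curves (TACs) with the
one-tissue compartment model and the simplified reference tissue model
(SRTM) family. The intended use case is a tracer with fast, effectively
one-tissue kinetics in both target and reference regions (the package's
defaults are styled on an SV2A synaptic-density tracer quantified
against the centrum semiovale, with the cerebellum as a pseudo-reference
for distribution volume ratios).

**One-tissue compartment (1TC).** With plasma input Cp(t),

    dC_T/dt = K1·Cp(t) − k2·C_T(t)

with delivery K1 (mL·cm⁻³·min⁻¹) and efflux k2 (min⁻¹); the total
distribution volume is DV = K1/k2. Fitting the reference region with the
1TC model yields its clearance k2′, whose cohort mean is the
*population k2′* used by SRTM2.

**SRTM (Lammertsma–Hume operational equation).** Assuming 1TC kinetics
in target and reference and a common nondisplaceable distribution
volume,

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a) · [C_R ⊗ e^{−k2a·t}](t)

with free parameters (R1, k2, k2a): relative delivery R1 = K1/K1′,
target efflux k2, and apparent efflux k2a = k2/(1 + BP_ND). Derived
quantities: BP_ND = k2/k2a − 1 and k2′ = k2/R1.

**SRTM2 (fixed k2′).** Substituting k2 = R1·k2′ removes one parameter:

    C_T(t) = R1·C_R(t) + R1·(k2′ − k2a) · [C_R ⊗ e^{−k2a·t}](t),

free (R1, k2a), BP_ND = R1·k2′/k2a − 1. k2′ is fixed, normally to the
population mean of reference-region 1TC k2 (package constants: 0.059
min⁻¹ for centrum semiovale, 0.052 min⁻¹ for cerebellum).

**SRTMC (coupled fit).** All target regions of one scan are fitted
jointly with the SRTM2 operational form, sharing a single free k2′
across regions: parameters {k2′} ∪ {R1_j, k2a_j}. At a fixed k2′ the
problem decouples into independent SRTM2 fits; this is exploited for
initialisation, and is also the basis of a test asserting that the
joint optimum's summed WRSS equals the decoupled sum at the fitted k2′.

DVR = BP_ND + 1 throughout; by the package's default pairing BP_ND is
reported against the white-matter reference and DVR against the
cerebellum pseudo-reference, mirroring common SV2A practice (both are
derivable for either reference).

## Estimation

Weighted nonlinear least squares with `scipy.optimize.least_squares`
(bounded trust-region reflective), analytic model curves, analytic
Jacobians for the reference-tissue models, cost tolerance 1e-8.
Multi-start initialisation: BP_ND ∈ {0.5, 1.5, 3} for SRTM/SRTM2, (K1,
k2) ∈ {(0.1, 0.03), (0.3, 0.06), (0.6, 0.12)} for 1TC, k2′ ∈ {0.04,
0.06, 0.09} (with decoupled prefits) for SRTMC. Bounds: K1 ∈ (1e-4, 2],
k2, k2a ∈ (1e-4, 1], R1 ∈ (0.01, 5]. A fit whose solution sits at a
bound is flagged `converged=False` rather than raising.

Frame weights w_i default to the frame duration (options: uniform, and
duration damped by isotope decay at the frame mid-time, half-life
109.77 min for ¹⁸F); weights are normalised to mean 1 and all reported
quantities are invariant to the overall weight scale.

Standard errors come from the Gauss–Newton covariance
σ²(JᵀWJ)⁻¹ with σ² = WRSS/(n − p); derived parameters (BP_ND, k2′ or
k2, DV) get delta-method SEs from the same covariance. rSE =
100·SE/|estimate|. AIC uses the least-squares form n·ln(WRSS/n) + 2p.
For SRTMC the per-region AIC counts p = 3 (the shared k2′ charged to
every region) so that values are conservative and comparable with SRTM;
per-region SEs come from the corresponding sub-blocks of the joint
covariance.

**Reliability filter.** Outcome records with rSE(BP_ND) > 25% (strict
inequality) are flagged `excluded`; rows are never deleted. Exclusion
propagates to stability and test–retest aggregation by dropping the
affected cell/pair only.

## Numerics

* Convolution grid: 0.01 min. The reference curve is reconstructed by a
  shape-preserving cubic (PCHIP) through (0, 0) and the (mid-time,
  value) points, then the knot values are corrected by 16 fixed-point
  iterations so that the reconstruction's *frame averages* reproduce
  the observed values — a PET frame records an average, not a mid-time
  sample. The iteration contracts at roughly a factor 2 per step,
  reaching ~1e-5 relative consistency. (Piecewise-linear interpolation
  through mid-points, a common simpler choice, was measured to leave up
  to ~1.6% parameter bias at ill-conditioned corners of the parameter
  space; the frame-average-consistent reconstruction brings noise-free
  recovery error below 0.01%.)
* The convolution with e^{−θt} is advanced exactly per linear grid
  segment (a one-pole recursion evaluated with `scipy.signal.lfilter`);
  its θ-derivative, needed for analytic Jacobians, uses the identity
  ∂B/∂θ(t) = −t·B(t) + [s·C_R ⊗ e^{−θt}](t).
* Model predictions are averaged over each frame (trapezoid on the
  grid); the direct R1·C_R term uses the observed frame averages
  verbatim. Simulated 1TC curves are exact closed-form convolutions of
  the tri-exponential input, frame-averaged by 101-point composite
  Simpson.
* Degenerate geometry: when a target's true k2a equals the reference
  k2′ (equivalently BP_ND = R1 − 1) the target TAC is an exact scalar
  multiple of the reference and (k2, k2a) lie on a ridge — only R1 and
  BP_ND are identifiable. The fit returns a point on the ridge with
  correct R1 and BP_ND; recovery tests avoid asserting k2/k2a at that
  coincidence.

## Synthetic data generator

The generator emulates the *structure* of a human test–retest study: 9
subjects, 15 gray-matter targets plus centrum semiovale, 5 subjects
scanned twice, 90-min scans framed 6×0.5, 3×1, 2×2, 16×5 min.
Every region follows true 1TC kinetics under a shared tri-exponential
(Feng-type) plasma input (defaults: A1 = 850 kBq·mL⁻¹·min⁻¹, A2 = 22,
A3 = 21 kBq·mL⁻¹, λ = 4.1, 0.12, 0.01 min⁻¹, t0 = 0.5 min; a sharp
bolus peaking ~75 kBq/mL at ~0.75 min with a slow bi-exponential tail).
Target kinetics are parameterised by (R1, BP_ND) templates relative to
the reference (R1 1.35–1.8, BP_ND 1.05–3.8, clamp range [0.5, 4]), with
K1′ = 0.17 mL·cm⁻³·min⁻¹ and k2′ = 0.059 min⁻¹; the cerebellum template
(R1 = 1.8, BP = 1.05) puts its apparent efflux near 0.052 min⁻¹.
Because k2a = R1·k2′/(1 + BP_ND), all distribution-volume ratios are
internally consistent and the SRTM assumptions hold exactly in the
noise-free limit, so every fitted quantity has a known truth.

Variability has three separable dials:

* `subject_sd` (default 0.10, lognormal): between-subject spread of
  target R1 and BP_ND;
* `ref_sd` (default 0.08): spread of reference-region kinetics — K1′,
  k2′ and the cerebellum pseudo-reference templates. Setting it to 0
  makes the single population k2′ exactly correct for every subject;
* `jitter_sd` (default 0.03): per-session multiplicative jitter on K1
  and k2 (biological test–retest variability, separate from
  measurement noise). Jittered binding potentials are clamped back into
  the configured range.

**Noise model.** Frame noise is independent Gaussian with variance
σ_i² = scale²·max(v_i, 0.01)·e^{λ_d·mid_i}/dur_i (λ_d = ln2/109.77
min⁻¹), the standard decay-corrected count-statistics shape: late and
short frames are noisier. The default scale (1.5) was calibrated once
by Monte-Carlo so that three-parameter SRTM fits of low-to-mid binding
regions put a several-percent tail of rSE(BP_ND) beyond the 25%
reliability threshold at 90 min while two-parameter SRTM2 fits stay
reliable — the regime the reliability filter exists for. At this scale
full-length SRTM2 test–retest aTRV of BP_ND comes out near 10%,
comparable to published SV2A reference-tissue reproducibility. The
calibration anchors *90-min reliability behavior*, not absolute count
rates; short-truncation reliability and minimum scan times are
therefore properties of these synthetic conditions and not estimates of
any real tracer's values.

What the generator does **not** emulate: image reconstruction and
partial-volume effects, motion, scatter, correlated inter-frame noise,
plasma metabolite kinetics, blood-volume signal (vB defaults to 0 so
the SRTM no-blood-volume assumption is exactly satisfiable; a nonzero
vB is available to probe that violation), and any disease-related
kinetics. Passing tests therefore demonstrate correctness of the
estimation machinery under its own assumptions, not performance on real
scans.

## Time stability and test–retest

Stability refits every baseline scan at truncated durations (10–80 min
in 10-min steps; whole frames only, no partial-frame reweighting) and
aggregates the signed percentage difference against the same scan's
full-length estimate (mean and inter-subject SD across scans, unreliable
fits excluded per duration). The minimum scan time is the earliest
duration from which |mean| < 5% *and* SD < 10% hold at that and every
longer truncation ("sustained" reading; a `pointwise` flag gives the
single-point reading — the sustained default is the stricter and more
defensible interpretation of "converged after t").

TRV = 100·(retest − test)/pair mean (signed, retest-minus-test);
aTRV = |TRV| per pair, both averaged across pairs. This
difference-over-mean definition is the common PET test–retest
convention; the sign convention is configurable by swapping labels.
"All regions" rows pool pair-level values across regions rather than
averaging region means, so regions with more surviving pairs weigh
more.

## Acceptance-check conditions and problem sizes

The package's acceptance checks run entirely on synthetic data at these
sizes: forward-model oracle on a 3×3 (K1, k2) grid; noise-free recovery
on the 15-region template; agreement and stability on a 9-subject
model-correct cohort (noise, jitter and `ref_sd` all zero — with
between-subject k2′ spread a single population k2′ is mis-specified per
subject, and identity-line agreement is unattainable by construction;
that spread is probed explicitly by the k2′-bias experiments instead);
reliability fractions from 200 replicate fits per model; TRT
monotonicity from 200 pairs per noise level; minimum-scan-time
brute-force cross-check on 1000 random tables.

## Known limitations

* The 1TC fit has no delay or blood-volume terms by default (the
  simulator's vB defaults to 0); fitting vB is out of scope.
* No basis-function or multilinear (MRTM/Logan) variants; no voxel-wise
  parametric imaging.
* The frame schedule is a configurable default, not a claim about any
  particular study's framing.
* SEs are asymptotic Gauss–Newton estimates; with heavy noise and
  near-bound solutions they understate uncertainty, which is precisely
  the regime the rSE > 25% filter is designed to flag.
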