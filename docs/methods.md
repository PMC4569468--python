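# Methods

This note records the modeling choices, numerical tactics, defaults and
known limitations of `hepwx`.  Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is asserted
from memory.

## Vascular input functions

The arterial (AIF) and portal-venous (PVIF) input functions are causal sums
of exponentials, `c(t) = Σ A_i e^{−μ_i (t−t0)}` for `t ≥ t0`, with the
constraint `Σ A_i = 0` so the curve rises continuously from zero, plus an
optional recirculation echo (the same curve delayed and scaled).  The
family was chosen because (a) measured first-pass + recirculation input
curves are well described by a small number of exponential modes, and (b)
it is closed under convolution with the exponential/box/delta kernels of
all five kinetic models, which is what makes the tissue curves analytic.
Three exponentials are the default; rates must be distinct because the
closed-form convolutions divide by rate differences (near-coincident rates
are handled by a series expansion, switching below |Δμ·t| < 1e−4).

The built-in synthetic AIF peaks near 3.7 mM roughly 10 s after arrival
(t0 = 0.10 min) and washes out on a minutes scale with a 12% recirculation
echo at +0.5 min; the PVIF arrives 9 s later (t0 = 0.25 min), broader and
lower (peak ≈ 1.3 mM).  These are deliberately conservative
population-scale curves for a peripheral 0.1 mmol/kg Gd-DTPA bolus sampled
with 14-s breath-hold frames, where temporal averaging suppresses the
narrow arterial first-pass peak.  Blood signal is converted to plasma
concentration by inverting the SPGR signal equation for R1(t), then
`C_plasma = (R1 − R10)/r1/(1 − H_LV)`.  Defaults: r1 = 4.5 s⁻¹mM⁻¹
(Gd-DTPA at 1.5 T), H_LV = 0.45, H_SV = 0.25, ρ_T = 1.04 g/cm³.  The
tissue density value is the one that closes the volume identity
v_B + v_I + v_C = 1 on the cohort scales the generator reproduces, which
is strong internal evidence it is the conventional choice for this tissue.
T2*/TE effects are ignored (TE ≪ T2* for the short-TE VIBE readout).

## Kinetic models

All five models share the dual input
`c_in = γ·c_A(t−t_Lag,T) + (1−γ)·c_PV(t−t_Lag,T)` with a single shared
delay t_Lag,T fitted as a free continuous parameter.  Kernels:

* **TK** — `Q_T = K^Trans e^{−k_ep t}` with `K^Trans = E·f`,
  `k_ep = E·f/v_I` (f ≡ F/V_T).  The v_P ≪ v_I limit makes the tissue a
  single interstitial compartment; v_C = 1 − v_I.
* **ETK** — adds the instantaneous vascular term `v_P·c_in`.  The vascular
  delta cannot be drawn on a grid, so `residue_function` displays the
  equivalent plug-flow box of width T_c = v_P/f; concentration curves use
  the exact delta form.
* **2CX** — coupled plasma/interstitium ODEs; the biexponential modes come
  from a closed-form 2×2 eigen-decomposition (no LAPACK calls inside the
  optimizer loop; the degenerate equal-eigenvalue case is split by an
  ulp-scale nudge).
* **AATH** — plug-flow capillary (box of width T_c = v_P/f) followed by
  `E f e^{−k_ep (t−T_c)}`, `E = 1 − e^{−ps/f}`.
* **DP** — plug-flow capillary with distributed back-exchange; after T_c
  the outflow density is `e^{−a}[δ(u−T_c) + e^{−k u}√(ak/u)·I₁(2√(aku))]`
  with `a = ps/f`, `k = ps/v_I`.  The survival tail
  `g(w) = 1 − e^{−a} − ∫₀^w φ` is tabulated by composite 5-point
  Gauss-Legendre on a grid refined on the 1/k scale and interpolated with a
  cubic spline; the Bessel factor is evaluated through the exponentially
  scaled `i1e` so the exponent `−(√(ks)−√a)²` never overflows.

Tissue curves are exact continuous-time convolutions: exponential×
exponential and exponential×box in closed form, the DP tail by piecewise
32-point Gauss-Legendre with integration intervals split at every input
kink.  An independent `numeric_oracle` path (composite-trapezoid discrete
convolution at Δt = 5×10⁻⁴ min default, breakpoint-aligned, with the DP
tail re-derived by cumulative trapezoid) agrees with the analytic path to
≤ 1e−6 relative L2 over 50 random draws per model (acceptance suite).

Per-compartment curves satisfy `C_T = v_P·C̄_P + v_I·C̄_I` by construction
(TK: `v_I·C̄_I`).  For DP, the vascular kernel is taken as the first-pass
box `f·1_{[0,T_c)}` and everything after T_c is attributed to the
interstitial site; strictly, tracer that re-enters the capillary and
transits out is intravascular, so the DP site split (not C_T itself) is an
approximation — its effect on the signal model is bounded by the small
vascular water fraction times the re-entry fraction.

Derived reporting units: BF = f·100/(ρ_T(1−H_LV)) (plasma→blood flow,
mL/min/100 g), BV = v_B·100/ρ_T with v_B = v_P/(1−H_SV), PS stays
plasma-referred (ps·100/ρ_T), MTT = (v_P+v_I)/f by the central volume
principle, v_C = 1 − v_B − v_I.  For TK/ETK, where E is the native free
parameter, the PS report inverts the Crone-Renkin form `ps = −f·ln(1−E)`.

## Water-exchange signal model

Longitudinal magnetization of the blood/interstitium/cell water sites
follows Bloch-McConnell exchange, `dm/dt = −(diag(R1_j(t)) + X)m + c`,
with `c_j = R1_j p_j M0` and X the exchange generator of the chain
B↔I↔C (3S2X) or I↔C (2SX).  Water population fractions equal volume
fractions (equal water density across sites, the standard default;
configurable).  Rates: `K_BI = 1/τ_B`, `K_CI = 1/τ_C`, with reverse rates
fixed by detailed balance, which makes X p-reversible; columns of X sum to
zero (water conservation) and X annihilates the equilibrium populations.

Because tracer concentrations change on seconds while TR = 5 ms, B(t) is
quasi-static within a frame and the pre-pulse steady state of the SPGR
pulse train has the closed form
`m = (I − cosα·e^{−B·TR})⁻¹(I − e^{−B·TR})B⁻¹c`; the enhancement is
`E_T = S(t)/S(0) − 1`.  Detailed balance makes B similar to a symmetric
matrix through D = diag(√p), so all matrix functions are computed by a
vectorized symmetric eigen-decomposition — stable for vanishing blood
fractions and ~10× faster than per-frame `expm`.  The implementation is
validated against a transient pulse-train oracle (explicit matrix
exponentials over thousands of pulses) to ≤ 1e−8 and converges to the
single-pool FXL signal as τ_C, τ_B → 0.

Blood-site relaxation is driven by plasma concentration diluted to whole
blood, `R1_B = R1_B0 + r1(1−H_SV)·C̄_P`; the cell site's R1 is constant
(the tracer is extracellular).  Precontrast defaults: blood T1 1200 ms,
tissue sites 586 ms (1.5 T); synthetic pipelines may draw them from the
VFA fitter instead.  τ_B is a free fit parameter by default (bounded
0.05–5 s) with the documented option to fix it.

## Fitting

Residuals are defined on E_T(t).  Bounded trust-region least squares
(`scipy.optimize.least_squares`, trf) with best-of-n multi-start: one
liver-typical start (f = 0.3 mL/min/mL, γ = 0.5, v_P = 0.15, v_I = 0.2,
E = 0.5 or ps = 0.15, τ_C = 1 s, τ_B = 0.5 s, t_Lag = 0.1 min) plus
seeded Latin-hypercube draws, log-uniform in the scale parameters
(f, ps, τ_C, τ_B).  Default bounds: f ∈ [1e−3, 5] mL/min/mL, γ ∈ [0,1],
v_P, v_I ∈ [1e−3, 0.6], E ∈ [0, 0.99], ps ∈ [1e−3, 5], τ_C ∈ [0.01, 5] s,
τ_B ∈ [0.05, 5] s, t_Lag,T ∈ [0, 0.5] min — these enclose reported
advanced-HCC ranges with margin.  A soft penalty keeps v_B + v_I ≤ 0.97 so
v_C stays positive; near-bound solutions are flagged (`active_bounds`),
not rejected.  With a fixed seed results are bit-reproducible.  Failed
voxels return a non-converged result instead of aborting a map.

### Identifiability — read before trusting per-parameter errors

Two structural facts shape what fitting can deliver:

1. **TK/ETK cannot separate E from f.**  Both enter the forward model only
   through `K^Trans = E·f` and `k_ep = E·f/v_I`; any (E, f) pair on that
   ridge reproduces the data exactly.  The package reports both (bounded),
   but only K^Trans, k_ep, v_P, v_I, γ, τ's and t_Lag are identified.
2. **At 20 frames and enhancement noise SD 0.02, several 3S2X parameters
   are variance-limited.**  A local Cramér-Rao analysis at cohort-typical
   operating points gives relative SDs of hundreds of percent for f, v_P,
   v_I with τ_B free (and still ≫ 10% for 2CX with τ_B fixed).  The
   acceptance suite measures this honestly: noiseless fits recover the
   identifiable parameters to ≪ 1%, while the noisy-recovery medians for
   f and v_I exceed 10% for most vascular models.  The derived v_C is the
   most stable of the fractions (errors in v_B and v_I partially cancel),
   consistent with it being the parameter that carries prognostic signal.

## Survival statistics

* 1-year-survival labels: survivor iff OS ≥ 12 months; patients censored
  before the horizon are excluded with a warning.
* ROC cutoff: thresholds at midpoints of sorted unique values, both
  orientations; minimize (1−sens)² + (1−spec)²; ties break toward higher
  specificity, then the lower threshold, then the high-values-survive
  orientation — fixed for bit-reproducibility.
* LOOCV: each patient is classified by a cutoff estimated without them; the
  modal cutoff is reported (ties → the smaller value); the group with the
  better observed survival (median, then mean, of OS) is labeled low-risk.
  Iterations that lose a class fall back to the full-data cutoff and are
  flagged.
* Log-rank: the standard chi-square statistic, implemented vectorized over
  permutation matrices (lifelines is the cross-check oracle in tests, but
  is far too slow for 200 replicates × 1000 permutations); P values use the
  add-one estimator (1 + #exceed)/(n_perm + 1), with exact enumeration when
  fewer distinct group assignments exist than requested permutations.
* Cox: Newton maximization of the Efron partial likelihood for the single
  covariate log2(parameter), so HR = exp(b) per two-fold change; monotone
  likelihoods (separation) are capped at |b| = 50 and flagged.  The
  permutation statistic is |b|.  Kaplan-Meier curves come from lifelines.
* Percent-risk arithmetic: `100·(e^{δ·ln HR} − 1)` for an absolute
  covariate step δ on the log2 scale (δ = 0.1 for "per 0.1 increase in
  v_C"); the alternative naive reading `100·(1−HR)` is also provided
  because published per-unit-flow statements for arterial blood flow match
  that form rather than the log-scale one.
* No multiple-testing adjustment is applied across parameters or models;
  tables report raw permutation P values, as is common for exploratory
  biomarker screens.  Interpret accordingly.

## Synthetic cohorts

The generator emulates: the breath-hold sampling grid (frame midpoints
5 + 35k + {3.5, 10.5} s; 10 cycles by default — the nominal 4.5-min scan
length corresponds to truncating at 270 s, available as a switch, but the
default keeps all 20 frames); truncated-Gaussian parameter draws per risk
group at published advanced-HCC scales (pooled mean ± SD per model), with
high-risk cohorts drawing v_C higher and γ lower by ±0.5 pooled SD
(directions configurable); the full kinetic × water-exchange forward model
plus iid Gaussian enhancement noise (SD 0.02 default); and exponential
proportional-hazards survival, hazard = (ln2/11.42 month⁻¹)·
exp(b·log2(value/median)), administratively censored at 36 months.
Parameters are drawn independently (joint correlations are not published);
the volume identity is enforced by renormalizing (v_C, v_I) when a draw
leaves v_B < 0.02.  τ_B draws default to 0.5 ± 0.2 s.  Everything is
deterministic under the master seed.

What the generator does **not** emulate: anatomy, motion, coil/B1
inhomogeneity, scanner noise beyond additive Gaussian, inflow enhancement,
and between-parameter correlations.  Passing tests therefore demonstrate
correctness of the computational pipeline under its own assumptions, not
clinical performance on real data.

## Problem sizes and calibration outcomes

The acceptance suite runs, per kinetic model, 50 random draws for the
convolution comparison, 3 noiseless and 100 noisy voxel fits for recovery
(3 starts, 150-function-evaluation cap for the noisy batch; 8 starts
noiseless, where the DP likelihood surface needs the deeper search), 200
null replicates for permutation calibration, and 20
replicates each for the effect/null power check at n = 20 patients.  Two
surfaces do not reach their nominal targets and are reported as genuine
findings rather than relaxed: the noisy-recovery medians for the
parameters listed under *Identifiability*, and the end-to-end power of the
n = 20 effect cohorts (~60% of replicates significant at permutation
P ≤ 0.05 — consistent with the borderline P values such an effect size
produces at that sample size, where ≥90% power would require a stronger
effect, tighter parameter spread, or more patients).

## Known limitations

* The DP per-site concentration split after T_c is approximate (see above);
  C_T and all fitted parameters are unaffected.
* The ETK residue-function display uses a box surrogate for the vascular
  delta; its area deficit relative to v_P + v_I is v_I(1 − e^{−k_ep T_c}),
  which is why conservation checks for TK/ETK integrate the impulse
  response rather than f·R_T.
* ROI means average converged voxels only.
* The LOOCV cutoff frequency table keys are exact float midpoints; data
  with heavy value ties can make the modal cutoff sensitive to rounding in
  upstream processing.
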