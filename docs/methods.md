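# Methods

`scleramech` models the posterior mouse sclera as a biphasic solid — an
incompressible porous elastic matrix saturated with interstitial water,
coupled by Darcy drag — tested in unconfined compression between
frictionless, impermeable platens with a free-draining lateral boundary.
This note records the model, the estimation and statistical procedures, the
synthetic-data generator that stands in for raw study data, and the
numerical and design choices a maintainer would want to know about.

## Constitutive model

Because the tissue is much stiffer in tension than in compression, the solid
skeleton is conewise linear elastic (CLE): each normal direction responds
with a tensile or compressive modulus according to the sign of its normal
strain. In the unconfined-compression protocol the axial direction is always
compressive and the radial/circumferential directions always tensile, so the
relevant constants are

- `H_A_plus` — aggregate modulus on the tensile branch (Pa), the "tensile
  stiffness" reported per step; typical posterior mouse sclera scale ~1 MPa;
- `H_A_minus` — aggregate modulus on the compressive branch (Pa);
- `lambda2` — off-diagonal (normal–normal coupling) modulus (Pa);
- `k` — hydraulic conductivity (m⁴ N⁻¹ s⁻¹), the "permeability"; scale
  ~10⁻¹⁶–10⁻¹⁵ for dense collagenous tissue.

Compressive axial strain and stress are positive throughout the mechanics
modules.

## Series solution (cle_forward)

With a spatially uniform prescribed axial strain ε(t), the dilatation obeys
a radial diffusion equation with diffusivity `D = H_A_plus * k`, giving the
gel diffusion time `τ_g = a² / (H_A_plus k)` for a disk of radius `a`.
Separation of variables yields eigenvalues `α_n`, the positive roots of

    C(x) = J₁(x) − β x J₀(x),    β = H_A_plus / (H_A_plus − lambda2),

which reduce to the zeros of J₁ at β = 0 and approach the zeros of J₀ as
β → ∞. Roots are bracketed between consecutive zeros of J₁ and J₀ (where a
sign change is guaranteed) and refined with Brent's method to 1e-12 relative
tolerance.

The stress response to a unit strain step is

    σ(t) = E_eq + Σₙ Bₙ exp(−αₙ² t / τ_g),

with the drained unconfined modulus and modal amplitudes

    E_eq = H_A_minus − 2 λ₂² / (H_A_plus + λ₂),
    Bₙ   = H_A_plus / (β² αₙ² − 2 β + 1).

Sanity identities used as tests: at H_A_plus = H_A_minus with λ₂ the Lamé
constant, E_eq reduces to the drained Young's modulus μ(3λ+2μ)/(λ+μ), the
instantaneous (undrained) modulus to 3μ, and β to the classical isotropic
shape constant (1−ν)/(1−2ν); Σ Bₙ equals the undrained-minus-drained modulus
gap.

A finite loading ramp is handled by Duhamel superposition of the step
response (exact for this linear model), evaluated with `expm1` in a form
that cannot overflow for small time constants. Truncation: terms are added
until the next term contributes < 1e-10 of the accumulated transient at the
earliest positive sample time, hard-capped at 200 roots (the Bₙτₙ tail
decays like αₙ⁻⁴, so the cap bounds the tail error near 1e-7 relative); the
term count is recorded in trace metadata.

## Finite-difference oracle (fd_oracle)

An independent solver integrates the radial PDE for the radial displacement
u(r,t),

    ∂u/∂t = D ∂/∂r[(1/r) ∂(ru)/∂r] + (r/2) dε/dt,

with u(0)=0 and the rim traction condition
`H_A_plus ∂u/∂r + λ₂ u/a = λ₂ ε(t)`, using Crank–Nicolson time stepping
(two backward-Euler startup steps damp the ramp-onset kink), second-order
central differences, and a ghost node for the Robin rim condition. The
measured stress needs only the rim displacement:

    σ(t) = (H_A_minus − λ₂) ε(t) + (H_A_plus − λ₂) u(a,t)/a.

Hold-phase time steps grow geometrically (factor 1.05 per step, capped at
40× the base step) because the late response is smooth; refining the base
step rescales every step, so convergence studies remain meaningful. The
oracle and the series solution are cross-checked to < 1% on hold-phase
stresses over random parameter draws; the oracle additionally satisfies
non-negative interior pore pressure during the ramp, a free-draining rim,
and discrete mass conservation (solid volume change = Darcy efflux) within
~1–2%.

A runtime check asserts the kinematics stay inside the assumed strain cone
(tensile radius/hoop, compressive axis). The threshold is 1e-4 of the peak
displacement: a genuine cone exit is O(peak), while Crank–Nicolson ringing
around the u = 0 equilibrium sits many orders below.

## Step fitting (uct_fitting)

Raw records are load–time traces in µN per step. Preprocessing subtracts
the first-sample load (the tare / previous-step equilibrium baseline) and
converts to engineering stress on the reference area (500 µN on a 1 mm disk
= 636 Pa, the protocol's tare stress).

Estimation is two-stage, with exactly the two reported properties free:

1. **Plateau.** The tail (t ≥ T/4) is fit with `a + b·exp(−t/τ)` over a
   small τ grid; the intercept `a` is the plateau (this subtracts the
   residual transient a plain tail mean would fold into the equilibrium
   modulus, which otherwise leverages into a ~0.2% bias in k). If the
   projected residual transient at the final sample exceeds 5% of the
   plateau the trace is flagged `InsufficientRelaxationError` rather than
   fitted. `E_eq_hat = plateau / applied_strain`.
2. **Transient.** `(log₁₀ H_A_plus, log₁₀ k)` minimize the sum of squared
   stress residuals over ramp + hold with the series model, bounds
   H_A_plus ∈ [10³, 10⁸] Pa and k ∈ [10⁻¹⁸, 10⁻¹²] m⁴/(N·s), five
   log-spaced multi-starts that pair high moduli with low conductivities so
   trial diffusion times sweep the plausible range.

**Coupling convention.** The packaged default fixes `lambda2 = 0`, so
`H_A_minus = E_eq_hat` directly and β = 1. At H_A_plus = H_A_minus this
reduces exactly to the isotropic ν = 0 solution. The alternative — solving
the isotropic identity for λ₂ at the measured E_eq — would force
H_A_minus ≈ H_A_plus and suppress the tension–compression nonlinearity the
model exists to capture, because scleral E_eq is 10–100× smaller than
H_A_plus. The forward model supports arbitrary λ₂ < H_A_plus, only the
fitting and generation conventions pin it.

The residual uses engineering stress and includes both ramp and hold.
Multiple punches from one eye are arithmetically averaged within eye × step;
interocular differences (IOD, treated − contralateral) are computed per step
and averaged. The applied-strain deviation Δε = applied − target is recorded
per step and passed to the statistical model as a covariate, not corrected
mechanically.

## Statistics (stats)

Strictly positive outcomes (moduli, conductivities, ratios) are analysed on
the log scale with fixed effects for eye, arm, step and strain deviation and
an animal-level random intercept (plus an eye-level variance component when
eyes carry repeated steps), by maximum likelihood. This linear mixed model
on log(outcome) is the package's working approximation of a Gamma GLMM with
log link: the mean structure and the percent-change estimands are identical,
the error family differs. A fixed-effects Gamma/log GLM with animal blocks
is provided as a cross-check mode and agrees on the eye contrast in tests.

Percent interocular differences are exponentiated contrasts,
`100·(exp(β)−1)`, evaluated at zero strain deviation (the covariate is
additive on the log scale, so the eye coefficient is itself the corrected
log-ratio), with delta-method (log-scale Wald) intervals. Fixed-effect
significance uses likelihood-ratio tests between the full model and null
models lacking one term. Families of contrasts are adjusted by the
single-step max-|t| (multivariate t) method via seeded Monte Carlo (default
1e5 draws); a single contrast, or a perfectly correlated family, is returned
at its raw p. Refractive error can be negative and gets an identity-link
Gaussian paired analysis. Agreement between paired measurements is
summarised by Lin's concordance correlation with population (1/n) moments.

## Synthetic cohorts (synthetic)

The generator emulates a unilateral form-deprivation study: paired eyes
within animals, arms FD1 (1 week), FD3 (3 weeks) and naive, with separate
refraction and compression cohorts. All randomness flows through per-entity
seeds derived from (master seed, entity keys), so outputs are deterministic
and stable under re-ordering of generation calls.

Key conditions (the packaged fd-study configuration):

- refractive shift per arm: −2.35 ± 1.11 D (FD1), −4.07 ± 0.72 D (FD3),
  0.02 ± 0.37 D (naive); 22 animals/arm in the refraction cohort;
- treated-eye material effects: ×0.708 on H_A_plus and ×1.801 on k (FD1),
  ×0.601 and ×2.314 (FD3), i.e. 1 + percent/100 of the configured percent
  IODs (−29.2/−39.9% stiffness, +80.1/+131.4% permeability); 6 animals/arm
  in the compression cohort;
- baseline material: H_A_plus 1.0 MPa, E_eq 50 kPa, k 3×10⁻¹⁶ m⁴/(N·s),
  lognormal between-animal SDs 0.25/0.35/0.25 (log scale, H/k/E) and
  between-eye SDs 0.08/0.12/0.08 — positivity-preserving variability
  matching the log-link analysis; the baseline gives a first-step relaxation
  time on the tens-of-minutes scale seen in the protocol;
- protocol: three ramp-and-hold steps of 5% nominal strain, 10 s ramps,
  3000 s holds (long enough to pass the equilibration check for the slow
  tail of the parameter distribution), applied strain jittered uniformly
  within ±1.5 percentage points, additive load-cell noise of 10 µN;
- strain-state dependence: per-step true properties scale as
  exp(−3·Δε) for the moduli and exp(−8·Δε) for k (compression closes
  pores), which gives the strain-deviation covariate a real signal to
  remove; because the dependence is exactly log-linear, the corrected EMM
  is unbiased for the configured effect;
- biometry: fixed component means (CCT 105, ACD 320, LT 2000, VCD 650,
  RT 230 µm) with animal- and eye-level Gaussian noise sized to give an AL
  interocular SD near 25 µm, zero configured treatment effect, one average
  refractive index of 1.39 applied to all segments;
- assays: linear DMMB/picogreen standard curves with 0.005 AU absorbance
  noise and triplicate wells; banded "sclera" slide images (12-bit range)
  with Poisson counting noise and configurable treated/control intensity
  ratios (C-4-S reduced at both durations, dermatan sulfate only at three
  weeks).

**No inverse crime.** Compression traces are simulated with the
finite-difference oracle; fitting uses the independent series model.
Recovery tolerances therefore include genuine model-discretisation error,
not just optimizer behaviour.

What the generator does *not* emulate: strain-dependent permeability within
a step, finite-deformation kinematics, platen friction, OCT speckle or
segmentation error, plate-edge effects, staining chemistry. Passing
recovery tests therefore demonstrates that the estimation and statistical
chain is unbiased and correctly calibrated under the assumed data-generating
structure — not that the constitutive model is adequate for any particular
real tissue.

## Problem sizes and numerical defaults

Estimand-recovery runs average 25 generator seeds; the compression cohort
uses 6 animals/arm × 2 eyes × 3 steps with one punch per eye, and the
oracle grid is 64 radial nodes with a 0.75 s base step (hold-phase error
vs. the refined grid ≈ 0.05%). The LRT calibration uses 1000 null
simulations of a reduced paired design (40 animals, one step). Unit tests
run the same operations on smaller, faster-relaxing configurations; the
forward models are scale-free in `a²/(H k)`, so a higher-k test material
probes the same physics at a fraction of the runtime.

## Known limitations

- The Gamma GLMM is approximated by a log-scale LMM (documented deviation;
  estimands identical, error family not).
- λ₂ is not identifiable from a single unconfined-compression protocol and
  is fixed by convention rather than estimated.
- The LRT uses the asymptotic χ² reference; with very few animals the test
  is mildly anticonservative (the calibration test sizes the design
  accordingly).
- Multi-step holds reuse the step's own reference configuration; the radius
  is treated as constant across steps (infinitesimal-strain bookkeeping).
- The IHC threshold step present in some imaging macros is off by default
  and configurable, since no principled default exists.
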