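# Methods

This note documents the models, numerical schemes, default parameters and
design choices behind `odnptraj`, and what the synthetic-data study does
and does not demonstrate about real trajectories.

## Scientific setting

In scalar Overhauser DNP, electron polarization flows to ¹³C nuclei through
the fluctuating Fermi-contact (isotropic hyperfine) interaction of a
radical–substrate complex. At 9.4 T the electron–¹³C zero-quantum
transition sits at ν_e − ν_C ≈ 0.263 THz, so only fluctuations with
sub-ps correlation times contribute to the cross-relaxation rate. Two
fluctuation mechanisms bracket the physics: transient
formation–dissociation "pulses" of short-lived complexes, and structural
dynamics *within* a long-lived complex. A two-state lifetime estimate
τ = K_a/k_on separates the regimes: with a diffusion-limited
k_on = 10¹⁰ M⁻¹s⁻¹, binding constants of 10⁻¹–10⁰ M⁻¹ (typical of
H-bonded complexes) give lifetimes of 10–100 ps — far too slow for the
THz window — while 10⁻² M⁻¹ (halogen-bonded) gives ~1 ps. For long-lived
complexes, intra-complex dynamics must carry the polarization transfer,
and the trajectory analysis in this package is the toolkit for
characterizing exactly those dynamics.

## Trajectory conventions

Time is femtoseconds internally (unit converters only at the boundary);
the reference sampling is 1 fs. Channels carry unit tags (`au` for spin
densities, `A` for distances, `deg` for angles). Trajectories must be
uniformly sampled to 1e-9 relative tolerance and at least 4 points long.
Results are JSON envelopes carrying the full run configuration, package
version and an input checksum.

## Autocorrelation

g(t) = ⟨ρ(t₀)ρ(t₀+t)⟩/⟨ρ(t₀)²⟩ with overlapping origins. Choices:

- **Centering.** The fluctuation language of spin-density dynamics implies
  mean removal, and an uncentered ACF of a nonzero-mean channel plateaus
  at a positive constant, breaking both the memory and the spectral
  stages. Default `centering="mean"`, switchable to `"none"`, recorded in
  every output.
- **Truncation.** Lags are limited to `max_lag_fraction` (default 0.5) of
  the record, preventing the artificial convergence to zero of
  long-lag estimates from a finite record.
- **Estimator.** Denominator over all N points; numerator at lag k over
  the N−k overlapping products divided by N−k. g(0) = 1 exactly; the
  per-lag null standard deviation is 1/√(N−k), widening toward the
  truncation edge.
- **Precision.** The ACF itself is computed in double precision (FFT
  path); a compensated-summation path (`method="fsum"`) agrees to better
  than 12 significant digits and serves as an accuracy reference.
  High-precision arithmetic matters in the memory-kernel recursion, not
  in the ACF sums.
- Non-finite samples abort with an error; silent masking would bias every
  downstream stage.

## Memory kernel

The memory equation ∂g/∂t = −∫₀ᵗ K(τ)g(t−τ)dτ determines K given g
(Laplace-domain K̂(s) = 1/ĝ(s) − s; the formal closed form is treated as
that identity, with the numerical Volterra route authoritative). Direct
quadrature marching on this equation is unstable — K appears only inside
the convolution (first-kind structure) and the parasitic mode is amplified
~2.5× per step. The solver instead marches the once-differentiated
equation

    g''(t) = −K(t)·g(0) − ∫₀ᵗ K(τ) g'(t−τ) dτ,

a genuine second-kind equation in K, lag by lag (Day-style quadrature
marching):

- second derivative of g by central differences; g'(0) = 0 by the even
  extension of a stationary ACF; the lag-0 anchor is
  K(0) = 2(g₀ − g₁)/(dt² g₀);
- the convolution uses the **product-trapezoid (Stieltjes) rule**
  Σ ½(K_j + K_{j+1})(g_{m+1} − g_m), whose increments telescope exactly
  for constant kernels. Consequence: the discrete scheme reproduces the
  closed-form benchmarks exactly up to the O((ω dt)²) dispersion of the
  difference stencils — g = cos(ωt) gives a constant kernel within
  (ω dt)²/12 (3.3×10⁻⁴ at 100 fs period, 1 fs sampling) at *every* lag,
  and g = e^{−t/τ} gives a kernel that vanishes identically beyond the
  first grid point. An end-corrected Gregory trapezoid on the sampled
  integrand is retained (`quadrature="gregory"`) for comparison; its
  O(dt²) constant-kernel inconsistency resonates with undamped oscillatory
  ACFs and grows secularly as t², which is why it is not the default.
- any delta component of the true kernel is absorbed by the first grid
  point (K(0) ≈ 2λ/dt + smooth part for an e^{−λt}-type ACF); that point
  is flagged `delta_contaminated` and excluded from smooth-oracle
  comparisons.

The recursion feeds its own output forward, so rounding compounds; all
recursion arithmetic runs in stdlib `decimal` at `precision_digits`
(default 100). Every solve runs the exact inverse recursion
(`reconstruct_acf`, same quadrature) and stores
max |g_reconstructed − g| over the first half of the lags as
`roundtrip_error`; `precision_drift_report` repeats the round trip over a
digit ladder, and the error is monotone non-increasing in precision by
construction of the shared discretization. Kernels of *sample* ACFs carry
statistical noise in their tails; `kernel_support(mode="first")` reads the
memory time as the first drop of |K| below 1% of its peak, while
`mode="sustained"` is the strict support for closed-form inputs.

## Spectral density

One-sided cosine transform J(ω) = 2∫₀^∞ g(t)cos(ωt)dt by trapezoid
end-corrected summation; the convention string is embedded in every result
because normalizations vary across the literature. No apodization by
default (a half-cosine taper is available and recorded when applied).
Relative accuracy follows the trapezoid error (ω dt)²/12; a Parseval check
∫J dω/π = variance is exposed as `parseval_mismatch`. The zero-quantum
frequency is ω_ZQ = 2π(ν_e − ν_C) and the rate estimate uses the declared
convention R_ZQ = ¼(2π a_iso)² J(ω_ZQ) (a_iso in Hz, J in s); different
spectral-density normalizations rescale absolute rates but not their
ordering across sites, so outputs are labelled convention-dependent.
Negative J values (truncation artifacts) clamp the rate at 0 with a flag.

## Inverse Laplace transform

Decaying ACFs are decomposed over a log-spaced grid of exponentials
(default 60 points/decade over 10⁻³–10² ps, spanning sub-0.1 ps initial
decays and 0.5–1 ps slow components with margin) by Tikhonov-regularized
nonnegative least squares with a second-difference smoothness operator —
the CONTIN formulation without its moment constraints and
probability-to-reject machinery. λ can be chosen at the L-curve curvature
maximum; for noisy sample ACFs a moderate fixed λ (10⁻³) is steadier, as
the L-curve corner tends to undersmooth and split single decays. Long ACFs
are subsampled to ≤600 log-spaced rows, which preserves both fast and slow
information while keeping the NNLS well conditioned. Oscillatory ACFs are
truncated at the first zero crossing (an exponential basis cannot
represent negative lobes); the truncation index is recorded.
`summarize_components` integrates watershed regions around local maxima
and reports mass-weighted log-mean positions, which are steadier than raw
argmax positions on a discrete grid.

## AR modelling

Conditional least squares (the linear regression of x_t on its p
predecessors) rather than Yule–Walker, for smaller finite-sample bias; an
order scan conditions every fit on the same p_max initial samples so AIC
values are comparable. AIC = n_eff ln σ̂² + 2(p+1) — the convention is
printed with every fit because absolute AIC values are software-specific;
only differences and the argmin carry meaning. Stationarity is verified
via the companion-matrix spectral radius.

Order selection reports two quantities. The **AIC argmin** has the
classical nonvanishing overselection probability (~20–30% across a few
spurious orders). The **convergence order** is the first p at which adding
a lag moves the shared coefficients φ₁..φ_p by less than 1% of the
coefficient vector's aggregate (L1) scale and changes the innovation
variance by less than 1%: an irrelevant extra lag leaves both nearly
unchanged, a relevant one shifts them. The aggregate scale is the design
choice that makes the 1% threshold commensurate with estimation noise at
n = 10⁴; per-coefficient relative changes would be noise-dominated for
small coefficients. `selected_order` is the convergence order when one
exists, falling back to the AIC argmin — mirroring the physical reading
that the converged order is the minimal memory needed, with p·dt the
memory time in fs. An ARMA(p,1) AIC can be reported side by side but is
never selected automatically: a moving-average term has no direct
interpretation as a time-point correlation of the physical process.

## ODNP bookkeeping

ε_OE = (I_DNP/I_Boltzmann)(n_Boltzmann/n_DNP) − 1. The error model takes
ΔI = 1/SNR literally as the absolute uncertainty of each integral as
entered (the natural reading when integrals are normalized to the
reference); Δε follows by first-order Gaussian propagation through both
integrals and is validated against brute-force Monte Carlo (agreement
within 5% for SNR ≥ 10; the 1/I_Boltzmann nonlinearity contributes ~1% at
SNR = 10). δ̄_para is the OLS slope of shift vs radical concentration with
the regression SE as its error; for carbons overlapping on the DNP
spectrum, the SD across their slopes is reported as well. The lifetime
model is two-state dissociation, τ = 1/k_off = K_a/k_on, with k_on
supplied by the user (default diffusion-limited 10¹⁰ M⁻¹s⁻¹) — a declared
model, not an inference. Capillary volumes are π(d/2)²l, rounded to
integer nL only in human-readable output. The constants table uses CODATA
gyromagnetic ratios; the derived electron/nucleus ratios round to −658
(¹H) and −2617 (¹³C).

## Synthetic generators: what they emulate, and what they do not

The generators reproduce the *statistical* structure the analysis assumes
in spin-density and geometry channels of an H-bonded radical–substrate
complex at 1 fs sampling:

- `DefaultConditions` mirrors a 10 ps, 10⁴-step record. The
  damped-oscillation surrogate combines a fast 0.05 ps decay carrying a
  0.3 ps wave (weight 0.7) with a slow 0.7 ps exponential (weight 0.3) —
  a sub-0.1 ps initial decorrelation, sub-ps oscillations, and a slower
  0.5–1 ps component.
- OU uses the exact discrete update x_{k+1} = x_k e^{−dt/τ} +
  σ√(1−e^{−2dt/τ}) ξ_k from a stationary start. Damped-cosine components
  are realized as the real part of an exactly discretized complex OU
  recursion (an AR(2)-equivalent real process), so the target ACF
  Σ wᵢ e^{−t/τᵢ}cos(ωᵢt) is exact — no integrator error. A plain real
  AR(2) was rejected because its ACF carries a large phase term
  (∝ cot(ω dt/2)) at sub-ps wave periods.
- The pulse model is an alternating renewal (telegraph) process:
  exponential off-times (mean 1/encounter rate), exponential on-times
  (mean contact duration), rectangular amplitude — the minimal faithful
  waveform for encounter-driven contact.
- `ar6_reference_spec` freezes the AR(6) fit to a three-component
  damped-oscillation surrogate with fs-scale waves, giving a genuinely
  identifiable 6-step memory: all six coefficients sit far above the
  n = 10⁴ estimation noise.
- Titration tables are linear in concentration with Gaussian ppm noise
  over the 0–200 mM window.

Amplitude statistics are Gaussian (except the two-valued pulse model).
Real spin-density fluctuations need not be Gaussian, are coupled across
sites through the shared electronic structure, and ride on slow
conformational drifts; passing tests on these surrogates therefore
validates the *estimators and numerics*, not any claim about a specific
molecular system. Sample sizes in the test suite (10⁴–10⁶ points,
50–100 replicates, kernel solves on 600–2000 lags) were chosen so each
statistical check has ~3σ headroom while the full suite stays well under a
minute of kernel arithmetic.

## Known limitations

- The zero-quantum rate prefactor is a declared convention pending a
  definitive normalization; compare rates only within one convention.
- The ILT, like all regularized exponential inversions, localizes slow
  components of a 10 ps record only to within roughly a factor of two
  and can split single decays when the sample ACF tail is noisy.
- The convergence-based order selector assumes coefficients well above
  1/√n; for marginal processes it may admit one extra lag (the AIC argmin
  is always reported alongside).
- The memory-kernel solver requires g(0) = 1 and a uniform lag grid; it
  does not handle gappy or nonuniformly sampled records.
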