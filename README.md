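# odnptraj

Trajectory time-series analysis and quantification for **scalar Overhauser
dynamic nuclear polarization (ODNP)** in radical–substrate complexes.

Scalar ODNP transfers polarization from an unpaired electron to nearby
nuclei (here ¹³C) through the *fluctuating Fermi-contact interaction* of a
transient or long-lived radical–substrate complex. At high magnetic field
(9.4 T) the efficiency is set by the spectral density of those fluctuations
at the electron–¹³C zero-quantum frequency, ω_ZQ = 2π(ν_e − ν_C) ≈ 2π·0.263
THz — deep in the sub-ps motional regime. This package provides the complete
analysis chain from a fluctuating spin-density trajectory (e.g. extracted
from a QM/MM MD run at 1 fs sampling) to the quantities that characterize
the mechanism, plus a synthetic-trajectory module that stands in for the MD
engine so every stage is testable end to end.

## What it computes

For a stationary channel ρ(t) sampled uniformly in fs:

- **ACF** — g(t) = ⟨ρ(t₀)ρ(t₀+t)⟩ / ⟨ρ(t₀)²⟩, mean-centered by default,
  evaluated only up to half the record length to avoid spurious
  convergence; inter-channel covariance matrices (`correlate`).
- **Memory kernel** — K(τ) solving the Volterra memory equation
  ∂g/∂t = −∫₀ᵗ K(τ) g(t−τ) dτ, marched at up to 100 decimal digits with a
  forward-reconstruction round-trip error stored for every solve
  (`memkernel`). A delta-like kernel marks Markovian dynamics; extended
  support measures the physical "memory time".
- **Spectral density** — J(ω) = 2∫₀^∞ g(t) cos(ωt) dt, evaluated at ω_ZQ,
  and the convention-pinned zero-quantum cross-relaxation rate
  R_ZQ = ¼(2π a_iso)² J(ω_ZQ) (`spectral`).
- **Correlation-time spectra** — CONTIN-style regularized inverse Laplace
  transform of decaying ACFs into nonnegative distributions over log-spaced
  correlation times (`ilt`).
- **AR models** — conditional least-squares AR(p) fits, AIC tables,
  coefficient-convergence order selection, stationarity and whiteness
  checks; p·dt is the memory time in fs (`armodel`).
- **ODNP bookkeeping** — ε_OE = (I_DNP/I_Boltzmann)(n_Boltzmann/n_DNP) − 1
  with Gaussian error propagation from spectral SNR; molar-free
  paramagnetic shifts δ̄_para (ppm/M) from titration slopes; two-state
  complex lifetimes τ = K_a/k_on; capillary sample volumes; CODATA
  gyromagnetic-ratio table (`odnp`).
- **Synthetic generators** — exact-discretization Ornstein–Uhlenbeck,
  telegraph "pulse-model" contact trajectories, stationary AR(p), and
  Gaussian processes with damped-cosine ACFs (fast sub-0.1 ps decay plus
  sub-ps waves), all seed-deterministic (`synth`).

## Worked example

```python
import numpy as np
from odnptraj import RunConfig
from odnptraj.synth import DefaultConditions, gen_damped_osc
from odnptraj.correlate import compute_acf
from odnptraj.memkernel import solve_memory_kernel
from odnptraj.spectral import ZqParams, acf_to_spectral_density, zq_frequency

cond = DefaultConditions()                      # 10^4 points at 1 fs
traj = gen_damped_osc(cond.damped_osc_spec(), cond.n, cond.dt_fs, seed=7)
acf = compute_acf(traj, "dosc", RunConfig())
kern = solve_memory_kernel(acf, RunConfig(precision_digits=100))
sd = acf_to_spectral_density(acf, normalized=True)
w_zq = zq_frequency(ZqParams(nu_e=263.0, nu_c=0.1006))
print(f"g decays below 1/e within {acf.lags[acf.g < np.exp(-1)][0]:.0f} fs")
print(f"kernel round-trip error {kern.roundtrip_error:.1e}")
print(f"J(omega_ZQ) = {sd.at(w_zq):.3e} ps")
```

prints (seed 7):

```
g decays below 1/e within 49 fs
kernel round-trip error 1.0e-103
J(omega_ZQ) = 9.339e-03 ps
```

i.e. the surrogate decorrelates on the sub-0.1 ps scale, the 100-digit
kernel solve is self-consistent to the working precision, and the spectral
density retains finite weight (~9×10⁻³ ps) out at the THz zero-quantum
window, where only sub-ps motion contributes.

The `analysis/` directory holds numbered drivers that run the same chain as
a narrative study (simulate → ACF/covariance → memory kernels → spectral
densities at ω_ZQ → correlation-time spectra → AR order selection → ODNP
bookkeeping), each printing what it found and writing a summary table under
`results/`.

A CLI mirrors the library:

```bash
odnptraj simulate --model dampedosc --params p.json --n 10000 --seed 7 --out t.tsv
odnptraj acf --input t.tsv --column dosc --out acf.json
odnptraj memory --input acf.json --digits 100 --out kernel.json
odnptraj spectrum --input acf.json --eval-zq --aiso 1.0
```

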