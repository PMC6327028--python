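# Methods

## The physical model

The package models picosecond pulse-radiolysis transient absorption of an
electron scavenger (a pyrimidine nucleoside) dissolved in a viscous glycol.
A short high-energy electron pulse ionizes the solvent and deposits excess
electrons; within the pulse a quasi-free electron either begins to relax
toward solvation or attaches to the solute. The kinetic scheme is a linear
cascade with a within-pulse branching:

```
             1 - exp(-C/C37)
  e_qf  --------------------------->  TNI*  --tau_tni-->  fragments (dark)
    |  exp(-C/C37)
    v
  e_ir  --tau1-->  e_vis(hot)  --tau2-->  e_sol
                                            |  1/tau_esol + k_attach C
                                            v
                             decay  /  ground-state anion
```

* **Branching.** The fraction of electrons captured within the pulse follows
  the exponential scavenging law `1 - exp(-C/C37)`; the scavenging capacity
  `C37` is the concentration at which the surviving fraction is `1/e`.
  The default `C37 = 0.37 mol/L` is the least-squares compromise between the
  two capture-fraction anchors the analysis reproduces (12% at 0.05 M and
  75% at 0.5 M, which by themselves imply 0.391 and 0.361 mol/L — the two
  anchors are not exactly consistent with a single exponential).
* **Relaxation.** The pre-solvated electron relaxes through a near-IR
  ("p-like") state decaying with `tau1 = 45 ps` into a hot visible state
  that relaxes with `tau2 = 80 ps` into the solvated electron (630 nm).
  The continuous blue shift of the visible band (~750 → 630 nm) is
  represented either as this two-state discretization (*bilinear* mode, the
  factorization curve resolution assumes) or as a band whose center actually
  moves, `lambda(t) = 630 + 120 exp(-t/tau2)` nm (*shifting* mode, which
  violates bilinearity the way the real band does).
* **Anion.** The excited anion TNI\* decays with `tau_tni = 350 ps` to
  non-absorbing fragments (dissociation rather than relaxation). The
  solvated electron decays with its intrinsic `tau_esol = 5 us` plus a slow
  attachment channel `k_attach C` (`k_attach = 5e8 /M/s`, a package default;
  only its long-time effect matters), the attached branch feeding the stable
  ground-state anion.

All populations are closed-form (Bateman cascade; the degenerate equal-rate
case has its own closed form to avoid catastrophic cancellation).

## The synthetic-data generator

`radtas.synthetic` produces wavelengths × delays optical-density matrices:

* grids: 370–1100 nm in 5 nm steps; delays −20…500 ps in 2 ps steps
  (ps mode) or 200 log-spaced points from 10 ps to 20 µs (µs mode; a
  log-spaced grid cannot start at 0);
* species bands (Gaussian, peak OD at the reference dose 25.3 Gy):
  e_ir 1080/220/0.080, hot-vis 750/210/0.070, e_sol 630/230/0.060,
  TNI\* 400/150/0.050, anion 520/140/0.040 (center/fwhm in nm/amplitude).
  The 630 and 750 nm centers are the observed band positions; the rest are
  package defaults chosen for spectral distinguishability. Amplitudes follow
  dosimetry realism: G(e⁻)·25 Gy ≈ 5 µM and ε ≈ 1.5×10⁴ /M/cm give a few
  0.01 OD;
* a 7 ps FWHM Gaussian instrument response, applied by discrete convolution
  on a supersampled time grid (the populations switch on sharply at t = 0;
  convolving on the coarse 2 ps grid leaves discretization residuals above
  the noise floor);
* additive i.i.d. Gaussian noise, default SD 5×10⁻⁴ OD (≈1% of the peak
  signal, typical of accumulated pulse-radiolysis kinetics), seeded;
* a masked detector region 770–790 nm (notch filter), stored as NaN rows;
* dose scaling strictly linear in dose/25.3 Gy.

What the generator does **not** emulate: shot-to-shot drift, wavelength-
dependent noise, spur recombination kinetics, solvent heating, or any
non-Gaussian band shape beyond the optional log-normal. Passing parameter
recovery here demonstrates the correctness of the estimators under the
stated model, not their robustness to those real-data effects.

## Analyses

**Global lifetime analysis** (`solvation.global_fit`): per wavelength
`offset + Σ_i DAS_i exp(-t/tau_i)` convolved with the Gaussian IRF
(closed form via `erfcx` for stability). The shared `tau_i` are optimized on
a log₁₀ scale (bounds 0.1 ps–10⁷ ps, trust-region least squares), with the
linear amplitudes projected out at every step (variable projection).
Negative decay-associated amplitudes (rise components) are allowed; the
non-decaying offset absorbs the solvated electron, which is effectively
stable on the ps window. Time constants are reported sorted ascending.

**Peak tracking** (`solvation.track_peak`): per delay, the band maximum is
the vertex of a least-squares quadratic in log-absorbance over ±8 grid
points (±40 nm) around the discrete argmax — exact for a Gaussian band at
any stencil width; the wide stencil suppresses the nm-scale vertex noise a
3-point parabola exhibits at this noise level. Delays whose maximum cannot
be bracketed away from the window edge, or whose vertex extrapolates outside
its stencil, are omitted. The relaxation
`lambda(t) = lambda_inf + shift · exp(-t/tau_shift)` is then fit with a
soft-L1 loss and multiple initial `tau_shift` values (a `tau_shift` below
the sampling resolution leaves the amplitude unconstrained and is rejected).
The reported total shift is the fitted amplitude, i.e. the model's
`lambda(∞) − lambda(0)`, since the band is not yet measurable at t = 0.

**Log-linear lifetimes** (`estimate_lifetime_loglinear`): OLS of ln(signal)
vs t inside a window where the trace is strictly positive; reports
`tau = -1/slope`, the half-life `tau·ln 2`, and r².

**Rank estimation** (`deconvolution.estimate_rank`): singular values of the
unmasked matrix; the noise floor is the median of the trailing half of the
spectrum (clamped at 10⁻¹² of the leading value for noiseless input), and
singular values above 5× the floor count as species.

**MCR-ALS** (`deconvolution.mcr_als`): alternating non-negative least
squares (active-set NNLS per column; ridge fallback `1e-10·trace` on
failure), lack of fit `100·sqrt(ΣR²/ΣD²)` tracked per iteration and
non-increasing; convergence when it changes by < 10⁻³ percentage points
(default), hitting `max_iter = 500` flags rather than raises. Scale
ambiguity is fixed by unit-maximum spectra with compensating profiles;
permutation ambiguity is resolved against a reference by brute-force
Pearson matching (`match_components`). Optional constraints: unimodal
profiles (isotonic projection on each side of the mode) and frozen spectrum
columns.

*Identifiability.* With four heavily overlapping bands the non-negativity
constraint alone does not pin the factorization: the lack-of-fit surface is
flat along rotations that trade excited-anion kinetics against electron
kinetics, and ALS drifts along it from any inexact initialization (verified
by initializing at the exact truth, which is a fixed point at the same lack
of fit). The band *positions* survive these rotations — the solvated-electron
spectrum peak is recovered at 630 ± 10 nm from the plain purest-variable
run — but the anion *lifetime* does not. The package therefore derives the
anion kinetics with the fixed-species variant: rank-3-denoised snapshot
columns of the neat-solvent matrix (defaults 8, 60, 450 ps) are frozen as a
non-negative basis of the electron spectral subspace, leaving the anion in
the free component. This mirrors the experimental fact the subtraction
route also exploits: the electron spectra in solution are identical to the
neat solvent's. The frozen-basis route carries a small (~ −10%) lifetime
bias from residual electron leakage at the earliest snapshot.

*Initialization.* Purest-variable selection uses the SIMPLISMA purity
`SD/(mean + α)` with α = 5% of the largest row mean and a determinant-based
independence weight for subsequent picks.

**Reference subtraction** (`subtract_reference`): per delay, the scalar
least-squares match of the neat matrix to the solution over the
electron-only 900–1000 nm window, shrunk toward the global scale with
`λ = 0.1·max_t(window power)` — without shrinkage the late-time scale is
noise-dominated once the near-IR signal has decayed, and the injected scale
noise multiplies the full neat spectrum. The isolated matrix is
`solution − scale·neat` with the union mask.

**Scavenging analysis** (`scavenging`): the initial near-IR absorbance is
the mean over 900–1000 nm and the first three delays after t₀ + IRF FWHM;
`A(C) = a0·exp(-C/C37)` is fit by absorbance-weighted least squares on
ln A vs C; capture fractions, the yield curve (`yield + capture = 1`
exactly), the model-free amplitude-ratio route, the `1/(kC)` scavenging
time, shape-invariance of normalized IR kinetics (max pairwise RMS of
unit-normalized band integrals) and the linearity of the new-species
amplitude with electrons captured.

## Problem sizes and reproducibility

The default matrices are 147 × 261 (ps mode) and 147 × 200 (µs mode); the
full pipeline (`radtas report`, five stages) runs in about a second, and
`scripts/acceptance.py` regenerates every dataset and analysis from one
seed in a few seconds. Every stochastic stage derives its seed from the run
seed via `SeedSequence.spawn`, so the machine-readable report is
byte-identical across reruns.

## Known limitations

* The bilinear/shifting dichotomy brackets, but does not reproduce, a
  genuinely inhomogeneously relaxing band; applying MCR to shifting-mode
  data is supported but model-violating (inflated lack of fit, by design).
* Unconstrained MCR lifetimes are rotationally biased (above); use the
  frozen-electron-basis route or the subtraction route for kinetics.
* The log-linear lifetime estimator is biased at low signal-to-noise
  (log of near-zero values); `positive_fit_window` only guards positivity.
* No rotational-ambiguity band computation, kinetic-constrained (hybrid)
  MCR, multiset analysis, maximum-entropy lifetime distributions, or
  dosimetry conversion to absolute concentrations.
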