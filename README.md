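# radtas

Pulse-radiolysis transient-absorption kinetics in Python: simulation of
multi-species electron relaxation and attachment transients with known
ground truth, and the analysis chain that recovers it — global
multi-exponential lifetime fitting, MCR-ALS species deconvolution,
neat-solvent reference subtraction, and exponential electron-scavenging
yield modelling.

## The problem

When a picosecond electron pulse ionizes a liquid, the ejected electrons
relax stepwise — quasi-free → weakly bound near-IR states → a solvated
electron with a broad visible band — while a dissolved scavenger (here a
pyrimidine nucleoside at 0.05–0.5 mol/L) competes for them. Electrons
captured while still quasi-free form an excited transient negative ion
(TNI\*) that decays in a few hundred picoseconds by glycosidic bond
rupture, the elementary step of electron-induced DNA damage. The
experimental observable is a time–wavelength absorbance matrix
ΔOD(λ, t), 370–1100 nm × ps–µs, and the questions are quantitative:

* the solvation time constants τ₁, τ₂ shared across wavelengths
  (global fit: `ΔOD(λ,t) = off(λ) + Σᵢ DASᵢ(λ) e^{−t/τᵢ} ⊛ IRF`);
* the blue shift of the relaxing visible band,
  `λ(t) = λ∞ + Δλ·e^{−t/τ₂}`;
* the species spectra and kinetics hidden in the matrix
  (`D ≈ S Cᵀ`, both factors non-negative — MCR-ALS), or equivalently the
  anion signal isolated by subtracting the scaled neat-solvent matrix;
* the scavenging law `A(C) = A₀ e^{−C/C37}` with capture fraction
  `1 − e^{−C/C37}`, and the scavenging time `1/(kC)`.

No public dataset accompanies the study this emulates, so
`radtas.synthetic` generates matrices with the full kinetic/spectral/noise
structure from known parameters, and every estimator is validated by
parameter recovery.

## Worked example

```python
from radtas import neat_solvent_matrix, global_fit, track_peak

neat = neat_solvent_matrix(seed=7)            # 147 x 261 OD matrix, 25.3 Gy
fit = global_fit(neat, n_components=2)        # shared-tau variable projection
print(fit.time_constants)                     # [44.21 81.13]  (truth: 45, 80 ps)

shifting = neat_solvent_matrix(seed=3, mode="shifting")
traj = track_peak(shifting, window=(550, 900), t_range=(10, 500))
print(round(-traj.total_shift, 1))            # 121.2  nm blue shift (truth: 120)
```

The two fitted time constants are the electron relaxation steps (near-IR →
visible transfer, and the visible-band relaxation that shows up as a
~120 nm blue shift toward the 630 nm solvated-electron band); the residual
RMS of the fit (5.0×10⁻⁴ OD) equals the injected noise.

The whole chain — simulation, global fit, peak tracking, rank estimation,
MCR-ALS, reference subtraction, scavenging fit, long-time lifetime — runs
as one command:

```bash
radtas report --seed 1 --out results/
```

which prints (abridged):

```
"tau1_ps": 44.29,            "tau2_ps": 81.23,
"blue_shift_nm": 119.3,      "esol_peak_nm": 620.0,
"tau_tni_subtraction_ps": 361.8,  "tau_tni_mcr_ps": 310.3,
"c37_mol_per_l": 0.372,      "capture_pct_0p05M": 12.6,
"capture_pct_0p5M": 73.9,    "tau_esol_us": 4.98
```

i.e. both routes to the excited-anion lifetime land near the 350 ps ground
truth, the scavenging fit reproduces the 12%/75% capture fractions, and the
solvated electron's 5 µs lifetime is recovered on the µs-mode matrix.
Reports are byte-identical across reruns with the same seed. The other
subcommands (`simulate`, `globalfit`, `trackpeak`, `mcr`, `subtract`,
`scavenging`) operate on the CSV matrix format documented in `radtas.io`.

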