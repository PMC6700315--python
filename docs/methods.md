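# Methods

## Model and assumptions

`txtlkit` models batch-mode cell-free expression of a single reporter gene
under a sigma-70 promoter with three ODEs (mRNA, dark reporter, mature
reporter) and two algebraic conservation laws for core RNA polymerase and
ribosomes. The assumptions baked in:

- Michaelis–Menten quasi-steady state for transcription, translation and
  mRNA degradation.
- Nutrients (NTPs, amino acids, tRNA) are unlimited during the phases
  modelled; none of the machinery degrades. The model therefore covers only
  the initial transient and the steady-state phase (roughly the first six
  hours); the late plateau caused by nutrient depletion and pH drift is out
  of scope, as is protein degradation.
- Sigma-70/core binding is at fast equilibrium (dissociation constant K70),
  so the holoenzyme is E70 = E0·S70/(K70 + E0).
- mRNA degradation is effectively first order (k_deg,m = kd_m/KM_m) but is
  kept in saturating Michaelis–Menten form so the mRNA concentration cannot
  be driven negative numerically. The individual values of kd_m and KM_m are
  immaterial as long as their ratio is fixed and KM_m ≫ [m]; the simulator
  warns when a trajectory exceeds KM_m/10.
- Maturation of the dark reporter is first order with rate k_mat.
- Elongating machinery is booked against the pools via occupancy factors
  1 + kcat_m·Lm/Cm (polymerases per initiating polymerase) and
  1 + kcat_p·Lm/Cp (ribosomes per initiating ribosome).

Saturation of protein synthesis with plasmid concentration emerges from
ribosome depletion: the steady-state ribosome demand is m_ss·(1+kcat_p·Lm/Cp),
and once it approaches R_tot the free pool collapses. With the best-fit
constants this crossing sits at 5.2 nM plasmid, matching the observed sharp
transition near 5 nM; free polymerase remains above 100 nM through 30 nM
plasmid, so transcription never limits in this range.

## Parameters

All concentrations nM, times s. Defaults (see `best_fit_parameters()`):

| name | default | meaning |
|---|---|---|
| kcat_m | 6.5e-2 1/s | transcription initiation rate constant (promoter strength) |
| KM_70 | 1 nM | Michaelis constant of transcription initiation |
| K70 | 0.26 nM | sigma-70/core RNAP dissociation constant |
| S70_total | 30 nM | total sigma-70 (literature range 30–35; model insensitive within it) |
| E_total | 400 nM | total core RNA polymerase |
| kd_m, KM_m | 6.6 nM/s, 8000 nM | mRNA degradation Vmax and Michaelis constant; ratio 8.25e-4 1/s (20.2 min lifetime) |
| kcat_p | 6e-3 1/s | translation initiation rate constant (UTR strength) |
| KM_R | 10 nM | Michaelis constant of translation initiation |
| R_total | 1100 nM | total active ribosomes |
| k_mat | 1.2e-3 1/s | reporter maturation rate — placeholder (~14 min); the measured value is not transcribed here. No headline quantity depends on it (total protein is invariant to k_mat) |
| Cm, Cp | 10, 2.5 nt/s | elongation speeds. Cp is kept at the printed 2.5 nt/s even though 1 aa/s would be 3 nt/s; the discrepancy is noted, not silently corrected |
| Lm | 750 nt | transcribed length for simulation; the load calculator's reference length is 800 nt |

Initiation rate constants above 0.5 1/s trigger a warning (physiological
ceiling on initiation frequency), not an error.

## Numerics

- Polymerase balance: bracketed Brent root on [0, E_total], xtol 1e-12. The
  residual is strictly increasing in E0, so the root is unique. Solved once
  per parameter set (it does not depend on the mRNA level).
- Ribosome balance: closed-form positive root of
  R0² + R0(KM_R + m·occ − R_tot) − KM_R·R_tot = 0, evaluated in a
  cancellation-safe form; verified in tests against bisection to 1e-9 nM
  over a 1000-point mRNA grid.
- Integration: LSODA, rtol 1e-8, atol 1e-9 nM, outputs on a fixed 180 s grid
  mirroring plate-reader sampling. States are clipped at zero at output
  (integrator noise is below atol). Conservation residuals are ≤ 1e-6 nM at
  every output time.
- "Maximum synthesis rate" is operationalized as the maximum sliding-window
  (default 30 min) least-squares slope of the mature reporter after a 30 min
  burn-in. For noisy traces the window should be widened (the max over many
  short windows is upward-biased under per-point noise; a 90 min window
  keeps the extraction within 10% at 5% multiplicative noise).
- Fits and limiting-DNA searches evaluate the closed-form regime-II
  steady-state rate (exact Michaelis–Menten mRNA balance, then the ribosome
  quadratic) instead of re-integrating the ODEs inside optimization loops; a
  test pins it to the simulated sliding-window slope within 5%.
- Joint (kcat_m, kcat_p) fits run as bounded least squares in log10 space
  (bounds 1e-6–0.5 1/s) with three seeded multi-starts spread half a decade
  around the initial guess. When a measured curve never leaves the linear
  regime only the kcat product is identifiable; the fit reports this in a
  note rather than pretending otherwise.
- Regime labelling: a grid point is "linear" when its rate/plasmid ratio is
  within 10% of the lowest-concentration ratio. The transition is sharp, so
  the labelling is insensitive to the exact threshold.

## Load calculator

The limiting DNA concentration is defined as the plasmid concentration at
which the model's steady-state rate falls 10% below the linear
extrapolation from low concentration (the published description is
qualitative; 10% is this package's convention). `derive_power_law` sweeps
promoter strength (scaling kcat_m), UTR strength (scaling kcat_p) and gene
length one at a time, locates the limiting concentration per point by
bracketed root finding, fits log–log lines and normalizes the prefactor so
the reference construct (P = U = 1, Lm = 800 nt) maps onto the base model's
own limiting concentration. Default sweep ranges — strengths 0.1–1, lengths
200–2000 nt — reflect the part sets (which run downward from the reference
strength) and typical single-gene lengths. The exponents are range-dependent
because the underlying relation is not an exact power law (the occupancy
factor 1 + kcat_p·Lm/Cp interpolates between constant and linear); the
promoter exponent is robustly ≈ −1 because transcription output is
proportional to kcat_m throughout. Budgeting across constructs is linear
bookkeeping (fractions of translation capacity) and deliberately ignores
any regulatory interaction between constructs; loads above 100% warn rather
than error, since the calculator is an approximation tool.

## Synthetic data

The generator emulates the measurement process the model is fitted to:
calibrated fluorescence kinetics sampled every 180 s for 16 h, first-order
decay/maturation assays, and rate-vs-plasmid datasets for a 3×3
promoter×UTR strength grid spanning two orders of magnitude (defaults 1,
0.1, 0.01 per set). Noise is multiplicative-plus-additive Gaussian
truncated at zero — defaults 3% + 5 nM for fluorescence kinetics, 5% + 0
for derived rate curves (an additive floor in nM/s has no instrument
counterpart) — with mandatory seeds. What it does not emulate: the
late-time plateau (traces are simply truncated), instrument gain drift or
crosstalk, correlated noise between wells, and the sigmoidal low-plasmid
response seen for one natural promoter. Passing round-trip tests therefore
demonstrates internal consistency of model + fitting under idealized iid
noise, not performance on real plate-reader quirks.

## Known limitations

- The model excludes the plateau phase; simulated 16 h traces keep
  accumulating protein where real reactions level off after ~6 h. Rate
  extraction windows are restricted to the steady-state phase for this
  reason.
- k_mat ships as a placeholder; analyses that depend on the dark/mature
  split (not on their sum) should fit it from a maturation assay first.
- Individual kcat values from linear-only rate curves are not identifiable
  (only the product); the fitting API surfaces this but cannot fix it.
- The power-law exponents for UTR strength and gene length depend on the
  sweep range; the published values are recovered only with comparable
  ranges.
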