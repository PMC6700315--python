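# txtlkit

Quantitative modeling of gene expression in an all-*E. coli* cell-free
transcription–translation (TXTL) system.

## Who this is for

Cell-free expression is widely used to prototype genetic parts and circuits:
a plasmid carrying a reporter gene is added to an *E. coli* lysate and the
fluorescent protein it encodes is tracked on a plate reader. Practitioners
face a recurring quantitative question: the maximum protein synthesis rate
grows linearly with plasmid concentration only up to a point (~5 nM for the
strongest promoter/UTR pair), then saturates sharply because the finite
ribosome pool is entirely recruited onto the mRNA. `txtlkit` implements a
compact ODE model of this behavior, the fitting machinery that constrains
its constants from plate-reader assays, sensitivity scans, and a "load
calculator" that predicts, for any construct, the DNA concentration above
which translation resources become limiting.

## The model

Three ODEs (concentrations in nM, time in s) describe the mRNA *m*, the
immature (dark) reporter and the mature fluorescent reporter:

```
dm/dt     = kcat_m [P70] [E0][S70] / (KM_70 (K70 + [E0]) + [E0][S70])  −  kd_m [m]/(KM_m + [m])
d[dark]/dt = kcat_p [m] [R0]/(KM_R + [R0])  −  k_mat [dark]
d[mat]/dt  = k_mat [dark]
```

coupled to two conservation laws for the machinery pools, solved at every
instant for the free core RNA polymerase E0 and free ribosomes R0:

```
E_tot = E0 + E0 S70/(K70 + E0) + E0 S70 P70/(KM_70 (K70+E0) + E0 S70) · (1 + kcat_m Lm/Cm)
R_tot = R0 + R0 m/(KM_R + R0) · (1 + kcat_p Lm/Cp)
```

The polymerase balance depends only on the plasmid concentration and is
solved once per run by bracketed root finding; the ribosome balance is a
quadratic in R0 solved in closed form inside every ODE right-hand-side
evaluation. Useful steady-state consequences: `m_ss = k_TX/k_deg,m · [P70]`
and, in the linear regime, a mature-reporter accumulation rate
`kcat_p·kcat_m/k_deg,m · [P70]` (0.47 nM/s per nM plasmid at the best-fit
constants). The bundled best-fit constants (`txtlkit.best_fit_parameters()`)
are: kcat_m = 6.5e-2 1/s, KM_70 = 1 nM, K70 = 0.26 nM, S70 = 30 nM,
E_tot = 400 nM, kd_m = 6.6 nM/s, KM_m = 8000 nM (so k_deg,m = 8.25e-4 1/s),
kcat_p = 6e-3 1/s, KM_R = 10 nM, R_tot = 1100 nM, Cm = 10 nt/s,
Cp = 2.5 nt/s, Lm = 750 nt.

The load calculator condenses the model into a power law for the limiting
DNA concentration of a construct with relative promoter strength P, relative
UTR strength U and gene length Lm (nt):

```
[DNA]_lim = 250 · P^−0.987 · U^−0.352 · Lm^−0.583   (nM)
```

`derive_power_law` re-derives prefactor and exponents from the model itself.

## Worked example

```python
import txtlkit as tk

params = tk.best_fit_parameters().replace(P70=1.0)   # 1 nM plasmid
trace = tk.simulate_kinetics(params, t_end=4 * 3600.0)
print(tk.max_synthesis_rate(trace))                  # 0.457 nM/s
print(tk.linear_regime_protein_rate(params))         # 0.473 nM/s (analytic)
print(tk.limiting_dna(tk.ConstructSpec(P=1, U=1, Lm=800)))  # 5.08 nM
```

Running `python examples/01_simulate_kinetics.py` prints:

```
free core RNA polymerase E0 = 364.3 nM (of 400 total)
steady-state mRNA           = 77.0 nM
mature deGFP after 4 h      = 5635 nM
max synthesis rate          = 0.457 nM/s (simulated)
linear-regime prediction    = 0.473 nM/s (analytic)
deviation                   = 3.4%
```

i.e. at 1 nM plasmid the reaction sits deep in the linear regime: mRNA
settles near 77 nM, the mature reporter accumulates at ~0.46 nM/s, and the
simulated slope sits a few percent under the reservoir-approximation value
because some ribosomes are already sequestered. The other scripts in
`examples/` walk through rate curves and resource depletion, constant
fitting, sensitivity scans, the load calculator and synthetic-data
generation; a thin CLI (`txtl simulate|fit|sensitivity|load-calc|synth`)
exposes the same operations from the shell.

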