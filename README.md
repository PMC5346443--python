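# nldfs — nonlinear dynamic force spectroscopy

Dynamic force spectroscopy (DFS) measures the rupture forces of single
receptor–ligand bonds under a time-increasing load and infers two kinetic
parameters: the **bond length** `x_b` (distance from the bound-state energy
minimum to the transition barrier, nm) and the **thermal off-rate**
`k_off^th` (spontaneous dissociation rate at zero force, 1/s). The classic
analysis requires a force that grows linearly in time. Real pulling
geometries often violate that: bonds anchored through worm-like-chain (WLC)
polymers, bacterial adhesion pili, membranes, or any compliant linker see a
*nonlinear* force ramp even when the transducer moves at constant velocity.

`nldfs` implements the theory and measurement protocol for that nonlinear
regime, for experimentalists and modelers working with AFM or
optical-tweezers pulling data.

## Model

Bond dissociation follows single-barrier Bell kinetics,

    k_off(F) = k_off^th · exp(F·x_b / k_B T),

so that under a monotone loading protocol `F(t)` with loading rate
`r(t) = dF/dt > 0` the survival probability is
`P(t) = exp(−∫₀ᵗ k_off(F(t′)) dt′)` and the rupture-force density is
`p(F) = k_off(F)·P(t(F))/r(t(F))`. The mode of that density — the *peak
force* `F*` read off a rupture spectrum — satisfies, for constant `r`,

    F* = (k_B T/x_b) · ln[ r·x_b / (k_off^th·k_B T) ],

and for an arbitrary increasing protocol the implicit condition

    F(t*) = (k_B T/x_b) · ln[ ( r(t*)·x_b/k_B T − d ln r/dt |_{t*} ) / k_off^th ],

which collapses onto the linear formula when `d ln r/dt = 0`. Measuring
`F*` at several pulling velocities and fitting this relation (least squares
in the peak forces, Nelder–Mead) recovers `(x_b, k_off^th)`.

The package provides:

* analytic survival, hazard and rupture-density machinery (`nldfs.kinetics`);
* loading protocols — constant rate, power-law distance response, WLC
  (force `F = (k_B T/l_p)[¼(1−L/L_c)⁻² − ¼ + L/L_c]`, `L = v·t`), and
  monotone interpolants of measured force–distance curves
  (`nldfs.protocols`);
* peak-force solvers: closed form, implicit condition, and an independent
  density-maximization cross-check (`nldfs.peaks`);
* exact inverse-hazard Monte Carlo rupture sampling (`nldfs.montecarlo`);
* Gaussian-kernel rupture spectra and peak identification
  (`nldfs.spectrum`);
* the velocity→peak-force estimation protocol and a Monte Carlo study of
  estimation error versus sample size (`nldfs.estimators`);
* plain-text I/O, YAML configuration, synthetic fixture generation and a
  CLI (`nldfs.io`, `nldfs.cli`).

## Worked example

Predict peak forces for a reference bond (`x_b = 0.70 nm`,
`k_off^th = 1e-4 /s`, `k_B T = 4.11 pN·nm`) under three loading modes
(`python examples/peak_force_prediction.py`):

```
constant rate 100 pN/s : F* = 70.7 pN (closed form)
quadratic response     : F* = 52.3 pN at t* = 22.9 s
WLC tether             : F* = 41.55 pN (density maximum 41.55 pN)
```

Each number is the mode of the rupture-force distribution the corresponding
experiment would record; the two solution paths for the WLC case (implicit
condition vs direct density maximization) agree to well below experimental
force resolution. Simulating the WLC experiment and reading the spectrum
back (`python examples/simulate_and_spectrum.py`):

```
simulated 100000 ruptures; 18.0% below 20 pN (low-force shoulder)
spectrum peak (kernel 0.5 pN): 42.07 pN
theory prediction            : 41.55 pN
```

The slow-WLC spectrum is bimodal — a minority of bonds dissociate during
the soft entropic phase (the shoulder below 20 pN) and the rest at the
steep terminal rise — and the kernel-density peak lands within sampling
noise of the theoretical prediction. `examples/fit_bond_parameters.py` and
`examples/error_vs_sample_size.py` run the full measurement protocol:
simulate 50 ruptures per velocity, locate the spectrum peaks, fit
`(x_b, k_off^th)`, and quantify how the errors shrink with sample size.

A CLI mirrors the library for shell use:

```sh
nldfs peak                  # peak force for the configured protocol
nldfs simulate -n 200 --seed 3 --out forces.txt
nldfs spectrum forces.txt --sigma 3
nldfs fit velocity_peaks.txt
nldfs errorstudy --iterations 100
nldfs fixtures --seed 1 --out fixtures/
```

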