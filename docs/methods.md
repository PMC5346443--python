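# Methods

## Model and assumptions

A single noncovalent receptor–ligand bond is modeled as a one-dimensional
escape over a single energy barrier with force-dependent rate
`k_off(F) = k_off^th · exp(F·x_b/k_B T)` (Bell kinetics). The two bond
parameters are the bond length `x_b` (nm) and the thermal off-rate
`k_off^th` (1/s); the attempt rate and barrier height behind `k_off^th`
are never needed separately and are not modeled. Assumptions inherited
from this model: no rebinding, a single barrier, force-independent `x_b`,
no catch-bond behavior.

The external load is any *monotone* protocol `F(t)` with strictly positive
loading rate `r(t) = dF/dt` on its domain, so force and time are in
one-to-one correspondence. The probe (cantilever or trapped bead) is
treated as infinitely stiff and viscous drag on it is neglected: only the
force actually felt by the bond matters, whatever combination of linker
and probe produced it. Rupture is then an inhomogeneous Poisson first
event: survival `P(t) = exp(−H(t))` with cumulative hazard
`H(t) = ∫₀ᵗ k_off(F(t′))dt′`, rupture-force density
`p(F) = k_off(F)·P(t(F))/r(t(F))`.

Stationarity of the rupture rate gives the peak-force (distribution mode)
condition

    F(t*) = (k_B T/x_b) · ln[ (r(t*)·x_b/k_B T − d ln r/dt|_{t*}) / k_off^th ],

reducing exactly to the constant-rate closed form when `d ln r/dt = 0`.

## Units

Internal canonical units are pN, nm, s (`x_b·F/k_B T` dimensionless with
`k_B T` in pN·nm; default 4.11 pN·nm ≈ 298 K). Transducer distances,
contour lengths and velocities enter interfaces in µm and µm/s and are
converted on ingest. Power-law coefficients are quoted against distance
(pN/µmⁿ), the form in which elastic responses are measured.

## Protocols

* **Constant rate** — `F = r·t`; the linear-DFS limit.
* **Power law** — `F = a_n (v·t)ⁿ`; `n = 1` is linear loading with
  `r = a_1 v`, `n = 2` a reversible elastic polymer. `d ln r/dt = (n−1)/t`
  diverges at `t = 0` for `n ≥ 2`; the peak solver treats that point as
  inadmissible.
* **Worm-like chain (inelastic)** — interpolation formula
  `F = (k_B T/l_p)[¼(1−L/L_c)⁻² − ¼ + L/L_c]`, `L = v·t`, with domain end
  `t_max = L_c/v` where the force diverges. No stretch-modulus
  (extensible-WLC) term. Computations are confined to
  `t ≤ t_max(1 − 1e-9)`; for any realistic parameters survival is
  numerically zero far earlier, so the truncation is harmless.
* **Tabulated** — a measured force–distance curve, interpolated with a
  monotone piecewise cubic (PCHIP) whose analytic derivative supplies
  `r = (dF/dL)·v`; an optional odd-width moving-average pre-smoother
  handles instrument noise (no principled width exists for unknown noise —
  it is an engineering control, disabled by default). Non-monotone curves
  are rejected with the offending distance interval named.

## Reference scenario

All examples, tests and the acceptance script use one study scenario: bond
`x_b = 0.70 nm`, `k_off^th = 1e-4 /s` (typical of noncovalent adhesion
bonds), WLC tether `l_p = 3 nm`, `L_c = 10 µm`, pulling velocities
`{0.01, 0.1, 1, 10} µm/s`. These velocities give `v/L_c` sweeping
`1e-3…1 s⁻¹` and analytic peak forces 41.55, 58.61, 74.49, 89.81 pN — a
span that exercises both the bimodal slow-pulling regime and the
quasi-linear fast regime. The non-WLC reference cases are constant loading
at 100 pN/s (`F* = 70.7 pN`) and the quadratic response
`a_2 = 1e-3 pN/µm²` at 10 µm/s (`F* = 52.3 pN`).

## Numerics

* **Hazard evaluation.** Per (bond, protocol) pair a cumulative-hazard
  grid is precomputed: 4096 intervals uniform in *force* from `F(0)` up to
  the smaller of the exponent-cap force `700·k_B T/x_b` and the guarded
  domain end, mapped to times through the protocol inverse, each interval
  integrated with 5-point Gauss–Legendre. Uniform force spacing bounds the
  Boltzmann-exponent variation per interval (≤ 0.2), so the quadrature is
  accurate to ~1e-12 relative (verified against the constant-rate closed
  form at ~1e-15 and an independent 2×10⁶-point trapezoid for the WLC).
  Arbitrary times use one extra partial-interval quadrature. The hazard is
  clamped at 745 — `exp(−745)` is the smallest positive float64 — beyond
  which survival is physically indistinguishable from zero.
* **Peak solving.** The implicit condition is solved by a coarse scan
  (default 512 nodes, log-spaced from both ends of a finite domain or up
  to the exponent-cap time of an unbounded one) for sign changes of
  `g(t) = F(t) − RHS(t)`, each bracket refined by Brent's method
  (residual < 1e-9 pN). With several stationary points (bimodal spectra)
  the root with the largest analytic density is reported and all roots are
  listed in diagnostics; the density comparison uses direct adaptive
  quadrature of the hazard, cheap for a handful of candidates.
  A non-positive log argument everywhere, or no sign change, raises a
  distinct "no interior peak" error; the constant-rate `r·x_b ≤
  k_off^th·k_B T` regime ("mode at zero force") is likewise reported as a
  physical regime, never clamped.
* **Density-oracle cross-check.** An independent path maximizes `p(F)` on
  a dense grid with bounded local refinement. It returns the largest
  *interior* mode: under very slow loading the density can be monotone
  into `F = 0` with a boundary value above the interior peak, but that
  boundary mass is not a spectrum peak — kernel estimates of measured
  data suppress it and the implicit condition has no stationary point
  there. The two paths agree to < 0.05 pN across the reference protocols
  and randomized parameters.
* **Monte Carlo sampling.** Rupture times are drawn by exact inverse
  transform on the hazard grid: `u ~ U(0,1)`, solve `H(t) = −ln u` by
  monotone bracketing plus safeguarded Newton polish (~1e-12 relative in
  t). No time-discretization error; agreement with a small-step Bernoulli
  chain (the definitional scheme, kept as a test oracle) is verified by
  KS tests at α = 0.01. Draws are reproducible from explicit integer
  seeds; study replicates spawn independent streams from a master seed
  via `numpy.random.SeedSequence`.
* **Spectra.** Fixed-width Gaussian KDE evaluated exactly on a uniform
  grid (default 0 to max(sample)+5σ, 2048 points), peak refined by
  quadratic interpolation through the three bracketing points; all local
  maxima above 10% of the global are reported. No boundary correction at
  `F = 0`: the resulting low-force artifact is part of the measurement
  model the fit sees, deliberately. Automatic bandwidth selection is not
  a default anywhere; reference analyses use σ = 0.5 pN (validation
  spectra) and σ = 3 pN (measurement protocol).
* **Fitting.** `(x_b, log10 k_off^th)` by Nelder–Mead on the mean squared
  peak-force error; the log coordinate matters because the off-rate spans
  decades and is only logarithmically identified. Initialization: `x_b⁰`
  from the slope of `F*` vs `ln v` between the extreme velocities (the
  linear-DFS relation), `k_off⁰` by inverting the closed form at the
  slowest velocity with the local loading rate at its measured peak;
  generic fallbacks when the data are non-monotone. Failures return the
  best point flagged, never silently.

## Error study

The study repeats the full pipeline — draw N ruptures per velocity, KDE
(σ = 3 pN), peak identification, fit — for many replicates and reports
the mean and quartiles of the relative errors `|estimate − truth|/truth`
(absolute value, which is what makes positive mean bars with quartile
whiskers coherent), plus quartiles of the recovered parameter values
themselves, plus per-velocity peak-force errors. Reference configuration:
500 replicates at N ∈ {50, 70, 100, 300} (larger replicate counts are a
parameter away); independent datasets are drawn for every (N, replicate)
cell. Fit failures are counted and excluded, never silently dropped.

Expected behavior at the reference conditions: errors fall monotonically
with N and with velocity; the bond-length error (a few percent) is far
below the off-rate error (tens of percent), because the peak force is
linearly sensitive to `x_b` but only logarithmically to `k_off^th`; at
N = 300 the bond length is recovered to ~2%. At N = 50 the off-rate error
distribution is heavy-tailed (median ≈ 44%, mean 70–85% across seeds):
occasional noisy peak sets are nearly degenerate and the weakly
identified off-rate wanders, inflating the mean. Larger kernel widths
would trade that variance for bias; σ is kept at the fixed reference
value rather than adapted to N.

## What the synthetic data does and does not emulate

The generator draws from the exact model the estimator assumes: Bell
kinetics, perfectly known protocol, no instrument noise, no drift, no
multiple tethers, no probe compliance. Passing tests therefore
demonstrate the *internal* consistency and statistical behavior of the
method — identifiability, convergence rates, sampler exactness — not
robustness to the additional noise of a real AFM/OT experiment. Error
magnitudes from the study are best-case floors for practice.

## Known limitations

* Single-barrier Bell kinetics only: no catch bonds, rebinding, or
  multi-barrier landscapes.
* Protocols must be strictly monotone in force; unwinding plateaus
  (constant-force regimes of some pili) are out of scope.
* The tabulated-protocol smoother is a plain moving average; heavily
  oversampled or strongly autocorrelated instrument noise may need
  external pre-processing.
* Only the iterate-and-aggregate uncertainty scheme is provided; no
  profile-likelihood or bootstrap confidence intervals.
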