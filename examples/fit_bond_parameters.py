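"""Recover bond length and thermal off-rate from peak-force data.

The measurement protocol for nonlinear loading: at each pulling velocity
collect rupture forces, read the peak force off the kernel-density
spectrum, and fit the implicit peak-force relation to the (velocity,
peak) pairs.  This script simulates 50 measurements per velocity -- a
realistic experimental session -- and fits; with finitely many noisy
ruptures the bond length is the better-identified of the two (typically
within a few percent, though single sessions can be off by ~10%), while
the off-rate, which the peak force is only logarithmically sensitive
to, carries tens of percent of uncertainty.
"""

import numpy as np

from nldfs import (
    BondParameters,
    VelocityPeakPair,
    WLCFamily,
    find_peak,
    fit_parameters,
    kde_spectrum,
    sample_rupture_forces,
)

truth = BondParameters(xb=0.70, koff_th=1e-4)
family = WLCFamily(lp=3.0, Lc=10.0)
velocities = [0.01, 0.1, 1.0, 10.0]

pairs = []
for i, v in enumerate(velocities):
    data = sample_rupture_forces(truth, family.protocol(v), n=50, seed=100 + i)
    peak = find_peak(kde_spectrum(data, sigma=3.0))
    pairs.append(VelocityPeakPair(v=v, f_star=peak.force, n=50))
    print(f"v = {v:6g} um/s : peak force {peak.force:6.2f} pN  (n = 50)")

fit = fit_parameters(pairs, family)
print(f"\nfitted bond length   : {fit.xb_hat:.3f} nm   (truth 0.700)")
print(f"fitted thermal off-rate: {fit.koff_hat:.3g} /s  (truth 1e-4)")
print(f"mean squared peak-force error: {fit.objective:.3f} pN^2")
print("The bond length is the better-identified parameter; the off-rate")
print("is weakly identified and may differ by tens of percent at n = 50.")
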