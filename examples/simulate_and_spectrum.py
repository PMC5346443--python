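"""Simulate a rupture-force experiment and build its spectrum.

Draws 100,000 rupture forces for a bond pulled through a worm-like-chain
tether (exact inverse-hazard sampling of the Bell-kinetics survival law)
and estimates the continuous rupture spectrum with a Gaussian kernel.
The spectrum of a slowly pulled WLC is bimodal: a small low-force
shoulder from bonds that dissociate during the soft entropic phase, and
the dominant peak set by the steep terminal loading.
"""

import numpy as np

from nldfs import (
    BondParameters,
    WLCProtocol,
    find_peak,
    kde_spectrum,
    peak_force_nonlinear,
    sample_rupture_forces,
)

bond = BondParameters(xb=0.70, koff_th=1e-4)
wlc = WLCProtocol(lp=3.0, Lc=10.0, v=0.01)

data = sample_rupture_forces(bond, wlc, n=100_000, seed=20)
print(f"simulated {data.n} ruptures; "
      f"{np.mean(data.forces < 20):.1%} below 20 pN (low-force shoulder)")

spec = kde_spectrum(data, sigma=0.5)
peak = find_peak(spec)
predicted = peak_force_nonlinear(bond, wlc).force
print(f"spectrum peak (kernel 0.5 pN): {peak.force:.2f} pN")
print(f"theory prediction            : {predicted:.2f} pN")
print("local maxima above 10% of the peak:",
      ", ".join(f"{f:.1f} pN" for f, _ in peak.local_maxima))
print("The spectrum peak should fall within sampling noise of the theory value.")
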