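"""Shared fixtures: reference bond, protocols, and the slow Monte Carlo
rupture oracle used to validate the fast inverse-hazard sampler."""

import numpy as np
import pytest

from nldfs import (
    BondParameters,
    ConstantRateProtocol,
    PowerLawProtocol,
    WLCFamily,
    WLCProtocol,
)
from nldfs.kinetics import _off_rate_clipped

#: Velocities (um/s) of the reference worm-like-chain scenario; their
#: analytic peak forces span ~41.6 to ~89.8 pN.
REFERENCE_VELOCITIES = (0.01, 0.1, 1.0, 10.0)


@pytest.fixture(scope="session")
def bond():
    """Reference noncovalent adhesion bond: xb = 0.70 nm, koff = 1e-4/s."""
    return BondParameters(xb=0.70, koff_th=1e-4, kbt=4.11)


@pytest.fixture(scope="session")
def linear_protocol():
    """Constant loading at 100 pN/s (classic linear DFS)."""
    return ConstantRateProtocol(rate=100.0)


@pytest.fixture(scope="session")
def quadratic_protocol():
    """Elastic-polymer response F = a2 L^2, a2 = 1e-3 pN/um^2, v = 10 um/s."""
    return PowerLawProtocol(coefficient=1e-3, exponent=2, v=10.0)


@pytest.fixture(scope="session")
def wlc_protocol():
    """WLC tether, lp = 3 nm, Lc = 10 um, slowest reference velocity."""
    return WLCProtocol(lp=3.0, Lc=10.0, v=REFERENCE_VELOCITIES[0])


@pytest.fixture(scope="session")
def wlc_family():
    return WLCFamily(lp=3.0, Lc=10.0)


def bernoulli_chain_rupture_forces(params, protocol, n, rng, max_step_hazard=1e-3):
    """Slow discrete-time rupture oracle, independent of inverse-hazard code.

    Discretizes the loading into small steps with per-step rupture
    probability p_j = k_off(F(t_j)) * dt_j, each kept below
    ``max_step_hazard``, and samples the rupture step from the exact
    distribution of that Bernoulli chain (survival ladder prod(1-p_j),
    inverted by searchsorted).  This is the textbook definition of
    Bell-kinetics rupture as dt -> 0; the fast sampler must agree with it
    in distribution.
    """
    # force-uniform backbone resolves the terminal steep region
    f0 = float(protocol.force(0.0))
    f_cap = 700.0 * params.kbt / params.xb
    if np.isfinite(protocol.t_max):
        f_hi = min(f_cap, float(protocol.force(protocol.t_guard)))
    else:
        f_hi = f_cap
    F_nodes = np.linspace(f0, f_hi, 2049)
    t_nodes = np.asarray(protocol.time_at_force(F_nodes), dtype=float)
    t_nodes[0] = 0.0
    # subdivide so that koff * dt stays below max_step_hazard
    k_right = _off_rate_clipped(params, F_nodes[1:])
    dt = np.diff(t_nodes)
    n_sub = np.minimum(np.ceil(k_right * dt / max_step_hazard), 4000).astype(int) + 1
    edges = [np.linspace(t_nodes[i], t_nodes[i + 1], n_sub[i] + 1)[:-1]
             for i in range(len(dt))]
    t = np.concatenate(edges + [t_nodes[-1:]])
    steps = np.diff(t)
    p = _off_rate_clipped(params, np.asarray(protocol.force(t[:-1]))) * steps
    p = np.clip(p, 0.0, 1.0)
    log_surv = np.cumsum(np.log1p(-np.minimum(p, 1 - 1e-15)))
    cdf = 1.0 - np.exp(log_surv)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    idx = np.minimum(idx, len(steps) - 1)
    # rupture happens during step idx; report its midpoint time
    t_rup = t[idx] + 0.5 * steps[idx]
    return np.asarray(protocol.force(t_rup))
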