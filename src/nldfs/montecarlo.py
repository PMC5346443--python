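"""Monte Carlo generation of rupture forces.

Rupture of a Bell bond under a monotone loading protocol is an
inhomogeneous Poisson first-event process with hazard k_off(F(t)).
Sampling is by exact inverse-transform on the cumulative hazard:
draw u ~ U(0,1) and solve H(t) = -ln u, which reproduces the survival
function exp(-H(t)) without any time-discretization error.  The
equivalent (but much slower) definition -- small-step Bernoulli rupture
trials with per-step probability k_off*dt -- serves as the independent
correctness oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import BondParameters, RuptureModel, get_model
from .protocols import LoadingProtocol

__all__ = ["RuptureDataset", "sample_rupture_times", "sample_rupture_forces"]


@dataclass(frozen=True)
class RuptureDataset:
    """A set of measured or simulated rupture forces.

    ``forces`` in pN; ``velocity`` (um/s) identifies the pulling speed
    the set was recorded at, which is the controlled variable of the
    nonlinear measurement protocol.  For synthetic data, ``params``,
    ``protocol`` and ``seed`` record how the draws were generated.
    """

    forces: np.ndarray
    velocity: float | None = None
    protocol: dict | None = None
    params: BondParameters | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.forces, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("forces must be a non-empty 1-d array")
        if np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ValueError("rupture forces must be finite and non-negative")
        object.__setattr__(self, "forces", f)

    @property
    def n(self) -> int:
        return int(self.forces.size)


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed (or Generator) is required "
                         "for reproducible sampling")
    return np.random.default_rng(seed)


def sample_rupture_times(
    params: BondParameters,
    protocol: LoadingProtocol,
    n: int,
    seed,
    model: RuptureModel | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. rupture times (s) by inverse-hazard sampling.

    ``seed`` may be an int or a ``numpy.random.Generator``; equal seeds
    give identical arrays.  A prebuilt :class:`RuptureModel` can be
    passed to amortize the hazard grid across many calls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _resolve_rng(seed)
    if model is None:
        model = get_model(params, protocol)
    return model.sample_times(n, rng)


def sample_rupture_forces(
    params: BondParameters,
    protocol: LoadingProtocol,
    n: int,
    seed,
    model: RuptureModel | None = None,
) -> RuptureDataset:
    """Draw ``n`` rupture forces (pN) and wrap them with their provenance."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _resolve_rng(seed)
    if model is None:
        model = get_model(params, protocol)
    forces = np.asarray(protocol.force(model.sample_times(n, rng)))
    return RuptureDataset(
        forces=forces,
        velocity=protocol.v,
        protocol=protocol.describe(),
        params=params,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
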