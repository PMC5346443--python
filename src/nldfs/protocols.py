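"""Monotone loading protocols F(t) for force spectroscopy.

A loading protocol describes the external force applied to a single
receptor--ligand bond as a function of time.  All protocols here are
restricted to continuously increasing forces with strictly positive
loading rate r(t) = dF/dt, so that every force value occurs exactly once
and the rupture-time and rupture-force descriptions are interchangeable.

Units follow the conventions of single-molecule force spectroscopy:
forces in pN, times in s, molecular lengths (persistence length, bond
length) in nm, transducer distances and velocities in um and um/s.
Mixing nm and um is the classic source of silent 1e3 errors in the
Boltzmann exponent, so every interface documents its unit and converts
on ingest; internally a protocol only ever produces (pN, s) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_KBT",
    "LoadingProtocol",
    "ConstantRateProtocol",
    "PowerLawProtocol",
    "WLCProtocol",
    "TabulatedProtocol",
    "wlc_force",
    "wlc_loading_rate",
    "tabulated_from_samples",
]

#: Thermal energy k_B*T at ~298 K in pN nm.
DEFAULT_KBT = 4.11

#: Relative distance kept from a finite domain end where the force diverges.
DOMAIN_EPS = 1e-9


class ProtocolDomainError(ValueError):
    """Raised when a time or force lies outside a protocol's domain."""


class LoadingProtocol:
    """Base class for monotone loading protocols.

    Subclasses provide ``force``, ``loading_rate``, ``dlnr_dt`` and
    ``time_at_force`` on the half-open time domain [0, t_max).  ``t_max``
    is ``np.inf`` for protocols that grow without bound in time.
    """

    #: End of the time domain in s (np.inf if unbounded).
    t_max: float = np.inf
    #: Pulling velocity in um/s where the protocol derives from a distance
    #: sweep L = v*t; None for protocols specified directly in time.
    v: float | None = None

    @property
    def t_guard(self) -> float:
        """Largest usable time: t_max*(1 - eps) for finite domains.

        Near a finite domain end (e.g. the WLC contour length) the force
        diverges; survival is numerically zero long before, so confining
        evaluation to the guard point loses nothing.
        """
        if np.isinf(self.t_max):
            return np.inf
        return self.t_max * (1.0 - DOMAIN_EPS)

    def _check_time(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t >= self.t_max):
            raise ProtocolDomainError(
                f"time outside protocol domain [0, {self.t_max!r}) s"
            )
        return t

    def force(self, t):
        """Force F(t) in pN."""
        raise NotImplementedError

    def loading_rate(self, t):
        """Loading rate r(t) = dF/dt in pN/s."""
        raise NotImplementedError

    def dlnr_dt(self, t):
        """Logarithmic rate derivative d ln r / dt in 1/s."""
        raise NotImplementedError

    def time_at_force(self, F):
        """Inverse of ``force``: the unique t with F(t) = F.

        Generic implementation by bracketed root finding on the strictly
        increasing force; subclasses override with closed forms.
        """
        F = np.asarray(F, dtype=float)
        f0 = float(self.force(0.0))
        hi = self.t_guard if np.isfinite(self.t_max) else None

        def _solve(fv: float) -> float:
            if fv < f0:
                raise ProtocolDomainError(f"force {fv} pN below F(0) = {f0} pN")
            if fv == f0:
                return 0.0
            if hi is None:
                b = 1.0
                while self.force(b) < fv:
                    b *= 4.0
                    if b > 1e18:
                        raise ProtocolDomainError(f"force {fv} pN unreachable")
                a = 0.0
            else:
                if self.force(hi) < fv:
                    raise ProtocolDomainError(
                        f"force {fv} pN not attained before domain end"
                    )
                a, b = 0.0, hi
            return brentq(lambda t: self.force(t) - fv, a, b,
                          xtol=1e-300, rtol=1e-15)

        if F.ndim == 0:
            return _solve(float(F))
        return np.array([_solve(fv) for fv in F.ravel()]).reshape(F.shape)

    def describe(self) -> dict:
        """Short serializable description used in file metadata."""
        return {"type": type(self).__name__}


@dataclass(frozen=True)
class ConstantRateProtocol(LoadingProtocol):
    """Linear loading F = r*t at constant loading rate r (pN/s).

    The classic dynamic-force-spectroscopy protocol; the nonlinear theory
    must reduce to it exactly since d ln r/dt = 0.
    """

    rate: float
    v: float | None = None
    t_max: float = field(default=np.inf, init=False)

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("loading rate must be positive")

    def force(self, t):
        out = self.rate * self._check_time(t)
        return out if out.ndim else float(out)

    def loading_rate(self, t):
        out = self.rate * np.ones_like(self._check_time(t))
        return out if out.ndim else float(out)

    def dlnr_dt(self, t):
        out = np.zeros_like(self._check_time(t))
        return out if out.ndim else float(out)

    def time_at_force(self, F):
        F = np.asarray(F, dtype=float)
        if np.any(F < 0):
            raise ProtocolDomainError("negative force")
        return F / self.rate

    def describe(self):
        return {"type": "linear", "rate_pN_per_s": self.rate, "v_um_per_s": self.v}


@dataclass(frozen=True)
class PowerLawProtocol(LoadingProtocol):
    """Power-law distance response F = a_n * (v*t)**n.

    ``coefficient`` a_n is in pN/um**n, matching how elastic responses are
    quoted against transducer distance; the time-domain form follows from
    L = v*t.  n = 1 recovers linear loading with r = a_1*v; n = 2 is the
    quadratic response of a reversible elastic polymer.
    """

    coefficient: float
    exponent: int
    v: float
    t_max: float = field(default=np.inf, init=False)

    def __post_init__(self):
        if self.coefficient <= 0 or self.v <= 0:
            raise ValueError("coefficient and velocity must be positive")
        if int(self.exponent) != self.exponent or self.exponent < 1:
            raise ValueError("exponent must be an integer >= 1")

    def force(self, t):
        t = self._check_time(t)
        out = self.coefficient * (self.v * t) ** self.exponent
        return out if out.ndim else float(out)

    def loading_rate(self, t):
        t = self._check_time(t)
        n = self.exponent
        out = n * self.coefficient * self.v**n * t ** (n - 1)
        return out if out.ndim else float(out)

    def dlnr_dt(self, t):
        # r ~ t**(n-1)  =>  d ln r/dt = (n-1)/t; +inf at t=0 for n >= 2
        # (the peak solver treats the infinity as "log argument non-positive").
        t = self._check_time(t)
        n = self.exponent
        if n == 1:
            out = np.zeros_like(t)
        else:
            with np.errstate(divide="ignore"):
                out = np.where(t > 0, (n - 1) / np.where(t > 0, t, 1.0), np.inf)
        return out if out.ndim else float(out)

    def time_at_force(self, F):
        F = np.asarray(F, dtype=float)
        if np.any(F < 0):
            raise ProtocolDomainError("negative force")
        return (F / self.coefficient) ** (1.0 / self.exponent) / self.v

    def describe(self):
        return {
            "type": "power_law",
            "coefficient_pN_per_um_n": self.coefficient,
            "exponent": self.exponent,
            "v_um_per_s": self.v,
        }


def wlc_force(lp: float, Lc: float, L, kbt: float = DEFAULT_KBT):
    """Worm-like-chain interpolation force--extension law (inelastic).

    F(L) = (kbt/lp) * [ 1/4 (1 - L/Lc)^-2 - 1/4 + L/Lc ]

    Parameters
    ----------
    lp : persistence length, nm.
    Lc : contour length, um.
    L : end-to-end distance, um (0 <= L < Lc).
    kbt : thermal energy, pN nm.

    Returns the entropic restoring force in pN; diverges as L -> Lc.
    """
    if lp <= 0 or Lc <= 0:
        raise ValueError("persistence and contour lengths must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0) or np.any(L >= Lc):
        raise ProtocolDomainError(f"extension outside [0, Lc={Lc} um)")
    x = L / Lc
    out = (kbt / lp) * (0.25 * (1.0 - x) ** -2 - 0.25 + x)
    return out if out.ndim else float(out)


def wlc_loading_rate(lp: float, Lc: float, v: float, t,
                     kbt: float = DEFAULT_KBT):
    """Effective loading rate of a WLC pulled at constant velocity.

    r(t) = (kbt/lp) * (v/Lc) * [ 1/2 (1 - v t/Lc)^-3 + 1 ]   (pN/s)

    with lp in nm, Lc in um, v in um/s, t in s.
    """
    if v <= 0:
        raise ValueError("velocity must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= Lc / v):
        raise ProtocolDomainError(f"time outside [0, Lc/v={Lc / v} s)")
    x = v * t / Lc
    out = (kbt / lp) * (v / Lc) * (0.5 * (1.0 - x) ** -3 + 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class WLCProtocol(LoadingProtocol):
    """Worm-like-chain loading: bond pulled through a WLC tether at
    constant velocity, F(t) from the interpolation formula with L = v*t.

    Parameters: persistence length ``lp`` (nm), contour length ``Lc``
    (um), pulling velocity ``v`` (um/s), thermal energy ``kbt`` (pN nm).
    The domain ends at t_max = Lc/v where the inelastic chain is taut and
    the force diverges.
    """

    lp: float
    Lc: float
    v: float
    kbt: float = DEFAULT_KBT

    def __post_init__(self):
        if self.lp <= 0 or self.Lc <= 0 or self.v <= 0:
            raise ValueError("lp, Lc and v must be positive")

    @property
    def t_max(self) -> float:  # type: ignore[override]
        return self.Lc / self.v

    def force(self, t):
        t = self._check_time(t)
        return wlc_force(self.lp, self.Lc, self.v * t, self.kbt)

    def loading_rate(self, t):
        return wlc_loading_rate(self.lp, self.Lc, self.v, t, self.kbt)

    def dlnr_dt(self, t):
        # r = C [ 1/2 (1-x)^-3 + 1 ],  x = v t/Lc
        # dr/dt = C (v/Lc) (3/2) (1-x)^-4
        t = self._check_time(t)
        x = self.v * t / self.Lc
        one_minus = 1.0 - x
        num = 1.5 * (self.v / self.Lc) * one_minus**-4
        den = 0.5 * one_minus**-3 + 1.0
        out = num / den
        return out if out.ndim else float(out)

    def time_at_force(self, F):
        """Invert the WLC law: solve the cubic-in-(1-x) bracket equation."""
        F = np.asarray(F, dtype=float)
        if np.any(F < 0):
            raise ProtocolDomainError("negative force")
        scale = self.kbt / self.lp

        def _solve(fv: float) -> float:
            if fv == 0.0:
                return 0.0
            target = fv / scale

            def g(x):
                return 0.25 * (1.0 - x) ** -2 - 0.25 + x - target

            x = brentq(g, 0.0, 1.0 - 1e-15, xtol=1e-300, rtol=1e-15)
            return x * self.Lc / self.v

        if F.ndim == 0:
            return _solve(float(F))
        return np.array([_solve(fv) for fv in F.ravel()]).reshape(F.shape)

    def describe(self):
        return {
            "type": "wlc",
            "lp_nm": self.lp,
            "Lc_um": self.Lc,
            "v_um_per_s": self.v,
            "kbt_pN_nm": self.kbt,
        }


class TabulatedProtocol(LoadingProtocol):
    """Loading protocol built from a measured force--distance curve.

    The curve is given as sample points (L in um, F in pN) with both
    coordinates strictly increasing and L starting at 0; pulling at
    constant velocity v maps distance to time via L = v*t.  F(L) is
    represented by a monotone piecewise-cubic (PCHIP) interpolant whose
    analytic derivative supplies r = (dF/dL)*v and d ln r/dt.

    Build instances with :func:`tabulated_from_samples`.
    """

    def __init__(self, L: np.ndarray, F: np.ndarray, v: float,
                 _interp: PchipInterpolator, _dinterp: PchipInterpolator):
        self.L = L
        self.F = F
        self.v = v
        self._interp = _interp
        self._dinterp = _dinterp

    def __repr__(self):
        return (f"TabulatedProtocol(n_points={len(self.L)}, "
                f"v={self.v}, L_max={self.L[-1]})")

    @property
    def t_max(self) -> float:  # type: ignore[override]
        return float(self.L[-1]) / self.v

    def force(self, t):
        t = self._check_time(t)
        out = self._interp(self.v * t)
        return out if out.ndim else float(out)

    def loading_rate(self, t):
        t = self._check_time(t)
        out = self._dinterp(self.v * t) * self.v
        return out if out.ndim else float(out)

    def dlnr_dt(self, t):
        # d ln r/dt = v * F''(L) / F'(L)
        t = self._check_time(t)
        L = self.v * t
        out = self.v * self._dinterp.derivative()(L) / self._dinterp(L)
        return out if out.ndim else float(out)

    def describe(self):
        return {"type": "tabulated", "n_points": len(self.L), "v_um_per_s": self.v}


def tabulated_from_samples(
    points: Sequence | np.ndarray,
    v: float,
    smooth_window: int = 0,
) -> TabulatedProtocol:
    """Build a :class:`TabulatedProtocol` from (distance, force) samples.

    Parameters
    ----------
    points : array-like of shape (m, 2)
        Columns (L in um, F in pN); L strictly increasing, starting at 0;
        at least 4 points.
    v : pulling velocity, um/s.
    smooth_window : odd moving-average width applied to F before
        interpolation (0 disables).  Measured curves carry instrument
        noise that would otherwise leak into dF/dL.

    Raises
    ------
    ValueError
        If fewer than 4 points are given, L is not strictly increasing,
        or the (smoothed) force is not strictly increasing; the error
        names the first offending distance interval.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (L, F) sample points")
    if v <= 0:
        raise ValueError("velocity must be positive")
    L, F = pts[:, 0].copy(), pts[:, 1].copy()
    if L[0] != 0.0:
        raise ValueError("distance samples must start at L = 0")
    if np.any(np.diff(L) <= 0):
        i = int(np.argmax(np.diff(L) <= 0))
        raise ValueError(f"distances not strictly increasing at L = {L[i]:g} um")
    if smooth_window:
        if smooth_window % 2 == 0 or smooth_window < 3:
            raise ValueError("smooth_window must be odd and >= 3")
        k = smooth_window // 2
        padded = np.concatenate([np.full(k, F[0]), F, np.full(k, F[-1])])
        F = np.convolve(padded, np.ones(smooth_window) / smooth_window, "valid")
    dF = np.diff(F)
    if np.any(dF <= 0):
        i = int(np.argmax(dF <= 0))
        raise ValueError(
            "force not strictly increasing on "
            f"[{L[i]:g}, {L[i + 1]:g}] um after smoothing"
        )
    interp = PchipInterpolator(L, F, extrapolate=False)
    return TabulatedProtocol(
        L=L, F=F, v=v, _interp=interp, _dinterp=interp.derivative()
    )
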