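"""Bell off-rate, cumulative hazard, survival and rupture density."""

import numpy as np
import pytest

from nldfs import (
    BondParameters,
    ConstantRateProtocol,
    RuptureModel,
    WLCProtocol,
    cumulative_hazard,
    off_rate,
    rupture_density_force,
    survival,
)
from nldfs.protocols import ProtocolDomainError


class TestBondParameters:
    def test_validation_rejects_nonpositive(self):
        for bad in [dict(xb=0.0, koff_th=1e-4), dict(xb=0.7, koff_th=-1.0),
                    dict(xb=0.7, koff_th=1e-4, kbt=0.0)]:
            with pytest.raises(ValueError):
                BondParameters(**bad)

    def test_default_thermal_energy(self):
        assert BondParameters(xb=0.7, koff_th=1e-4).kbt == 4.11


class TestOffRate:
    @pytest.mark.parametrize(
        "force, expected, rtol",
        [
            (0.0, 1e-4, 0.0),                       # exp(0) = 1
            (4.11 / 0.70 * np.log(2.0), 2e-4, 1e-12),  # one force-scale doubling
            (70.7, 16.96279, 1e-5),                 # direct evaluation
        ],
    )
    def test_reference_values(self, bond, force, expected, rtol):
        assert off_rate(bond, force) == pytest.approx(expected, rel=rtol, abs=0)

    def test_monotone_in_force(self, bond):
        F = np.linspace(0, 120, 300)
        k = off_rate(bond, F)
        assert np.all(np.diff(k) > 0)

    def test_negative_force_rejected(self, bond):
        with pytest.raises(ValueError):
            off_rate(bond, -1.0)

    def test_exponent_overflow_guard(self, bond):
        # F*xb/kBT > 700 must raise, not return inf
        with pytest.raises(OverflowError):
            off_rate(bond, 701.0 * bond.kbt / bond.xb)
        assert np.isfinite(off_rate(bond, 699.0 * bond.kbt / bond.xb, cap=700.0))


class TestCumulativeHazard:
    def test_zero_at_time_origin(self, bond, linear_protocol, wlc_protocol):
        assert cumulative_hazard(bond, linear_protocol, 0.0) == 0.0
        assert cumulative_hazard(bond, wlc_protocol, 0.0) == 0.0

    def test_matches_constant_rate_closed_form(self, bond, linear_protocol):
        r = linear_protocol.rate
        # times chosen with H(t) spanning ~1e-5 .. ~1e2 (survival from
        # ~1 down to numerically 0)
        for t in [0.05, 0.2, 0.5, 0.8, 1.0]:
            a = r * bond.xb / bond.kbt
            expected = bond.koff_th / a * (np.exp(a * t) - 1.0)
            got = cumulative_hazard(bond, linear_protocol, t)
            assert got == pytest.approx(expected, rel=1e-8)

    def test_wlc_hazard_against_fine_trapezoid(self, bond, wlc_protocol):
        # independent oracle: brute-force trapezoid on a 2e6-point grid
        t_end = 0.9 * wlc_protocol.t_max
        ts = np.linspace(0.0, t_end, 2_000_001)
        koff = bond.koff_th * np.exp(
            np.asarray(wlc_protocol.force(ts)) * bond.xb / bond.kbt)
        expected = np.trapezoid(koff, ts)
        got = cumulative_hazard(bond, wlc_protocol, t_end)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_strictly_increasing_below_clamp(self, bond, wlc_protocol):
        ts = np.linspace(0.0, 0.99 * wlc_protocol.t_max, 64)
        H = cumulative_hazard(bond, wlc_protocol, ts)
        assert H[0] == 0.0
        sub = H[H < 700.0]  # beyond ~745 the hazard is clamped by design
        assert np.all(np.diff(sub) > 0)
        assert np.all(np.diff(H) >= 0)

    def test_outside_domain_rejected(self, bond, wlc_protocol):
        with pytest.raises(ProtocolDomainError):
            cumulative_hazard(bond, wlc_protocol, wlc_protocol.t_max * 1.5)
        with pytest.raises(ProtocolDomainError):
            cumulative_hazard(bond, wlc_protocol, -0.1)


class TestSurvival:
    def test_certain_at_time_origin(self, bond, linear_protocol):
        assert survival(bond, linear_protocol, 0.0) == 1.0

    def test_half_life_where_hazard_is_ln2(self, bond, linear_protocol):
        # solve H(t) = ln 2 from the closed form, then survival must be 1/2
        a = bond.xb / bond.kbt * linear_protocol.rate
        t_half = np.log(1.0 + np.log(2.0) * a / bond.koff_th) / a
        assert survival(bond, linear_protocol, t_half) == pytest.approx(0.5, rel=1e-8)

    def test_equals_exp_of_minus_hazard(self, bond, wlc_protocol):
        # restrict to the sub-clamp region where survival is resolvable
        ts = np.linspace(0.0, 0.9 * wlc_protocol.t_max, 40)
        P = survival(bond, wlc_protocol, ts)
        H = cumulative_hazard(bond, wlc_protocol, ts)
        np.testing.assert_allclose(P, np.exp(-H), rtol=1e-14)
        assert np.all(P > 0) and np.all(P <= 1)
        assert np.all(np.diff(P) <= 0)


class TestRuptureDensityForce:
    def test_normalized_over_attainable_range(self, bond, wlc_protocol,
                                              linear_protocol):
        for proto in (wlc_protocol, linear_protocol):
            model = RuptureModel(bond, proto)
            lo, hi = model.force_range
            F = np.linspace(lo, hi * (1 - 1e-9), 40_000)
            p = model.rupture_density_force(F)
            assert np.all(p >= 0)
            assert np.trapezoid(p, F) == pytest.approx(1.0, abs=1e-3)

    def test_mode_matches_constant_rate_closed_form(self, bond, linear_protocol):
        model = RuptureModel(bond, linear_protocol)
        F = np.linspace(0, 120, 24_001)
        p = model.rupture_density_force(F)
        f_mode = F[np.argmax(p)]
        expected = bond.kbt / bond.xb * np.log(
            linear_protocol.rate * bond.xb / (bond.koff_th * bond.kbt))
        assert f_mode == pytest.approx(expected, abs=0.01)

    def test_wlc_low_force_shoulder_mass(self, bond, wlc_protocol):
        # slow WLC pulling: a small but real fraction ruptures early
        model = RuptureModel(bond, wlc_protocol)
        F = np.linspace(0, 20, 2001)
        frac = np.trapezoid(model.rupture_density_force(F), F)
        assert 0.01 < frac < 0.5

    def test_module_level_wrapper_agrees(self, bond, linear_protocol):
        model = RuptureModel(bond, linear_protocol)
        assert rupture_density_force(bond, linear_protocol, 50.0) == pytest.approx(
            model.rupture_density_force(50.0), rel=1e-12)
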