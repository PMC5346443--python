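"""Loading protocols: forces, rates, log-rate derivatives, inverses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nldfs import (
    ConstantRateProtocol,
    PowerLawProtocol,
    WLCProtocol,
    tabulated_from_samples,
    wlc_force,
    wlc_loading_rate,
)
from nldfs.protocols import ProtocolDomainError


class TestWLCForce:
    def test_zero_extension_zero_force(self):
        assert wlc_force(3.0, 10.0, 0.0) == 0.0

    def test_half_contour_bracket_value(self):
        # bracket term is exactly 1/4*4 - 1/4 + 1/2 = 1.25 at L = Lc/2
        assert wlc_force(3.0, 10.0, 5.0) == pytest.approx(4.11 / 3.0 * 1.25)

    def test_diverges_toward_contour_length(self):
        assert wlc_force(3.0, 10.0, 10.0 * (1 - 1e-8)) > 1e10

    def test_outside_domain_rejected(self):
        with pytest.raises(ProtocolDomainError):
            wlc_force(3.0, 10.0, 10.0)

    def test_strictly_increasing(self):
        L = np.linspace(0, 9.99, 500)
        F = wlc_force(3.0, 10.0, L)
        assert np.all(np.diff(F) > 0)


class TestWLCLoadingRate:
    def test_initial_rate_closed_form(self):
        # r(0) = 1.5 * kBT * v / (lp * Lc) with the um/nm conversions folded in
        assert wlc_loading_rate(3.0, 10.0, 10.0, 0.0) == pytest.approx(2.055)

    def test_matches_finite_difference_of_force(self):
        lp, Lc, v = 3.0, 10.0, 10.0
        for t in [0.0, 0.3, 0.7, 0.95]:
            h = 1e-7
            fd = (wlc_force(lp, Lc, v * (t + h)) -
                  wlc_force(lp, Lc, v * max(t - h, 0.0))) / (
                      (t + h) - max(t - h, 0.0))
            assert wlc_loading_rate(lp, Lc, v, t) == pytest.approx(fd, rel=1e-5)

    def test_domain_end_rejected(self):
        with pytest.raises(ProtocolDomainError):
            wlc_loading_rate(3.0, 10.0, 10.0, 1.0)


class TestLogRateDerivative:
    def test_constant_rate_protocol_is_zero(self):
        proto = ConstantRateProtocol(rate=100.0)
        assert proto.dlnr_dt(0.0) == 0.0
        assert proto.dlnr_dt(5.0) == 0.0

    def test_power_law_is_n_minus_one_over_t(self):
        proto = PowerLawProtocol(coefficient=1e-3, exponent=2, v=10.0)
        assert proto.dlnr_dt(10.0) == pytest.approx(0.1)
        assert np.isposinf(proto.dlnr_dt(0.0))

    @pytest.mark.parametrize("t_frac", [0.1, 0.5, 0.9, 0.99])
    def test_wlc_matches_finite_difference_of_log_rate(self, t_frac):
        proto = WLCProtocol(lp=3.0, Lc=10.0, v=10.0)
        t = t_frac * proto.t_max
        h = 1e-8 * proto.t_max
        fd = (np.log(proto.loading_rate(t + h)) -
              np.log(proto.loading_rate(t - h))) / (2 * h)
        assert proto.dlnr_dt(t) == pytest.approx(fd, rel=1e-5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    lp=st.floats(0.5, 50.0),
    Lc=st.floats(0.5, 100.0),
    v=st.floats(1e-3, 1e3),
)
def test_wlc_protocol_monotone_force_positive_rate(lp, Lc, v):
    """Any WLC protocol has strictly increasing force and positive rate."""
    proto = WLCProtocol(lp=lp, Lc=Lc, v=v)
    ts = np.linspace(0.0, 0.999 * proto.t_max, 200)
    F = proto.force(ts)
    r = proto.loading_rate(ts)
    assert np.all(np.diff(F) > 0)
    assert np.all(r > 0)
    # analytic rate agrees with a central finite difference
    mid = ts[1:-1]
    fd = (proto.force(mid + 1e-7 * proto.t_max) -
          proto.force(mid - 1e-7 * proto.t_max)) / (2e-7 * proto.t_max)
    np.testing.assert_allclose(proto.loading_rate(mid), fd, rtol=1e-4)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    coeff=st.floats(1e-5, 10.0),
    n=st.integers(1, 4),
    v=st.floats(1e-2, 1e3),
)
def test_power_law_monotone_and_consistent(coeff, n, v):
    proto = PowerLawProtocol(coefficient=coeff, exponent=n, v=v)
    ts = np.linspace(1e-6, 10.0, 100)
    F = proto.force(ts)
    assert np.all(np.diff(F) > 0)
    assert np.all(proto.loading_rate(ts) > 0)
    np.testing.assert_allclose(proto.time_at_force(F), ts, rtol=1e-10)


class TestTimeAtForce:
    def test_wlc_inverse_round_trip(self):
        proto = WLCProtocol(lp=3.0, Lc=10.0, v=0.01)
        ts = np.linspace(0.0, 0.9999 * proto.t_max, 50)
        F = proto.force(ts)
        np.testing.assert_allclose(proto.time_at_force(F), ts,
                                   rtol=1e-10, atol=1e-12)

    def test_unreachable_force_rejected(self):
        proto = ConstantRateProtocol(rate=100.0)
        with pytest.raises(ProtocolDomainError):
            proto.time_at_force(-5.0)


class TestTabulatedProtocol:
    def test_linear_samples_reproduce_constant_rate(self):
        a1, v = 10.0, 2.0
        L = np.linspace(0.0, 5.0, 50)
        proto = tabulated_from_samples(np.column_stack([L, a1 * L]), v=v)
        ts = np.linspace(0.0, 0.99 * proto.t_max, 40)
        np.testing.assert_allclose(proto.loading_rate(ts), a1 * v, rtol=1e-6)

    def test_wlc_samples_match_analytic_protocol_downstream(self, bond):
        from nldfs import peak_force_nonlinear
        analytic = WLCProtocol(lp=3.0, Lc=10.0, v=0.01)
        L = np.linspace(0.0, 10.0 * (1 - 1e-4), 200)
        F = wlc_force(3.0, 10.0, L)
        tab = tabulated_from_samples(np.column_stack([L, F]), v=0.01)
        f_tab = peak_force_nonlinear(bond, tab).force
        f_ana = peak_force_nonlinear(bond, analytic).force
        assert f_tab == pytest.approx(f_ana, rel=0.01)

    def test_too_few_points_rejected(self):
        pts = [[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]
        with pytest.raises(ValueError, match="4"):
            tabulated_from_samples(pts, v=1.0)

    def test_non_monotone_force_names_interval(self):
        pts = [[0.0, 0.0], [1.0, 2.0], [2.0, 1.5], [3.0, 3.0], [4.0, 4.0]]
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            tabulated_from_samples(pts, v=1.0)

    def test_smoothing_recovers_noisy_monotone_curve(self):
        rng = np.random.default_rng(5)
        L = np.linspace(0.0, 5.0, 120)
        F = 10.0 * L + rng.normal(0.0, 0.05, L.size)
        F[0] = 0.0
        proto = tabulated_from_samples(np.column_stack([L, F]), v=1.0,
                                       smooth_window=9)
        # away from the ends, where the moving window has full support
        ts = np.linspace(0.15, 0.85 * proto.t_max, 30)
        # residual derivative noise after a 9-point window is ~sigma-level
        np.testing.assert_allclose(proto.loading_rate(ts), 10.0, rtol=0.12)
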