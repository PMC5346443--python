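"""Parameter recovery from (velocity, peak force) data."""

import numpy as np
import pytest

from nldfs import (
    BondParameters,
    ConstantRateFamily,
    VelocityPeakPair,
    error_study,
    fit_parameters,
    peak_force_linear,
    predict_peak_forces,
)
from tests.conftest import REFERENCE_VELOCITIES

#: Analytic peaks of the reference WLC scenario (pN), slowest to fastest.
WLC_REFERENCE_PEAKS = (41.55, 58.61, 74.49, 89.81)

#: One simulated 50-measurement realization's peak forces (pN) for the
#: same four velocities, and the parameters a deterministic least-squares
#: fit of the implicit relation recovers from them.
SIMULATED_PEAKS_N50 = (39.57, 55.33, 74.58, 88.47)
FIT_FROM_SIMULATED = (0.685, 1.54e-4)


class TestPredictPeakForces:
    def test_wlc_reference_velocity_sweep(self, bond, wlc_family):
        peaks = predict_peak_forces(bond, wlc_family, REFERENCE_VELOCITIES)
        np.testing.assert_allclose(peaks, WLC_REFERENCE_PEAKS, atol=0.01)

    def test_linear_family_reduces_to_closed_form(self, bond):
        fam = ConstantRateFamily(stiffness=10.0)  # r = 10*v pN/s
        vels = [1.0, 5.0, 25.0, 125.0]
        got = predict_peak_forces(bond, fam, vels)
        expected = [peak_force_linear(bond, 10.0 * v).force for v in vels]
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_monotone_in_velocity(self, bond, wlc_family):
        vels = np.geomspace(0.01, 10.0, 9)
        peaks = predict_peak_forces(bond, wlc_family, vels)
        assert np.all(np.diff(peaks) > 0)


class TestFitParameters:
    def test_noise_free_round_trip_identifiability(self, bond, wlc_family):
        # predict -> fit must recover the true parameters: the core
        # identifiability property of the measurement protocol
        peaks = predict_peak_forces(bond, wlc_family, REFERENCE_VELOCITIES)
        pairs = [VelocityPeakPair(v, f)
                 for v, f in zip(REFERENCE_VELOCITIES, peaks)]
        fit = fit_parameters(pairs, wlc_family)
        assert fit.xb_hat == pytest.approx(bond.xb, rel=1e-3)
        assert fit.koff_hat == pytest.approx(bond.koff_th, rel=1e-3)
        assert fit.objective < 1e-8

    def test_fit_from_simulated_realization_peaks(self, bond, wlc_family):
        # deterministic fit from one finite-sample realization's peaks
        pairs = [VelocityPeakPair(v, f)
                 for v, f in zip(REFERENCE_VELOCITIES, SIMULATED_PEAKS_N50)]
        fit = fit_parameters(pairs, wlc_family)
        assert fit.xb_hat == pytest.approx(FIT_FROM_SIMULATED[0], rel=0.01)
        assert fit.koff_hat == pytest.approx(FIT_FROM_SIMULATED[1], rel=0.05)

    def test_two_pairs_minimum(self, bond, wlc_family):
        peaks = predict_peak_forces(bond, wlc_family, REFERENCE_VELOCITIES[:2])
        pairs = [VelocityPeakPair(v, f)
                 for v, f in zip(REFERENCE_VELOCITIES[:2], peaks)]
        fit = fit_parameters(pairs, wlc_family)
        assert fit.xb_hat == pytest.approx(bond.xb, rel=0.01)

    def test_single_pair_rejected(self, bond, wlc_family):
        with pytest.raises(ValueError):
            fit_parameters([VelocityPeakPair(1.0, 50.0)], wlc_family)

    def test_deterministic_given_data(self, wlc_family):
        pairs = [VelocityPeakPair(v, f)
                 for v, f in zip(REFERENCE_VELOCITIES, SIMULATED_PEAKS_N50)]
        a = fit_parameters(pairs, wlc_family)
        b = fit_parameters(pairs, wlc_family)
        assert (a.xb_hat, a.koff_hat) == (b.xb_hat, b.koff_hat)


@pytest.fixture(scope="module")
def small_study(bond, wlc_family):
    return error_study(
        bond, wlc_family, REFERENCE_VELOCITIES,
        sample_sizes=[50], iterations=25, sigma_kde=3.0, seed=42,
        keep_records=True,
    )


class TestErrorStudy:
    def test_summary_statistics_coherent(self, small_study):
        row = small_study.summary.loc[50]
        assert row["mean_rel_err_xb"] >= 0
        assert (row["q25_rel_err_koff"] <= row["q50_rel_err_koff"]
                <= row["q75_rel_err_koff"])
        assert row["n_ok"] + row["n_failed"] == 25

    def test_bond_length_better_identified_than_off_rate(self, small_study):
        # the peak force is far more sensitive to xb than to koff
        row = small_study.summary.loc[50]
        assert row["mean_rel_err_xb"] < row["mean_rel_err_koff"]

    def test_peak_error_decreases_with_velocity(self, small_study):
        errs = small_study.peak_errors.loc[50].to_numpy()
        assert errs[0] > errs[-1]

    def test_reproducible_under_master_seed(self, bond, wlc_family,
                                            small_study):
        again = error_study(
            bond, wlc_family, REFERENCE_VELOCITIES,
            sample_sizes=[50], iterations=25, sigma_kde=3.0, seed=42,
        )
        assert again.summary.equals(small_study.summary)

    def test_invalid_arguments_rejected(self, bond, wlc_family):
        with pytest.raises(ValueError):
            error_study(bond, wlc_family, REFERENCE_VELOCITIES, [50],
                        iterations=0, seed=1)
        with pytest.raises(ValueError):
            error_study(bond, wlc_family, REFERENCE_VELOCITIES, [1],
                        iterations=1, seed=1)


def test_identifiability_for_shifted_truth(wlc_family):
    """Round-trip recovery also holds away from the reference bond."""
    truth = BondParameters(xb=0.45, koff_th=3e-5)
    peaks = predict_peak_forces(truth, wlc_family, REFERENCE_VELOCITIES)
    pairs = [VelocityPeakPair(v, f)
             for v, f in zip(REFERENCE_VELOCITIES, peaks)]
    fit = fit_parameters(pairs, wlc_family)
    assert fit.xb_hat == pytest.approx(truth.xb, rel=1e-3)
    assert fit.koff_hat == pytest.approx(truth.koff_th, rel=1e-3)
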