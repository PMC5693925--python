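"""FDNIRS inversion: medians, calibration, slope fitting, QC rules."""

import numpy as np
import pytest
from scipy import optimize

from nirsflow.cohort import simulate_phantom
from nirsflow.fdnirs import (
    SlopeFit,
    calibrate,
    fdnirs_qc,
    identity_calibration,
    invert_measurement,
    multidistance_fit,
    temporal_median,
)
from nirsflow.forward import dpdw_wavenumbers, fdnirs_forward


def _medians_from_state(mua, musp, instrument, **kw):
    ac, phase = fdnirs_forward(mua, musp, instrument, **kw)
    return temporal_median(ac, phase)


class TestTemporalMedian:
    def test_constant_series(self):
        ac = np.full((4, 100), 3.0)
        ph = np.full((4, 100), 0.5)
        m_ac, m_ph, noise = temporal_median(ac, ph)
        assert np.all(m_ac == 3.0) and np.all(m_ph == 0.5)
        assert np.all(noise == 0.0)

    def test_median_robust_to_single_outlier(self):
        ac = np.full((1, 100), 2.0)
        ac[0, 17] = 1e6
        m_ac, _, _ = temporal_median(ac, np.zeros((1, 100)))
        assert m_ac[0] == 2.0

    def test_phase_noise_estimates_generating_sigma(self):
        rng = np.random.default_rng(11)
        ph = rng.normal(1.0, 0.02, (1, 100))
        _, _, noise = temporal_median(np.ones((1, 100)), ph)
        assert noise[0] == pytest.approx(0.02, rel=0.25)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            temporal_median(np.empty((4, 0)), np.empty((4, 0)))


class TestMultidistanceFit:
    def test_inverts_analytic_forward_exactly(self, instrument):
        m_ac, m_ph, _ = _medians_from_state(0.1, 10.0, instrument)
        mua, musp, fit = multidistance_fit(m_ac, m_ph, instrument)
        assert mua == pytest.approx(0.1, rel=1e-10)
        assert musp == pytest.approx(10.0, rel=1e-10)
        assert fit.r2_ac == pytest.approx(1.0, abs=1e-12)
        assert fit.r2_phase == pytest.approx(1.0, abs=1e-12)

    def test_equal_slopes_give_zero_absorption(self, instrument):
        """s_ac = s_phase is the zero-absorption limit of the slope algebra."""
        s = 1.3
        omega, v = instrument.omega, instrument.speed_in_tissue
        mua = (omega / (2 * v)) * (s / s - s / s)
        assert mua == 0.0

    def test_agrees_with_numerical_slope_search(self, instrument):
        """Inversion formulas vs brute-force 2-parameter slope matching."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            mua_true = rng.uniform(0.05, 0.25)
            musp_true = rng.uniform(4.0, 15.0)
            m_ac, m_ph, _ = _medians_from_state(mua_true, musp_true, instrument)
            mua_hat, musp_hat, fit = multidistance_fit(m_ac, m_ph, instrument)

            def mismatch(x):
                k = dpdw_wavenumbers(x[0], x[1], instrument)
                return (k.k_real - fit.s_ac) ** 2 + (k.k_imag - fit.s_phase) ** 2

            res = optimize.minimize(mismatch, [0.1, 8.0], method="Nelder-Mead",
                                    options={"xatol": 1e-12, "fatol": 1e-24})
            assert mua_hat == pytest.approx(res.x[0], rel=1e-6)
            assert musp_hat == pytest.approx(res.x[1], rel=1e-6)

    def test_unphysical_slopes_flagged_invalid(self, instrument):
        rho = np.array(instrument.fdnirs_distances_cm)
        ac = np.exp(+1.0 * rho) / rho**2  # amplitude grows with distance
        mua, musp, fit = multidistance_fit(ac, 0.2 * rho, instrument)
        assert not fit.valid and np.isnan(mua) and np.isnan(musp)

    def test_too_few_distances_rejected(self, instrument):
        with pytest.raises(ValueError):
            multidistance_fit(np.array([1.0, np.nan, np.nan, 0.5]),
                              np.zeros(4), instrument)


class TestQC:
    @pytest.mark.parametrize("phase_noise,r2,keep", [
        (0.06, 1.0, False),   # noisy phase channel is discarded
        (0.05, 1.0, True),    # boundary inclusive on the keep side
        (0.01, 0.94, False),  # poor linear fit is discarded
        (0.01, 0.95, True),
        (0.01, 0.99, True),
    ])
    def test_thresholds(self, phase_noise, r2, keep):
        fit = SlopeFit(s_ac=1.0, s_phase=0.2, r2_ac=r2, r2_phase=r2,
                       phase_noise=phase_noise)
        assert fdnirs_qc(fit) is keep


class TestCalibration:
    def test_undistorted_phantom_yields_identity(self, instrument):
        n_wl = len(instrument.fdnirs_wavelengths_nm)
        mua = np.full(n_wl, 0.1)
        musp = np.full(n_wl, 10.0)
        ac, ph = simulate_phantom(mua, musp, instrument)
        factors = calibrate(ac, ph, mua, musp, instrument)
        assert np.allclose(factors.amplitude_gain, 1.0, rtol=1e-12)
        assert np.allclose(factors.phase_offset, 0.0, atol=1e-12)

    def test_recovers_injected_distortions(self, instrument):
        rng = np.random.default_rng(4)
        n_wl = len(instrument.fdnirs_wavelengths_nm)
        n_d = len(instrument.fdnirs_distances_cm)
        mua = np.full(n_wl, 0.12)
        musp = np.full(n_wl, 8.0)
        amp_d = rng.uniform(0.5, 2.0, (n_wl, n_d))
        ph_d = rng.uniform(-0.5, 0.5, (n_wl, n_d))
        ac, ph = simulate_phantom(mua, musp, instrument,
                                  amplitude_distortion=amp_d, phase_distortion=ph_d)
        factors = calibrate(ac, ph, mua, musp, instrument)
        assert np.allclose(factors.amplitude_gain * amp_d, 1.0, rtol=1e-10)
        assert np.allclose(factors.phase_offset, ph_d, atol=1e-10)

    def test_calibrated_phantom_reinverts_to_known_properties(self, instrument):
        rng = np.random.default_rng(9)
        n_wl = len(instrument.fdnirs_wavelengths_nm)
        n_d = len(instrument.fdnirs_distances_cm)
        mua = np.linspace(0.08, 0.2, n_wl)
        musp = np.linspace(12.0, 7.0, n_wl)
        amp_d = rng.uniform(0.7, 1.5, (n_wl, n_d))
        ph_d = rng.uniform(-0.3, 0.3, (n_wl, n_d))
        ac, ph = simulate_phantom(mua, musp, instrument,
                                  amplitude_distortion=amp_d, phase_distortion=ph_d)
        factors = calibrate(ac, ph, mua, musp, instrument)
        spectrum = invert_measurement(ac, ph, factors, instrument)
        assert np.allclose(spectrum.mua, mua, rtol=1e-3)
        assert np.allclose(spectrum.musp, musp, rtol=1e-3)
        assert spectrum.qc_pass.all()

    def test_missing_channel_rejected(self, instrument):
        with pytest.raises(ValueError, match="channels"):
            calibrate(np.ones((8, 3, 10)), np.ones((8, 3, 10)),
                      np.full(8, 0.1), np.full(8, 10.0), instrument)

    def test_identity_calibration_is_identity(self, instrument):
        factors = identity_calibration(instrument)
        ac = np.random.default_rng(0).uniform(1, 2, (4, 5))
        ph = np.random.default_rng(1).uniform(0, 1, (4, 5))
        ac2, ph2 = factors.apply(ac, ph, 0)
        np.testing.assert_array_equal(ac, ac2)
        np.testing.assert_array_equal(ph, ph2)
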