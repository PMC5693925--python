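"""Multi-distance FDNIRS inversion: calibration, temporal reduction,
slope fitting and quality control.

For each wavelength the instrument records the AC amplitude and phase of
the photon density wave at four source-detector separations.  After
calibrating against a solid phantom of known optical properties and taking
temporal medians, ln(AC·ρ²) and phase are fitted as straight lines in ρ;
identifying the negated amplitude slope with the real wavenumber k_r and
the phase slope with the imaginary wavenumber k_i inverts to

    μs′ = 2 v k_r k_i / (3 ω),      μa = (ω / 2v)·(k_r/k_i − k_i/k_r),

with v the speed of light in tissue and ω the angular modulation
frequency.  Measurements are discarded when the worst-channel phase noise
exceeds 0.05 rad or either line's R² falls below 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .forward import ComplexWavenumber, InstrumentConfig, dpdw_wavenumbers

PHASE_NOISE_MAX_RAD = 0.05
SLOPE_R2_MIN = 0.95


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationFactors:
    """Per-(wavelength, distance) amplitude gain and phase offset.

    ``amplitude_gain[i, j]`` multiplies the raw AC of wavelength i at
    distance j; ``phase_offset[i, j]`` is subtracted from the raw phase.
    """

    wavelengths_nm: np.ndarray
    distances_cm: np.ndarray
    amplitude_gain: np.ndarray  # (n_wavelengths, n_distances)
    phase_offset: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.amplitude_gain <= 0):
            raise CalibrationError("amplitude gains must be positive")

    def apply(self, ac: np.ndarray, phase: np.ndarray, i_wavelength: int):
        """Calibrate raw (ac, phase) arrays of shape (n_distances, ...)."""
        g = self.amplitude_gain[i_wavelength][:, None]
        off = self.phase_offset[i_wavelength][:, None]
        ac2 = np.atleast_2d(ac)
        ph2 = np.atleast_2d(phase)
        return ac2 * g, ph2 - off


@dataclass
class SlopeFit:
    """Diagnostics of one wavelength's multi-distance linear fits."""

    s_ac: float       # negated slope of ln(AC·ρ²) vs ρ, cm⁻¹
    s_phase: float    # slope of phase vs ρ, cm⁻¹
    r2_ac: float
    r2_phase: float
    phase_noise: float = 0.0  # worst-channel std of the phase samples, rad
    valid: bool = True


@dataclass
class OpticalSpectrum:
    """Per-wavelength μa, μs′ with fit diagnostics for one measurement."""

    wavelengths_nm: np.ndarray
    mua: np.ndarray
    musp: np.ndarray
    slope_fits: list[SlopeFit] = field(default_factory=list)
    qc_pass: np.ndarray | None = None


def temporal_median(ac_series: np.ndarray, phase_series: np.ndarray):
    """Reduce per-channel time series to medians.

    Parameters
    ----------
    ac_series, phase_series
        Arrays of shape (n_distances, n_samples); the ~100 samples of one
        10 s acquisition.

    Returns
    -------
    (median_ac, median_phase, phase_noise)
        Per-distance medians and the per-distance standard deviation of
        the phase samples (the phase-noise QC statistic).
    """
    ac_series = np.atleast_2d(np.asarray(ac_series, dtype=float))
    phase_series = np.atleast_2d(np.asarray(phase_series, dtype=float))
    if ac_series.shape[-1] == 0 or phase_series.shape[-1] == 0:
        raise ValueError("empty time series")
    med_ac = np.median(ac_series, axis=-1)
    med_phase = np.median(phase_series, axis=-1)
    phase_noise = np.std(phase_series, axis=-1, ddof=1) if phase_series.shape[-1] > 1 \
        else np.zeros(phase_series.shape[0])
    return med_ac, med_phase, phase_noise


def calibrate(
    phantom_ac: np.ndarray,
    phantom_phase: np.ndarray,
    known_mua: np.ndarray,
    known_musp: np.ndarray,
    config: InstrumentConfig,
) -> CalibrationFactors:
    """Derive per-channel calibration factors from a solid-phantom run.

    Parameters
    ----------
    phantom_ac, phantom_phase
        Raw phantom data, shape (n_wavelengths, n_distances, n_samples).
    known_mua, known_musp
        The phantom's certified optical properties per wavelength, cm⁻¹.

    The gain is model-predicted AC over measured median AC and the offset
    is measured median phase minus model-predicted phase, per channel, so
    applying the factors maps the instrument response onto the diffusion
    model exactly for the phantom.
    """
    wavelengths = np.asarray(config.fdnirs_wavelengths_nm, dtype=float)
    rho = np.asarray(config.fdnirs_distances_cm, dtype=float)
    phantom_ac = np.asarray(phantom_ac, dtype=float)
    phantom_phase = np.asarray(phantom_phase, dtype=float)
    if phantom_ac.shape[:2] != (wavelengths.size, rho.size):
        raise CalibrationError(
            f"phantom data shape {phantom_ac.shape[:2]} does not cover all "
            f"({wavelengths.size} wavelengths, {rho.size} distances) channels"
        )
    if len(known_mua) != wavelengths.size or len(known_musp) != wavelengths.size:
        raise CalibrationError("need one known (mua, musp) pair per wavelength")
    gains = np.empty((wavelengths.size, rho.size))
    offsets = np.empty_like(gains)
    for i in range(wavelengths.size):
        k = dpdw_wavenumbers(float(known_mua[i]), float(known_musp[i]), config)
        model_ac = np.exp(-k.k_real * rho) / rho**2
        model_phase = k.k_imag * rho
        med_ac, med_phase, _ = temporal_median(phantom_ac[i], phantom_phase[i])
        gains[i] = model_ac / med_ac
        offsets[i] = med_phase - model_phase
    return CalibrationFactors(
        wavelengths_nm=wavelengths, distances_cm=rho,
        amplitude_gain=gains, phase_offset=offsets,
    )


def identity_calibration(config: InstrumentConfig) -> CalibrationFactors:
    """Unit gains and zero offsets (for already-calibrated data)."""
    shape = (len(config.fdnirs_wavelengths_nm), len(config.fdnirs_distances_cm))
    return CalibrationFactors(
        wavelengths_nm=np.asarray(config.fdnirs_wavelengths_nm, dtype=float),
        distances_cm=np.asarray(config.fdnirs_distances_cm, dtype=float),
        amplitude_gain=np.ones(shape),
        phase_offset=np.zeros(shape),
    )


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line y = a + b x; returns (slope, intercept, R²)."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def multidistance_fit(
    median_ac: np.ndarray,
    median_phase: np.ndarray,
    config: InstrumentConfig,
    phase_noise: np.ndarray | float = 0.0,
) -> tuple[float, float, SlopeFit]:
    """Invert one wavelength's multi-distance medians to (μa, μs′).

    Fits ln(AC·ρ²) and phase against ρ by ordinary least squares and maps
    the slopes through the DPDW wavenumber identities.  Returns NaN
    coefficients with ``valid=False`` when either slope is unphysical
    (non-positive decay or phase slope).
    """
    rho = np.asarray(config.fdnirs_distances_cm, dtype=float)
    median_ac = np.asarray(median_ac, dtype=float)
    median_phase = np.asarray(median_phase, dtype=float)
    finite = np.isfinite(median_ac) & (median_ac > 0) & np.isfinite(median_phase)
    if finite.sum() < 3:
        raise ValueError("need at least 3 distances with finite, positive AC")
    x = rho[finite]
    ln_ac_rho2 = np.log(median_ac[finite] * x**2)
    slope_ac, _, r2_ac = _line_fit(x, ln_ac_rho2)
    slope_ph, _, r2_phase = _line_fit(x, median_phase[finite])
    s_ac = -slope_ac
    s_phase = slope_ph
    worst_phase_noise = float(np.max(np.atleast_1d(phase_noise)))
    fit = SlopeFit(s_ac=s_ac, s_phase=s_phase, r2_ac=r2_ac, r2_phase=r2_phase,
                   phase_noise=worst_phase_noise)
    if s_ac <= 0 or s_phase <= 0:
        fit.valid = False
        return float("nan"), float("nan"), fit
    omega = config.omega
    v = config.speed_in_tissue
    musp = 2.0 * v * s_ac * s_phase / (3.0 * omega)
    mua = (omega / (2.0 * v)) * (s_ac / s_phase - s_phase / s_ac)
    if mua < 0 or musp <= 0:
        fit.valid = False
        return float("nan"), float("nan"), fit
    return float(mua), float(musp), fit


def fdnirs_qc(
    fit: SlopeFit,
    phase_noise_max: float = PHASE_NOISE_MAX_RAD,
    r2_min: float = SLOPE_R2_MIN,
) -> bool:
    """Keep a wavelength iff phase noise ≤ 0.05 rad and both R² ≥ 0.95.

    Comparisons are inclusive on the keep side; thresholds configurable.
    """
    return bool(
        fit.valid
        and fit.phase_noise <= phase_noise_max
        and fit.r2_ac >= r2_min
        and fit.r2_phase >= r2_min
    )


def invert_measurement(
    ac: np.ndarray,
    phase: np.ndarray,
    calibration: CalibrationFactors,
    config: InstrumentConfig,
    phase_noise_max: float = PHASE_NOISE_MAX_RAD,
    r2_min: float = SLOPE_R2_MIN,
) -> OpticalSpectrum:
    """Calibrate → median → slope-fit one measurement at all wavelengths.

    Parameters
    ----------
    ac, phase
        Raw data of shape (n_wavelengths, n_distances, n_samples).
    """
    wavelengths = np.asarray(config.fdnirs_wavelengths_nm, dtype=float)
    mua = np.full(wavelengths.size, np.nan)
    musp = np.full(wavelengths.size, np.nan)
    qc = np.zeros(wavelengths.size, dtype=bool)
    fits: list[SlopeFit] = []
    for i in range(wavelengths.size):
        ac_cal, ph_cal = calibration.apply(ac[i], phase[i], i)
        med_ac, med_phase, phase_noise = temporal_median(ac_cal, ph_cal)
        mua_i, musp_i, fit = multidistance_fit(med_ac, med_phase, config, phase_noise)
        fits.append(fit)
        mua[i], musp[i] = mua_i, musp_i
        qc[i] = fdnirs_qc(fit, phase_noise_max, r2_min)
    return OpticalSpectrum(wavelengths_nm=wavelengths, mua=mua, musp=musp,
                           slope_fits=fits, qc_pass=qc)
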