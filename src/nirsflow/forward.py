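"""Closed-form forward models for frequency-domain photon diffusion and
correlation diffusion in the semi-infinite reflection geometry.

Two physics problems are solved here, both as damped-wave solutions of a
diffusion equation in a half space:

* **Diffuse photon density waves (DPDW).**  Intensity-modulated light
  (here 110 MHz) launched into a highly scattering medium produces a
  spherical wave whose amplitude decays and whose phase advances linearly
  with source-detector distance.  The complex wavenumber of that wave is an
  analytic function of the absorption coefficient ``mua`` and reduced
  scattering coefficient ``musp``; measuring the amplitude and phase slopes
  over several distances therefore determines both coefficients.

* **Correlation diffusion.**  The electric-field autocorrelation of
  coherent light that has multiply scattered off moving red blood cells
  obeys a diffusion equation with a decay rate set by the blood flow index
  ``cbfi``.  The semi-infinite Green's function with an extrapolated zero
  boundary gives the normalized field autocorrelation ``g1``; the Siegert
  relation maps it to the measured intensity autocorrelation
  ``g2 = 1 + beta * g1**2``.

These closed forms are used both to generate synthetic raw data and as the
model functions inside the inverse fits, so round-trip recovery tests
exercise exactly the physics the inversion assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPEED_OF_LIGHT_CM_S = 2.99792458e10

#: Effective reflection coefficient for a refractive index of 1.4,
#: standard approximation used in the extrapolated-boundary condition.
R_EFF_N14 = 0.493

DEFAULT_WAVELENGTHS_NM = (672.0, 689.0, 701.0, 724.0, 771.0, 783.0, 803.0, 829.0)
DEFAULT_DISTANCES_CM = (1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry, wavelengths and timing of the hybrid FDNIRS-DCS instrument.

    Defaults describe a frequency-domain system modulated at 110 MHz with
    eight laser wavelengths and four source-detector separations, run
    concurrently with a single-distance DCS channel at 850 nm.
    """

    modulation_frequency_hz: float = 110e6
    fdnirs_wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    fdnirs_distances_cm: tuple[float, ...] = DEFAULT_DISTANCES_CM
    dcs_wavelength_nm: float = 850.0
    dcs_distance_cm: float = 2.0
    tau_grid_s: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.logspace(-7, -1, 128))
    )
    refractive_index: float = 1.4
    fdnirs_rate_hz: float = 10.0
    dcs_rate_hz: float = 1.2
    acquisition_duration_s: float = 10.0

    def __post_init__(self) -> None:
        dist = np.asarray(self.fdnirs_distances_cm, dtype=float)
        if dist.size == 0 or np.any(dist <= 0) or np.any(np.diff(dist) <= 0):
            raise ValueError("fdnirs_distances_cm must be positive and strictly increasing")
        tau = np.asarray(self.tau_grid_s, dtype=float)
        if tau.size == 0 or np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau_grid_s must be positive and strictly increasing")
        for name in ("modulation_frequency_hz", "dcs_wavelength_nm", "dcs_distance_cm",
                     "refractive_index", "fdnirs_rate_hz", "dcs_rate_hz",
                     "acquisition_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(w <= 0 for w in self.fdnirs_wavelengths_nm):
            raise ValueError("wavelengths must be positive")

    @property
    def omega(self) -> float:
        """Angular modulation frequency, rad/s."""
        return 2.0 * np.pi * self.modulation_frequency_hz

    @property
    def speed_in_tissue(self) -> float:
        """Speed of light in the medium, cm/s."""
        return SPEED_OF_LIGHT_CM_S / self.refractive_index

    @property
    def n_fdnirs_samples(self) -> int:
        return int(round(self.fdnirs_rate_hz * self.acquisition_duration_s))

    @property
    def n_dcs_curves(self) -> int:
        return int(round(self.dcs_rate_hz * self.acquisition_duration_s))

    def tau_array(self) -> np.ndarray:
        return np.asarray(self.tau_grid_s, dtype=float)


@dataclass
class TissueState:
    """Ground-truth optical and physiological parameters of one tissue volume.

    hbo, hbr
        Oxy-/deoxy-hemoglobin concentration, μM.
    water_fraction
        Volume fraction of water, dimensionless (brain convention 0.75).
    a_500, b_power
        Mie power-law scattering parameters: μs′(λ) = a·(λ/500 nm)^−b, with
        ``a_500`` in cm⁻¹.
    cbfi
        Blood flow index, cm²/s.
    beta
        Siegert coherence factor, 0 < β ≤ 1.
    sao2
        Arterial oxygen saturation (pulse-oximeter), fraction.
    """

    hbo: float
    hbr: float
    a_500: float
    b_power: float
    cbfi: float
    beta: float = 0.5
    sao2: float = 0.98
    water_fraction: float = 0.75

    def __post_init__(self) -> None:
        if min(self.hbo, self.hbr, self.a_500, self.cbfi) < 0:
            raise ValueError("hbo, hbr, a_500 and cbfi must be nonnegative")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must be in [0, 1]")
        if not 0.0 <= self.sao2 <= 1.0:
            raise ValueError("sao2 must be in [0, 1]")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")

    @property
    def hbt(self) -> float:
        return self.hbo + self.hbr

    @property
    def so2(self) -> float:
        return self.hbo / self.hbt if self.hbt > 0 else float("nan")


@dataclass(frozen=True)
class ComplexWavenumber:
    """Real and imaginary DPDW wavenumber, cm⁻¹.

    ``k_real`` is the decay rate of ln(AC·ρ²) with distance; ``k_imag`` is
    the phase slope.  They satisfy k_real² − k_imag² = 3·μa·μs′ and
    k_real·k_imag = 3·μs′·ω/(2v) for the generating coefficients.
    """

    k_real: float
    k_imag: float

    def __post_init__(self) -> None:
        if not (self.k_real >= self.k_imag >= 0.0):
            raise ValueError("require k_real >= k_imag >= 0")


def dpdw_wavenumbers(mua: float, musp: float, config: InstrumentConfig) -> ComplexWavenumber:
    """Complex wavenumber of the diffuse photon density wave.

    Parameters
    ----------
    mua, musp
        Absorption and reduced scattering coefficients, cm⁻¹; both > 0.

    Returns
    -------
    ComplexWavenumber
        k_real = sqrt((3 μa μs′ / 2)(sqrt(1 + (ω/(v μa))²) + 1)),
        k_imag = sqrt((3 μa μs′ / 2)(sqrt(1 + (ω/(v μa))²) − 1)),
        with v the speed of light in the medium.
    """
    if mua <= 0 or musp <= 0:
        raise ValueError("mua and musp must be positive")
    v = config.speed_in_tissue
    ratio = config.omega / (v * mua)
    root = np.sqrt(1.0 + ratio * ratio)
    base = 1.5 * mua * musp
    return ComplexWavenumber(
        k_real=float(np.sqrt(base * (root + 1.0))),
        k_imag=float(np.sqrt(base * (root - 1.0))),
    )


def fdnirs_forward(
    mua: float,
    musp: float,
    config: InstrumentConfig,
    *,
    gain: float = 1.0,
    phase_offset: float = 0.0,
    ln_ac_noise_std: float = 0.0,
    phase_noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate FDNIRS amplitude/phase time series at every distance.

    Noise-free model: AC(ρ) = gain·exp(−k_real·ρ)/ρ² and
    phase(ρ) = k_imag·ρ + phase_offset.  Optional zero-mean Gaussian noise is
    added on ln(AC) and on phase, independently per time sample.

    Returns
    -------
    (ac, phase)
        Arrays of shape (n_distances, n_samples).
    """
    if ln_ac_noise_std < 0 or phase_noise_std < 0:
        raise ValueError("noise std must be nonnegative")
    if gain <= 0:
        raise ValueError("gain must be positive")
    k = dpdw_wavenumbers(mua, musp, config)
    rho = np.asarray(config.fdnirs_distances_cm, dtype=float)
    n = config.n_fdnirs_samples
    ln_ac0 = np.log(gain) - k.k_real * rho - 2.0 * np.log(rho)
    phase0 = k.k_imag * rho + phase_offset
    ln_ac = np.tile(ln_ac0[:, None], (1, n))
    phase = np.tile(phase0[:, None], (1, n))
    if ln_ac_noise_std > 0 or phase_noise_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        if ln_ac_noise_std > 0:
            ln_ac = ln_ac + rng.normal(0.0, ln_ac_noise_std, ln_ac.shape)
        if phase_noise_std > 0:
            phase = phase + rng.normal(0.0, phase_noise_std, phase.shape)
    return np.exp(ln_ac), phase


@dataclass(frozen=True)
class CorrelationModelParams:
    """Inputs of the semi-infinite correlation-diffusion solution.

    rho : source-detector separation, cm
    mua, musp : optical coefficients at the DCS wavelength, cm⁻¹
    k0 : wavenumber of light in the medium 2π·n/λ, cm⁻¹
    zb : extrapolated zero-boundary distance, cm
    cbfi : blood flow index, cm²/s
    beta : Siegert coherence factor
    """

    rho: float
    mua: float
    musp: float
    k0: float
    zb: float
    cbfi: float
    beta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("rho", "mua", "musp", "k0", "zb", "cbfi"):
            if getattr(self, name) < 0 or (name != "cbfi" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")

    @property
    def r1(self) -> float:
        """Distance from the detector to the isotropic source, cm."""
        return float(np.hypot(self.rho, 1.0 / self.musp))

    @property
    def rb(self) -> float:
        """Distance from the detector to the image source, cm."""
        return float(np.hypot(self.rho, 1.0 / self.musp + 2.0 * self.zb))


def extrapolated_boundary(musp: float, r_eff: float = R_EFF_N14) -> float:
    """Extrapolated zero-boundary distance zb = (2/(3 μs′))·(1+R_eff)/(1−R_eff)."""
    if musp <= 0:
        raise ValueError("musp must be positive")
    return (2.0 / (3.0 * musp)) * (1.0 + r_eff) / (1.0 - r_eff)


def light_wavenumber(wavelength_nm: float, refractive_index: float = 1.4) -> float:
    """Wavenumber of light in the medium, cm⁻¹: k0 = 2π·n/λ."""
    return 2.0 * np.pi * refractive_index / (wavelength_nm * 1e-7)


def correlation_params(
    mua: float,
    musp: float,
    cbfi: float,
    config: InstrumentConfig,
    beta: float = 0.5,
) -> CorrelationModelParams:
    """Assemble CorrelationModelParams from optical coefficients and geometry."""
    return CorrelationModelParams(
        rho=config.dcs_distance_cm,
        mua=mua,
        musp=musp,
        k0=light_wavenumber(config.dcs_wavelength_nm, config.refractive_index),
        zb=extrapolated_boundary(musp),
        cbfi=cbfi,
        beta=beta,
    )


def g1_semi_infinite(params: CorrelationModelParams, tau: np.ndarray | float) -> np.ndarray:
    """Normalized field autocorrelation g1(τ) for the semi-infinite medium.

    G1(ρ,τ) = (3 μs′ / 4π)·[exp(−K τ·r1)/r1 − exp(−K τ·rb)/rb] with decay
    rate K(τ) = sqrt(3 μa μs′ + 6 μs′² k0² CBFi τ); the returned value is
    G1(ρ,τ)/G1(ρ,0) so g1(0) = 1.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be nonnegative")
    k_tau = np.sqrt(
        3.0 * params.mua * params.musp
        + 6.0 * params.musp**2 * params.k0**2 * params.cbfi * tau_arr
    )
    r1, rb = params.r1, params.rb

    def unnormalized(k):
        return np.exp(-k * r1) / r1 - np.exp(-k * rb) / rb

    g0 = unnormalized(np.sqrt(3.0 * params.mua * params.musp))
    out = unnormalized(k_tau) / g0
    return out if out.shape else float(out)


def g2_model(params: CorrelationModelParams, tau: np.ndarray) -> np.ndarray:
    """Siegert relation: g2(τ) = 1 + β·g1(τ)²."""
    g1 = g1_semi_infinite(params, tau)
    return 1.0 + params.beta * np.asarray(g1) ** 2


def g2_forward(
    params: CorrelationModelParams,
    config: InstrumentConfig,
    n_curves: int | None = None,
    noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a set of intensity-autocorrelation curves on the τ grid.

    Each curve is 1 + β·g1(τ)² plus optional zero-mean Gaussian noise with
    per-bin standard deviation ``noise_std`` (flat across τ).  Returns an
    array of shape (n_curves, n_tau); defaults to the instrument's curve
    count per acquisition (rate × duration).
    """
    if n_curves is None:
        n_curves = config.n_dcs_curves
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    if noise_std < 0:
        raise ValueError("noise_std must be nonnegative")
    tau = config.tau_array()
    clean = g2_model(params, tau)
    curves = np.tile(clean, (n_curves, 1))
    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        curves = curves + rng.normal(0.0, noise_std, curves.shape)
    return curves
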