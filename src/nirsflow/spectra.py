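"""Spectral decomposition of the fitted optical coefficients.

The absorption spectrum μa(λ) is modelled as a water-corrected linear
mixture of oxy- and deoxy-hemoglobin,

    μa(λ) = ε_HbO(λ)·C_HbO + ε_HbR(λ)·C_HbR + f_water·μa_water(λ),

solved for the two concentrations by nonnegative least squares.  The
reduced scattering spectrum follows the Mie-derived power law
μs′(λ) = a·(λ/500 nm)^−b, fitted as a straight line in log-log space.
Both fits carry R² and F-test p-value diagnostics with the quality cuts
used downstream (discard when p > 0.03 or R² < 0.6), and both are
extrapolated to the 850 nm DCS wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

WATER_FRACTION_DEFAULT = 0.75
MIE_REFERENCE_NM = 500.0

#: Quality cuts for the two spectral fits.
SPECTRAL_P_MAX = 0.03
SPECTRAL_R2_MIN = 0.6


class SpectralFitError(ValueError):
    """Raised when a spectral fit has too few usable wavelengths."""


@dataclass(frozen=True)
class ExtinctionTable:
    """Chromophore extinction spectra on a fixed wavelength support.

    eps_hbo / eps_hbr are in cm⁻¹ per μM (natural-log base); mua_water is
    the pure-water absorption coefficient in cm⁻¹.
    """

    wavelengths_nm: np.ndarray
    eps_hbo: np.ndarray
    eps_hbr: np.ndarray
    mua_water: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("eps_hbo", "eps_hbr", "mua_water"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} entries must be nonnegative")

    def at(self, wavelengths_nm) -> "ExtinctionTable":
        """Restrict the table to the given wavelengths (must all be present)."""
        idx = []
        for w in np.atleast_1d(wavelengths_nm):
            hits = np.flatnonzero(np.isclose(self.wavelengths_nm, w))
            if hits.size == 0:
                raise KeyError(f"wavelength {w} nm not in extinction table")
            idx.append(hits[0])
        idx = np.asarray(idx)
        return ExtinctionTable(
            wavelengths_nm=self.wavelengths_nm[idx],
            eps_hbo=self.eps_hbo[idx],
            eps_hbr=self.eps_hbr[idx],
            mua_water=self.mua_water[idx],
            provenance=self.provenance,
        )

    def mua(self, hbo: float, hbr: float, water_fraction: float = WATER_FRACTION_DEFAULT) -> np.ndarray:
        """Forward absorption model on the table's wavelength support."""
        return self.eps_hbo * hbo + self.eps_hbr * hbr + water_fraction * self.mua_water


def load_extinction_table() -> ExtinctionTable:
    """Load the bundled extinction table (8 instrument wavelengths + 850 nm)."""
    with resources.files("nirsflow.data").joinpath("extinction_coefficients.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return ExtinctionTable(
        wavelengths_nm=df["wavelength_nm"].to_numpy(float),
        eps_hbo=df["eps_hbo"].to_numpy(float),
        eps_hbr=df["eps_hbr"].to_numpy(float),
        mua_water=df["mua_water"].to_numpy(float),
        provenance="bundled approximate literature compendium, v1",
    )


@dataclass
class ChromophoreFit:
    """Hemoglobin concentrations unmixed from an absorption spectrum."""

    hbo: float
    hbr: float
    fit_r2: float
    fit_pvalue: float
    qc_pass: bool = True

    @property
    def hbt(self) -> float:
        return self.hbo + self.hbr

    @property
    def so2(self) -> float:
        return self.hbo / self.hbt if self.hbt > 0 else float("nan")


@dataclass
class ScatteringModelFit:
    """Mie power-law parameters fitted to a reduced-scattering spectrum."""

    a_500: float
    b_power: float
    fit_r2: float
    fit_pvalue: float
    qc_pass: bool = True


def _regression_diagnostics(y: np.ndarray, fitted: np.ndarray, n_params: int) -> tuple[float, float]:
    """R² and F-test p-value of a least-squares fit with n_params parameters."""
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    if ss_tot <= 0:
        # flat response: define R²=1 and p=0 for an exact fit, else undefined
        return (1.0, 0.0) if ss_res < 1e-25 else (0.0, 1.0)
    r2 = 1.0 - ss_res / ss_tot
    df_num = n_params - 1
    df_den = n - n_params
    if df_den <= 0 or df_num <= 0:
        return r2, float("nan")
    if ss_res <= 0:
        return r2, 0.0
    f_stat = (ss_tot - ss_res) / df_num / (ss_res / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return r2, p


def fit_chromophores(
    mua: np.ndarray,
    wavelengths_nm: np.ndarray,
    table: ExtinctionTable,
    water_fraction: float = WATER_FRACTION_DEFAULT,
) -> ChromophoreFit:
    """Unmix HbO and HbR from μa(λ) by nonnegative least squares.

    The water contribution ``water_fraction * mua_water`` is subtracted
    first; the remaining spectrum is decomposed on the two hemoglobin
    extinction spectra with concentrations constrained nonnegative.
    """
    mua = np.asarray(mua, dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    ok = np.isfinite(mua)
    if ok.sum() < 2:
        raise SpectralFitError("need at least 2 usable wavelengths to unmix")
    sub = table.at(wavelengths_nm[ok])
    target = mua[ok] - water_fraction * sub.mua_water
    design = np.column_stack([sub.eps_hbo, sub.eps_hbr])
    conc, _ = optimize.nnls(design, target)
    fitted = design @ conc + water_fraction * sub.mua_water
    r2, p = _regression_diagnostics(mua[ok], fitted, n_params=2)
    return ChromophoreFit(hbo=float(conc[0]), hbr=float(conc[1]), fit_r2=r2, fit_pvalue=p)


def evaluate_mie(a_500: float, b_power: float, wavelength_nm: float | np.ndarray):
    """Mie power law μs′(λ) = a·(λ/500 nm)^−b, cm⁻¹."""
    if np.any(np.asarray(wavelength_nm) <= 0):
        raise ValueError("wavelength must be positive")
    return a_500 * (np.asarray(wavelength_nm, dtype=float) / MIE_REFERENCE_NM) ** (-b_power)


def fit_scattering_model(musp: np.ndarray, wavelengths_nm: np.ndarray) -> ScatteringModelFit:
    """Fit the Mie power law to μs′(λ) as a line in log-log space.

    ln μs′ regressed on ln(λ/500 nm): slope = −b, intercept = ln a.
    Non-positive μs′ values are excluded.  Diagnostics (R², F-test p) are
    computed on the original μs′ scale.
    """
    musp = np.asarray(musp, dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    ok = np.isfinite(musp) & (musp > 0)
    if ok.sum() < 2:
        raise SpectralFitError("need at least 2 positive musp values")
    x = np.log(wavelengths_nm[ok] / MIE_REFERENCE_NM)
    y = np.log(musp[ok])
    slope, intercept = np.polyfit(x, y, 1)
    a_500 = float(np.exp(intercept))
    b_power = float(-slope)
    fitted = evaluate_mie(a_500, b_power, wavelengths_nm[ok])
    r2, p = _regression_diagnostics(musp[ok], fitted, n_params=2)
    return ScatteringModelFit(a_500=a_500, b_power=b_power, fit_r2=r2, fit_pvalue=p)


def spectral_qc(
    fit_r2: float,
    fit_pvalue: float,
    p_max: float = SPECTRAL_P_MAX,
    r2_min: float = SPECTRAL_R2_MIN,
) -> bool:
    """Quality cut for spectral fits: keep iff p ≤ p_max and R² ≥ r2_min."""
    return bool(fit_pvalue <= p_max and fit_r2 >= r2_min)


def extrapolate_to_dcs(
    chromo: ChromophoreFit,
    scatter: ScatteringModelFit,
    table: ExtinctionTable,
    water_fraction: float = WATER_FRACTION_DEFAULT,
    dcs_wavelength_nm: float = 850.0,
) -> tuple[float, float]:
    """Extrapolate μa and μs′ to the DCS wavelength from the two spectral fits.

    Returns (mua_850, musp_850) in cm⁻¹.
    """
    sub = table.at([dcs_wavelength_nm])
    mua = float(sub.eps_hbo[0] * chromo.hbo + sub.eps_hbr[0] * chromo.hbr
                + water_fraction * sub.mua_water[0])
    musp = float(evaluate_mie(scatter.a_500, scatter.b_power, dcs_wavelength_nm))
    return mua, musp
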