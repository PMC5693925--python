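"""Synthetic neonatal cohort generator.

Emulates the measurement campaign of a hybrid FDNIRS-DCS study on healthy
term newborns: a 30-infant cohort (19 male / 11 female by default), seven
cortical sites (left/middle/right frontal, left/right temporal and
parietal), several probe repositionings per site, and for every placement
a raw multi-distance amplitude/phase acquisition plus a set of intensity
autocorrelation curves generated from the closed-form diffusion models.

The generator draws a ground-truth :class:`~nirsflow.forward.TissueState`
per subject × site × repetition around configurable population baselines,
with three layers of structure:

* demographic effects — a multiplicative male/female ratio on HbT, SO2 and
  CBFi (split symmetrically so the cohort mean stays at baseline), and
  additive per-week gestational-age slopes on HbT and SO2;
* a multiplicative right/left hemisphere ratio on CBFi (again split
  symmetrically; midline sites unaffected);
* biological variability — mean-one log-normal subject and site draws for
  the strictly positive quantities (HbT, CBFi, a) and logit-normal draws
  for SO2, keeping every invariant satisfiable.

Ground truth is retained alongside the raw tables so every pipeline stage
can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .forward import (
    InstrumentConfig,
    TissueState,
    correlation_params,
    fdnirs_forward,
    g2_forward,
)
from .spectra import evaluate_mie, load_extinction_table

LOCATIONS = (
    "frontal_left", "frontal_mid", "frontal_right",
    "temporal_left", "temporal_right",
    "parietal_left", "parietal_right",
)


class BaselineState(BaseModel):
    """Population-mean tissue parameters the cohort is drawn around."""

    hbt_um: float = 54.0
    so2: float = 0.66
    cbfi_cm2s: float = 2.1e-8
    a_500: float = 13.7
    b_power: float = 1.43
    beta: float = 0.5
    water_fraction: float = 0.75


class SexEffects(BaseModel):
    """Male/female multiplicative ratios (1.0 = no dimorphism)."""

    hbt: float = Field(default=1.10, gt=0)
    so2: float = Field(default=1.05, gt=0)
    cbfi: float = Field(default=0.90, gt=0)


class GASlopes(BaseModel):
    """Additive change per gestational week, centred on the cohort mean GA.

    Defaults reproduce a subject-level Pearson correlation of about 0.49
    between gestational age and HbT/SO2 at the default between-subject
    dispersion and a GA standard deviation of 1.2 weeks.
    """

    hbt_um_per_week: float = 7.0
    so2_per_week: float = 0.06


class VariabilityConfig(BaseModel):
    """Between-subject and between-site (repositioning) dispersion.

    Log-scale standard deviations for the positive quantities, logit-scale
    for SO2, plain additive for the scattering power b.
    """

    subject_log_hbt: float = 0.28
    subject_logit_so2: float = 0.60
    subject_log_cbfi: float = 0.32
    subject_log_a: float = 0.24
    subject_b_sd: float = 0.40
    site_log_hbt: float = 0.10
    site_logit_so2: float = 0.25
    site_log_cbfi: float = 0.15
    site_log_a: float = 0.08
    site_b_sd: float = 0.10


class NoiseConfig(BaseModel):
    """Instrument noise levels injected into the raw channels."""

    fdnirs_ln_amplitude: float = Field(default=0.01, ge=0)
    fdnirs_phase_rad: float = Field(default=0.02, ge=0)
    dcs_g2: float = Field(default=0.005, ge=0)


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort run (JSON-serializable)."""

    n_male: int = Field(default=19, ge=0)
    n_female: int = Field(default=11, ge=0)
    ga_mean_weeks: float = 39.2
    ga_sd_weeks: float = 1.2
    ga_range_weeks: tuple[float, float] = (37.0, 42.0)
    postnatal_age_mean_days: float = 2.4
    postnatal_age_sd_days: float = 1.1
    locations: tuple[str, ...] = LOCATIONS
    repetitions_per_site: int = Field(default=3, ge=1)
    baseline: BaselineState = BaselineState()
    sex_effects: SexEffects = SexEffects()
    hemisphere_effect_cbfi: float = Field(default=1.152, gt=0)
    ga_slopes: GASlopes = GASlopes()
    variability: VariabilityConfig = VariabilityConfig()
    noise: NoiseConfig = NoiseConfig()
    sao2_range: tuple[float, float] = (0.95, 0.99)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.n_male + self.n_female < 1:
            raise ValueError("cohort must contain at least one subject")
        return self

    def null_effects(self) -> "CohortConfig":
        """Copy with all demographic/hemisphere effects switched off."""
        return self.model_copy(update={
            "sex_effects": SexEffects(hbt=1.0, so2=1.0, cbfi=1.0),
            "hemisphere_effect_cbfi": 1.0,
            "ga_slopes": GASlopes(hbt_um_per_week=0.0, so2_per_week=0.0),
        })


@dataclass
class RawCohort:
    """Synthetic cohort: subject table, per-measurement ground truth, raw data.

    ``fdnirs_ac``/``fdnirs_phase`` have shape (n_meas, n_wavelengths,
    n_distances, n_samples); ``dcs_curves`` has shape (n_meas, n_curves,
    n_tau).  Row ``i`` of ``measurements`` labels slice ``i`` of each raw
    array.  The raw arrays are ``None`` when generated truth-only.
    """

    subjects: pd.DataFrame
    measurements: pd.DataFrame
    fdnirs_ac: np.ndarray | None
    fdnirs_phase: np.ndarray | None
    dcs_curves: np.ndarray | None
    config: CohortConfig
    instrument: InstrumentConfig


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, low, high)


def _lognormal_mean_one(rng, sigma, size=None):
    """exp(σz − σ²/2): multiplicative noise with unit expectation."""
    if sigma == 0:
        return np.ones(size) if size else 1.0
    return np.exp(rng.normal(0.0, sigma, size) - 0.5 * sigma**2)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the demographic table: ids, sex, GA, postnatal age, SaO2."""
    n = config.n_male + config.n_female
    sexes = ["M"] * config.n_male + ["F"] * config.n_female
    ga = _truncated_normal(rng, config.ga_mean_weeks, config.ga_sd_weeks,
                           *config.ga_range_weeks, size=n)
    age = _truncated_normal(rng, config.postnatal_age_mean_days,
                            config.postnatal_age_sd_days, 0.5, 7.0, size=n)
    sao2 = rng.uniform(*config.sao2_range, size=n)
    return pd.DataFrame({
        "subject_id": [f"S{i+1:03d}" for i in range(n)],
        "sex": sexes,
        "ga_weeks": ga,
        "postnatal_age_days": age,
        "sao2_frac": sao2,
        "hgb_g_dl": [np.nan] * n,
    })


def _draw_truth(config: CohortConfig, subjects: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth TissueState per subject × location × repetition."""
    base = config.baseline
    eff = config.sex_effects
    hemi = np.sqrt(config.hemisphere_effect_cbfi)
    rows = []
    for _, subj in subjects.iterrows():
        is_male = subj["sex"] == "M"
        sex_sign = 0.5 if is_male else -0.5
        d_ga = subj["ga_weeks"] - config.ga_mean_weeks
        v = config.variability
        subj_hbt = (base.hbt_um + config.ga_slopes.hbt_um_per_week * d_ga) \
            * eff.hbt ** sex_sign * _lognormal_mean_one(rng, v.subject_log_hbt)
        subj_so2_center = np.clip(
            base.so2 * eff.so2 ** sex_sign + config.ga_slopes.so2_per_week * d_ga,
            0.02, 0.98)
        subj_so2 = _expit(_logit(subj_so2_center) + (
            rng.normal(0.0, v.subject_logit_so2) if v.subject_logit_so2 > 0 else 0.0))
        subj_cbfi = base.cbfi_cm2s * eff.cbfi ** sex_sign \
            * _lognormal_mean_one(rng, v.subject_log_cbfi)
        subj_a = base.a_500 * _lognormal_mean_one(rng, v.subject_log_a)
        subj_b = max(base.b_power + (rng.normal(0.0, v.subject_b_sd)
                                     if v.subject_b_sd > 0 else 0.0), 0.2)
        for loc in config.locations:
            side = loc.rsplit("_", 1)[1]
            side_factor = hemi if side == "right" else (1.0 / hemi if side == "left" else 1.0)
            for rep in range(1, config.repetitions_per_site + 1):
                hbt = subj_hbt * _lognormal_mean_one(rng, v.site_log_hbt)
                so2 = _expit(_logit(np.clip(subj_so2, 0.02, 0.98)) + (
                    rng.normal(0.0, v.site_logit_so2) if v.site_logit_so2 > 0 else 0.0))
                cbfi = subj_cbfi * side_factor * _lognormal_mean_one(rng, v.site_log_cbfi)
                a500 = subj_a * _lognormal_mean_one(rng, v.site_log_a)
                b = max(subj_b + (rng.normal(0.0, v.site_b_sd)
                                  if v.site_b_sd > 0 else 0.0), 0.2)
                rows.append({
                    "subject_id": subj["subject_id"],
                    "location": loc,
                    "repetition": rep,
                    "hbo_um": so2 * hbt,
                    "hbr_um": (1.0 - so2) * hbt,
                    "hbt_um": hbt,
                    "so2_frac": so2,
                    "a_500": a500,
                    "b_power": b,
                    "cbfi_cm2s": cbfi,
                    "beta": base.beta,
                    "sao2_frac": subj["sao2_frac"],
                    "water_frac": base.water_fraction,
                })
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig,
    instrument: InstrumentConfig | None = None,
    emit_raw: bool = True,
) -> RawCohort:
    """Generate a full synthetic cohort.

    With ``emit_raw`` the raw FDNIRS amplitude/phase time series and DCS
    g2 curves are synthesized from the forward models (μa(λ) from the
    extinction table, μs′(λ) from the Mie power law, g2 from the
    correlation-diffusion solution), with the configured instrument noise.
    Truth-only generation (``emit_raw=False``) is much faster and serves
    statistical simulations that start from fitted-level records.

    All randomness flows from ``config.seed``; reruns are bit-identical.
    """
    if instrument is None:
        instrument = InstrumentConfig()
    rng = np.random.default_rng(config.seed)
    subjects = simulate_subjects(config, rng)
    truth = _draw_truth(config, subjects, rng)
    if not emit_raw:
        return RawCohort(subjects, truth, None, None, None, config, instrument)

    table = load_extinction_table()
    wavelengths = np.asarray(instrument.fdnirs_wavelengths_nm)
    sub_table = table.at(wavelengths)
    dcs_table = table.at([instrument.dcs_wavelength_nm])
    n_meas = len(truth)
    n_wl, n_dist = wavelengths.size, len(instrument.fdnirs_distances_cm)
    n_samp = instrument.n_fdnirs_samples
    n_curves = instrument.n_dcs_curves
    n_tau = instrument.tau_array().size
    ac_all = np.empty((n_meas, n_wl, n_dist, n_samp))
    ph_all = np.empty((n_meas, n_wl, n_dist, n_samp))
    g2_all = np.empty((n_meas, n_curves, n_tau))
    noise = config.noise
    for i, row in enumerate(truth.itertuples(index=False)):
        mua_lam = sub_table.mua(row.hbo_um, row.hbr_um, row.water_frac)
        musp_lam = evaluate_mie(row.a_500, row.b_power, wavelengths)
        for j in range(n_wl):
            ac, ph = fdnirs_forward(
                float(mua_lam[j]), float(musp_lam[j]), instrument,
                ln_ac_noise_std=noise.fdnirs_ln_amplitude,
                phase_noise_std=noise.fdnirs_phase_rad, rng=rng,
            )
            ac_all[i, j], ph_all[i, j] = ac, ph
        mua850 = float(dcs_table.mua(row.hbo_um, row.hbr_um, row.water_frac)[0])
        musp850 = float(evaluate_mie(row.a_500, row.b_power, instrument.dcs_wavelength_nm))
        params = correlation_params(mua850, musp850, row.cbfi_cm2s, instrument,
                                    beta=row.beta)
        g2_all[i] = g2_forward(params, instrument, n_curves=n_curves,
                               noise_std=noise.dcs_g2, rng=rng)
    return RawCohort(subjects, truth, ac_all, ph_all, g2_all, config, instrument)


def tissue_state_from_row(row) -> TissueState:
    """Reconstruct the TissueState dataclass from a truth-table row."""
    return TissueState(
        hbo=row["hbo_um"], hbr=row["hbr_um"], a_500=row["a_500"],
        b_power=row["b_power"], cbfi=row["cbfi_cm2s"], beta=row["beta"],
        sao2=row["sao2_frac"], water_fraction=row["water_frac"],
    )


def simulate_phantom(
    known_mua: np.ndarray,
    known_musp: np.ndarray,
    instrument: InstrumentConfig,
    amplitude_distortion: np.ndarray | None = None,
    phase_distortion: np.ndarray | None = None,
    ln_ac_noise_std: float = 0.0,
    phase_noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a solid-phantom calibration run.

    ``amplitude_distortion``/``phase_distortion`` are per-channel
    (n_wavelengths, n_distances) instrument imperfections: the emitted AC
    is multiplied by the former and the emitted phase shifted by the
    latter.  ``calibrate`` recovers their inverses (gain = 1/distortion,
    offset = +distortion) so that calibrated data match the diffusion
    model.  Returns (ac, phase) of shape (n_wl, n_dist, n_samples).
    """
    wavelengths = np.asarray(instrument.fdnirs_wavelengths_nm)
    n_wl, n_dist = wavelengths.size, len(instrument.fdnirs_distances_cm)
    known_mua = np.asarray(known_mua, dtype=float)
    known_musp = np.asarray(known_musp, dtype=float)
    if known_mua.size != n_wl or known_musp.size != n_wl:
        raise ValueError("need one known mua and musp per instrument wavelength")
    if amplitude_distortion is None:
        amplitude_distortion = np.ones((n_wl, n_dist))
    if phase_distortion is None:
        phase_distortion = np.zeros((n_wl, n_dist))
    amplitude_distortion = np.asarray(amplitude_distortion, dtype=float)
    phase_distortion = np.asarray(phase_distortion, dtype=float)
    if amplitude_distortion.shape != (n_wl, n_dist) or phase_distortion.shape != (n_wl, n_dist):
        raise ValueError("distortion arrays must be (n_wavelengths, n_distances)")
    n_samp = instrument.n_fdnirs_samples
    ac_out = np.empty((n_wl, n_dist, n_samp))
    ph_out = np.empty((n_wl, n_dist, n_samp))
    for i in range(n_wl):
        ac, ph = fdnirs_forward(
            float(known_mua[i]), float(known_musp[i]), instrument,
            ln_ac_noise_std=ln_ac_noise_std, phase_noise_std=phase_noise_std,
            rng=rng,
        )
        ac_out[i] = ac * amplitude_distortion[i][:, None]
        ph_out[i] = ph + phase_distortion[i][:, None]
    return ac_out, ph_out


def apply_distortions(raw: RawCohort, amplitude_distortion: np.ndarray,
                      phase_distortion: np.ndarray) -> RawCohort:
    """Return a copy of the cohort with per-channel instrument distortions
    applied to the raw FDNIRS arrays (for exercising calibration)."""
    if raw.fdnirs_ac is None:
        raise ValueError("cohort has no raw data")
    ac = raw.fdnirs_ac * amplitude_distortion[None, :, :, None]
    ph = raw.fdnirs_phase + phase_distortion[None, :, :, None]
    return RawCohort(raw.subjects, raw.measurements, ac, ph, raw.dcs_curves,
                     raw.config, raw.instrument)
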