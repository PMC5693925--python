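"""End-to-end orchestration: simulate → calibrate → fit → derive → stats.

`fit_cohort` runs every measurement of a (synthetic or file-loaded)
cohort through the full inversion chain — phantom calibration, temporal
medians, multi-distance slope fits, chromophore unmixing, Mie scattering
fit, extrapolation to 850 nm, correlation-diffusion CBFi fit and the
derived hemodynamics — and returns one results row per measurement with
all QC flags.  `run_stats` then produces the group-level report:
mixed-model sex contrasts (overall and per lobe), gestational-age trends,
Pearson correlations, demographic t-tests and the hemispheric percent
differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as nio
from .cohort import CohortConfig, RawCohort, simulate_cohort, simulate_phantom
from .dcs import DCSMeasurement, average_curves, fit_cbfi
from .fdnirs import (
    PHASE_NOISE_MAX_RAD,
    SLOPE_R2_MIN,
    CalibrationFactors,
    calibrate,
    identity_calibration,
    invert_measurement,
)
from .forward import InstrumentConfig
from .hemodynamics import GAMMA_DEFAULT, KAPPA_O2_PER_G_HGB, derive_hemodynamics
from .spectra import (
    SPECTRAL_P_MAX,
    SPECTRAL_R2_MIN,
    SpectralFitError,
    extrapolate_to_dcs,
    fit_chromophores,
    fit_scattering_model,
    load_extinction_table,
    spectral_qc,
)
from .stats import (
    HEMODYNAMIC_PARAMS,
    aggregate_repetitions,
    demographics_ttest,
    lme_ga_trend,
    lme_sex_contrast,
    pearson_ga,
    percent_side_difference,
)

logger = logging.getLogger("nirsflow")

#: Fixed cohort-average reduced scattering at the DCS wavelength, cm⁻¹,
#: used in the flow fit unless per-measurement μs′ is requested.
FIXED_MUSP_850 = 6.4


class QCThresholds(BaseModel):
    phase_noise_max_rad: float = PHASE_NOISE_MAX_RAD
    slope_r2_min: float = SLOPE_R2_MIN
    spectral_p_max: float = SPECTRAL_P_MAX
    spectral_r2_min: float = SPECTRAL_R2_MIN
    min_usable_wavelengths: int = 2


class RunConfig(BaseModel):
    """Single JSON document controlling an end-to-end run."""

    cohort: CohortConfig = CohortConfig()
    thresholds: QCThresholds = QCThresholds()
    water_fraction: float = Field(default=0.75, ge=0, le=1)
    gamma: float = Field(default=GAMMA_DEFAULT, gt=0, le=1)
    kappa: float = KAPPA_O2_PER_G_HGB
    fixed_musp_850: float | None = FIXED_MUSP_850  # None => per-measurement μs′
    seed: int | None = None  # overrides cohort.seed when set

    def instrument(self) -> InstrumentConfig:
        return InstrumentConfig()


def calibrate_from_phantom(
    instrument: InstrumentConfig,
    known_mua: np.ndarray | None = None,
    known_musp: np.ndarray | None = None,
) -> CalibrationFactors:
    """Simulate a solid-phantom run and derive calibration factors.

    Defaults to a typical epoxy phantom (flat μa = 0.1 cm⁻¹,
    μs′ = 10 cm⁻¹ at every wavelength).
    """
    n_wl = len(instrument.fdnirs_wavelengths_nm)
    if known_mua is None:
        known_mua = np.full(n_wl, 0.1)
    if known_musp is None:
        known_musp = np.full(n_wl, 10.0)
    ac, phase = simulate_phantom(known_mua, known_musp, instrument)
    return calibrate(ac, phase, known_mua, known_musp, instrument)


def fit_cohort(
    raw: RawCohort,
    calibration: CalibrationFactors | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Run the full inversion chain on every measurement of a cohort.

    Returns the results table (one row per subject × location ×
    repetition) with per-wavelength optical coefficients, spectral fits,
    CBFi, derived hemodynamics and QC flags.  Every QC rejection is
    logged with the measurement id, rule and offending value.
    """
    if raw.fdnirs_ac is None:
        raise ValueError("cohort carries no raw data (generated truth-only?)")
    if config is None:
        config = RunConfig()
    thr = config.thresholds
    instrument = raw.instrument
    if calibration is None:
        calibration = identity_calibration(instrument)
    table = load_extinction_table()
    wavelengths = np.asarray(instrument.fdnirs_wavelengths_nm)
    sao2_by_subject = raw.subjects.set_index("subject_id")["sao2_frac"]
    hgb_by_subject = raw.subjects.set_index("subject_id")["hgb_g_dl"]

    rows = []
    for i, meas in enumerate(raw.measurements.itertuples(index=False)):
        meas_id = f"{meas.subject_id}/{meas.location}/r{meas.repetition}"
        row: dict = {
            "subject_id": meas.subject_id,
            "location": meas.location,
            "repetition": meas.repetition,
        }
        spectrum = invert_measurement(
            raw.fdnirs_ac[i], raw.fdnirs_phase[i], calibration, instrument,
            phase_noise_max=thr.phase_noise_max_rad, r2_min=thr.slope_r2_min,
        )
        for j, wl in enumerate(wavelengths):
            row[f"mua_{int(wl)}"] = spectrum.mua[j]
            row[f"musp_{int(wl)}"] = spectrum.musp[j]
        usable = spectrum.qc_pass
        qc_fdnirs = bool(usable.sum() >= thr.min_usable_wavelengths)
        if not qc_fdnirs:
            worst = max(f.phase_noise for f in spectrum.slope_fits)
            logger.info("QC reject %s: fdnirs usable wavelengths=%d (worst phase "
                        "noise %.3f rad)", meas_id, usable.sum(), worst)
        row["qc_fdnirs"] = qc_fdnirs

        qc_spectral = False
        chromo = scatter = None
        mua850 = musp850 = np.nan
        if qc_fdnirs:
            try:
                chromo = fit_chromophores(spectrum.mua[usable], wavelengths[usable],
                                          table, config.water_fraction)
                scatter = fit_scattering_model(spectrum.musp[usable], wavelengths[usable])
            except SpectralFitError as err:
                logger.info("QC reject %s: spectral fit failed (%s)", meas_id, err)
            else:
                ok_c = spectral_qc(chromo.fit_r2, chromo.fit_pvalue,
                                   thr.spectral_p_max, thr.spectral_r2_min)
                ok_s = spectral_qc(scatter.fit_r2, scatter.fit_pvalue,
                                   thr.spectral_p_max, thr.spectral_r2_min)
                chromo.qc_pass, scatter.qc_pass = ok_c, ok_s
                qc_spectral = ok_c and ok_s
                if not qc_spectral:
                    logger.info(
                        "QC reject %s: spectral fit quality (chromo R2=%.3f p=%.3g; "
                        "Mie R2=%.3f p=%.3g)", meas_id, chromo.fit_r2,
                        chromo.fit_pvalue, scatter.fit_r2, scatter.fit_pvalue)
                mua850, musp850 = extrapolate_to_dcs(chromo, scatter, table,
                                                     config.water_fraction,
                                                     instrument.dcs_wavelength_nm)
        row.update({
            "a_500": scatter.a_500 if scatter else np.nan,
            "b_power": scatter.b_power if scatter else np.nan,
            "hbo_um": chromo.hbo if chromo else np.nan,
            "hbr_um": chromo.hbr if chromo else np.nan,
            "hbt_um": chromo.hbt if chromo else np.nan,
            "so2_frac": chromo.so2 if chromo else np.nan,
            "mua850": mua850,
            "musp850": musp850,
            "qc_spectral": qc_spectral,
        })

        qc_dcs = False
        cbfi = beta = np.nan
        if qc_spectral:
            musp_for_fit = config.fixed_musp_850 if config.fixed_musp_850 else musp850
            mean_g2 = average_curves(DCSMeasurement(
                tau_s=instrument.tau_array(), curves=raw.dcs_curves[i],
                rho_cm=instrument.dcs_distance_cm))
            dcs_fit = fit_cbfi(mean_g2, mua850, musp_for_fit, instrument)
            cbfi, beta = dcs_fit.cbfi, dcs_fit.beta
            qc_dcs = bool(dcs_fit.converged and not dcs_fit.degenerate)
            if not qc_dcs:
                logger.info("QC reject %s: DCS fit (converged=%s degenerate=%s)",
                            meas_id, dcs_fit.converged, dcs_fit.degenerate)
        row.update({"cbfi_cm2s": cbfi, "beta": beta, "qc_dcs": qc_dcs})

        sao2 = float(sao2_by_subject[meas.subject_id])
        hgb = hgb_by_subject[meas.subject_id]
        if qc_spectral and np.isfinite(cbfi):
            hemo = derive_hemodynamics(
                row["hbt_um"], row["so2_frac"], cbfi, sao2,
                subject_id=meas.subject_id, location=meas.location,
                repetition=meas.repetition, gamma=config.gamma,
                kappa=config.kappa,
                hgb_g_dl=None if pd.isna(hgb) else float(hgb),
            )
            row.update({"oef": hemo.oef, "cmro2i": hemo.cmro2i,
                        "sao2_frac": sao2})
        else:
            row.update({"oef": np.nan, "cmro2i": np.nan, "sao2_frac": sao2})
        row["qc_pass"] = qc_fdnirs and qc_spectral and qc_dcs
        rows.append(row)
    return pd.DataFrame(rows)


def run_stats(results: pd.DataFrame, subjects: pd.DataFrame) -> dict:
    """Group-level report on a results table.

    Aggregates repetitions by median, then computes mixed-model sex
    contrasts (all locations and per lobe), GA trends and Pearson
    correlations for HbT/SO2, hemispheric percent differences for CBFi
    and CMRO2i, and demographic t-tests.
    """
    agg = aggregate_repetitions(results)
    report: dict = {"n_records": int(len(results)),
                    "n_qc_passed": int(results.get("qc_pass", True).sum()
                                       if "qc_pass" in results else len(results)),
                    "sex_contrasts": {}, "ga": {}, "hemisphere": {},
                    "demographics": {}}
    lobes = sorted({loc.rsplit("_", 1)[0] for loc in agg["location"].unique()})
    for param in HEMODYNAMIC_PARAMS:
        if param not in agg.columns or agg[param].dropna().empty:
            continue
        entry = {}
        for scope in ["all"] + lobes:
            try:
                res = lme_sex_contrast(agg, subjects, param,
                                       lobe=None if scope == "all" else scope)
                entry[scope] = asdict(res)
            except Exception as err:  # degenerate subsets are reported, not fatal
                entry[scope] = {"error": str(err)}
        report["sex_contrasts"][param] = entry
    for param in ("hbt_um", "so2_frac"):
        if param not in agg.columns:
            continue
        try:
            trend = lme_ga_trend(agg, subjects, param)
            r, p = pearson_ga(agg, subjects, param)
            report["ga"][param] = {"lme": asdict(trend),
                                   "pearson_r": r, "pearson_p": p}
        except Exception as err:
            report["ga"][param] = {"error": str(err)}
    for param in ("cbfi_cm2s", "cmro2i"):
        if param not in agg.columns:
            continue
        try:
            report["hemisphere"][param] = {
                "percent_right_vs_left": percent_side_difference(agg, param)}
        except Exception as err:
            report["hemisphere"][param] = {"error": str(err)}
    for field in ("ga_weeks", "postnatal_age_days"):
        if field in subjects.columns:
            try:
                report["demographics"][field] = asdict(demographics_ttest(subjects, field))
            except Exception as err:
                report["demographics"][field] = {"error": str(err)}
    return report


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full synthetic run: simulate, calibrate, fit, derive, stats.

    Returns a dict with the cohort, results table and stats report;
    optionally writes subjects/results CSVs and the stats JSON to
    ``out_dir``.  Deterministic for a fixed seed.
    """
    cohort_cfg = config.cohort
    if config.seed is not None:
        cohort_cfg = cohort_cfg.model_copy(update={"seed": config.seed})
    instrument = config.instrument()
    logger.info("simulating cohort: %d subjects, %d sites, %d repetitions",
                cohort_cfg.n_male + cohort_cfg.n_female,
                len(cohort_cfg.locations), cohort_cfg.repetitions_per_site)
    raw = simulate_cohort(cohort_cfg, instrument)
    calibration = calibrate_from_phantom(instrument)
    logger.info("fitting %d measurements", len(raw.measurements))
    results = fit_cohort(raw, calibration, config)
    stats_report = run_stats(results, raw.subjects)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nio.write_table(raw.subjects, out / "subjects.csv")
        nio.write_table(results, out / "results.csv")
        (out / "stats.json").write_text(json.dumps(stats_report, indent=2,
                                                   default=float))
        logger.info("wrote subjects.csv, results.csv, stats.json to %s", out)
    return {"raw": raw, "results": results, "stats": stats_report}
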