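"""CSV schemas and (de)serialization for the pipeline's tables.

Raw diffuse-optical data has no community file standard, so the pipeline
fixes four plain CSV schemas (headers normative, units encoded in the
column names: cm, cm⁻¹, μM, fractions in [0,1], radians, cm²/s):

``fdnirs.csv``
    subject_id, location, repetition, wavelength_nm, rho_cm, sample_index,
    ac_amplitude, phase_rad
``dcs.csv``
    subject_id, location, repetition, curve_index, tau_s, g2
``subjects.csv``
    subject_id, sex, ga_weeks, postnatal_age_days, sao2_frac, hgb_g_dl
``results.csv``
    one row per subject × location × repetition with per-wavelength
    μa/μs′ wide columns plus the fitted spectral, flow and metabolic
    quantities and QC flags.

Reading validates required columns and numeric fields, reporting
offending rows by line number; unknown columns are preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("nirsflow")

FDNIRS_COLUMNS = ("subject_id", "location", "repetition", "wavelength_nm",
                  "rho_cm", "sample_index", "ac_amplitude", "phase_rad")
DCS_COLUMNS = ("subject_id", "location", "repetition", "curve_index", "tau_s", "g2")
SUBJECTS_COLUMNS = ("subject_id", "sex", "ga_weeks", "postnatal_age_days",
                    "sao2_frac", "hgb_g_dl")

_NUMERIC = {
    "fdnirs": ("wavelength_nm", "rho_cm", "sample_index", "ac_amplitude", "phase_rad"),
    "dcs": ("curve_index", "tau_s", "g2"),
    "subjects": ("ga_weeks", "postnatal_age_days", "sao2_frac", "hgb_g_dl"),
}

SCHEMAS = {
    "fdnirs": FDNIRS_COLUMNS,
    "dcs": DCS_COLUMNS,
    "subjects": SUBJECTS_COLUMNS,
}


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def _validate(df: pd.DataFrame, schema: str, path: str = "<memory>") -> pd.DataFrame:
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_lines: list[int] = []
    for col in _NUMERIC[schema]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = df[col].notna() & coerced.isna()
        if newly_bad.any():
            # +2: header line plus 1-based counting
            bad_lines.extend((df.index[newly_bad] + 2).tolist())
        df[col] = coerced
    if bad_lines:
        raise SchemaError(
            f"{path}: non-numeric values at line(s) {sorted(set(bad_lines))[:20]}"
        )
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the pipeline CSVs ('fdnirs', 'dcs', 'subjects')."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s is empty", path)
        return pd.DataFrame(columns=SCHEMAS[schema])
    return _validate(df, schema, str(path))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long-form tables <-> the dense measurement arrays used internally

def fdnirs_to_table(measurements: pd.DataFrame, ac: np.ndarray, phase: np.ndarray,
                    instrument) -> pd.DataFrame:
    """Flatten (n_meas, n_wl, n_dist, n_samples) raw arrays to the long schema."""
    n_meas, n_wl, n_dist, n_samp = ac.shape
    wl = np.asarray(instrument.fdnirs_wavelengths_nm)
    rho = np.asarray(instrument.fdnirs_distances_cm)
    meta = measurements[["subject_id", "location", "repetition"]]
    per_meas = n_wl * n_dist * n_samp
    return pd.DataFrame({
        "subject_id": np.repeat(meta["subject_id"].to_numpy(), per_meas),
        "location": np.repeat(meta["location"].to_numpy(), per_meas),
        "repetition": np.repeat(meta["repetition"].to_numpy(), per_meas),
        "wavelength_nm": np.tile(np.repeat(wl, n_dist * n_samp), n_meas),
        "rho_cm": np.tile(np.repeat(rho, n_samp), n_meas * n_wl),
        "sample_index": np.tile(np.arange(n_samp), n_meas * n_wl * n_dist),
        "ac_amplitude": ac.ravel(),
        "phase_rad": phase.ravel(),
    })


def dcs_to_table(measurements: pd.DataFrame, curves: np.ndarray, instrument) -> pd.DataFrame:
    """Flatten (n_meas, n_curves, n_tau) g2 arrays to the long schema."""
    n_meas, n_curves, n_tau = curves.shape
    tau = instrument.tau_array()
    meta = measurements[["subject_id", "location", "repetition"]]
    per_meas = n_curves * n_tau
    return pd.DataFrame({
        "subject_id": np.repeat(meta["subject_id"].to_numpy(), per_meas),
        "location": np.repeat(meta["location"].to_numpy(), per_meas),
        "repetition": np.repeat(meta["repetition"].to_numpy(), per_meas),
        "curve_index": np.tile(np.repeat(np.arange(n_curves), n_tau), n_meas),
        "tau_s": np.tile(tau, n_meas * n_curves),
        "g2": curves.ravel(),
    })


def table_to_fdnirs_arrays(df: pd.DataFrame, instrument) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Inverse of :func:`fdnirs_to_table`.

    Returns (measurements index, ac, phase) with arrays shaped
    (n_meas, n_wl, n_dist, n_samples); assumes a complete grid per
    measurement, sorted as written.
    """
    wl = np.asarray(instrument.fdnirs_wavelengths_nm)
    rho = np.asarray(instrument.fdnirs_distances_cm)
    n_samp = int(df["sample_index"].max()) + 1
    keys = df[["subject_id", "location", "repetition"]].drop_duplicates().reset_index(drop=True)
    n_meas = len(keys)
    expected = n_meas * wl.size * rho.size * n_samp
    if len(df) != expected:
        raise SchemaError(
            f"fdnirs table has {len(df)} rows; expected a complete "
            f"{n_meas}x{wl.size}x{rho.size}x{n_samp} grid ({expected})")
    df = df.sort_values(["subject_id", "location", "repetition", "wavelength_nm",
                         "rho_cm", "sample_index"], kind="stable")
    keys = df[["subject_id", "location", "repetition"]].drop_duplicates().reset_index(drop=True)
    shape = (n_meas, wl.size, rho.size, n_samp)
    return keys, df["ac_amplitude"].to_numpy().reshape(shape), \
        df["phase_rad"].to_numpy().reshape(shape)


def table_to_dcs_arrays(df: pd.DataFrame, instrument) -> tuple[pd.DataFrame, np.ndarray]:
    """Inverse of :func:`dcs_to_table`."""
    tau = instrument.tau_array()
    n_curves = int(df["curve_index"].max()) + 1
    keys = df[["subject_id", "location", "repetition"]].drop_duplicates().reset_index(drop=True)
    n_meas = len(keys)
    expected = n_meas * n_curves * tau.size
    if len(df) != expected:
        raise SchemaError(
            f"dcs table has {len(df)} rows; expected a complete "
            f"{n_meas}x{n_curves}x{tau.size} grid ({expected})")
    df = df.sort_values(["subject_id", "location", "repetition", "curve_index", "tau_s"],
                        kind="stable")
    keys = df[["subject_id", "location", "repetition"]].drop_duplicates().reset_index(drop=True)
    return keys, df["g2"].to_numpy().reshape(n_meas, n_curves, tau.size)
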