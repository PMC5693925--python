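"""Derived hemodynamic quantities combining FDNIRS and DCS outputs.

The optically measured tissue saturation SO2 mixes arterial and venous
blood, SO2 = (1−γ)·SaO2 + γ·SvO2, with γ the venous fraction of the
optical signal.  From tissue and arterial saturation the oxygen
extraction fraction is OEF = (SaO2 − SO2)/(γ·SaO2), and an index of
cerebral oxygen metabolism is CMRO2i = CBFi·(SaO2 − SO2) via Fick's law.
With a blood hemoglobin concentration HGB (g/dL) the absolute scale
follows from the arterial oxygen content CaO2 = κ·HGB·SaO2 with
κ = 1.34 mL O2 per gram of hemoglobin.
"""

from __future__ import annotations

from dataclasses import dataclass

GAMMA_DEFAULT = 0.75  # venous fraction of the optical signal; field convention
KAPPA_O2_PER_G_HGB = 1.34  # mL O2 carried per gram of hemoglobin


@dataclass
class HemodynamicsRecord:
    """One measurement's hemodynamic summary with provenance labels."""

    subject_id: str
    location: str
    repetition: int
    hbt_um: float
    so2: float
    cbfi: float
    sao2: float
    svo2: float
    oef: float
    cmro2i: float
    gamma: float
    cao2_ml_dl: float | None = None
    cmro2_abs: float | None = None
    flag_negative_oef: bool = False
    qc_pass: bool = True

    @property
    def side(self) -> str:
        return self.location.rsplit("_", 1)[1] if "_" in self.location else ""

    @property
    def lobe(self) -> str:
        return self.location.rsplit("_", 1)[0] if "_" in self.location else self.location


def derive_hemodynamics(
    hbt_um: float,
    so2: float,
    cbfi: float,
    sao2: float,
    *,
    subject_id: str = "",
    location: str = "",
    repetition: int = 0,
    gamma: float = GAMMA_DEFAULT,
    kappa: float = KAPPA_O2_PER_G_HGB,
    hgb_g_dl: float | None = None,
    qc_pass: bool = True,
) -> HemodynamicsRecord:
    """Combine fitted SO2 and CBFi with arterial saturation into one record.

    Computes SvO2 = (SO2 − (1−γ)·SaO2)/γ, OEF = (SaO2 − SO2)/(γ·SaO2) and
    CMRO2i = CBFi·(SaO2 − SO2); when HGB is supplied, also the arterial
    oxygen content CaO2 = κ·HGB·SaO2 (mL O2/dL) and the absolute metabolic
    rate κ·HGB·CBFi·(SaO2 − SO2).  A tissue saturation above the arterial
    value yields a negative OEF and flags the record rather than erroring.
    """
    if sao2 <= 0:
        raise ValueError("sao2 must be positive")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    svo2 = (so2 - (1.0 - gamma) * sao2) / gamma
    oef = (sao2 - so2) / (gamma * sao2)
    cmro2i = cbfi * (sao2 - so2)
    cao2 = kappa * hgb_g_dl * sao2 if hgb_g_dl is not None else None
    cmro2 = kappa * hgb_g_dl * cbfi * (sao2 - so2) if hgb_g_dl is not None else None
    return HemodynamicsRecord(
        subject_id=subject_id, location=location, repetition=repetition,
        hbt_um=hbt_um, so2=so2, cbfi=cbfi, sao2=sao2,
        svo2=svo2, oef=oef, cmro2i=cmro2i, gamma=gamma,
        cao2_ml_dl=cao2, cmro2_abs=cmro2,
        flag_negative_oef=bool(so2 > sao2), qc_pass=qc_pass,
    )
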