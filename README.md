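# nirsflow

Analysis pipeline for hybrid **FDNIRS–DCS** neuromonitoring of the neonatal
brain: from raw multi-distance amplitude/phase data and intensity
autocorrelation curves to absorption/scattering spectra, hemoglobin
concentrations, oxygen saturation, a cerebral blood flow index and an index
of cerebral oxygen metabolism, through to group-level mixed-effects
statistics. A synthetic-cohort generator built on the same closed-form
physics makes every stage of the chain verifiable by parameter recovery,
without any human-subject data.

## Who this is for

Researchers in diffuse optics / neonatal neuromonitoring who need a tested,
scriptable reference implementation of the standard frequency-domain
multi-distance inversion and correlation-diffusion flow fit, and a
simulation harness to validate analysis choices (QC thresholds, fixed-μs′
conventions, mixed-model specifications) against known ground truth.

## The models

**Frequency-domain NIRS.** Intensity-modulated light (110 MHz) in a
semi-infinite scattering medium forms a damped spherical wave. Writing
ω for the angular modulation frequency and v for the speed of light in
tissue, the complex wavenumber is

    k_r = sqrt( (3 μa μs′ / 2) ( sqrt(1 + (ω/(v μa))²) + 1 ) )
    k_i = sqrt( (3 μa μs′ / 2) ( sqrt(1 + (ω/(v μa))²) − 1 ) )

so that ln(AC·ρ²) decays linearly with source–detector distance ρ at rate
k_r and phase grows at rate k_i. Fitting both lines over the four
distances (1.5–3.0 cm) and inverting

    μs′ = 2 v k_r k_i / (3ω),    μa = (ω/2v) (k_r/k_i − k_i/k_r)

yields the absorption and reduced scattering coefficients at each of the 8
wavelengths (672–829 nm). The μa spectrum is unmixed into oxy- and
deoxy-hemoglobin (water fraction fixed at 0.75), μs′(λ) is fitted with the
Mie power law μs′ = a·(λ/500 nm)^−b, and both are extrapolated to 850 nm.

**Diffuse correlation spectroscopy.** The normalized field autocorrelation
of the semi-infinite correlation-diffusion solution,

    G1(ρ,τ) ∝ exp(−K(τ) r1)/r1 − exp(−K(τ) rb)/rb,
    K(τ) = sqrt( 3 μa μs′ + 6 μs′² k0² CBFi τ ),

is related to the measured intensity autocorrelation by the Siegert
relation g2 = 1 + β g1². Nelder–Mead minimization of the squared residual
on the averaged 12-curve g2 recovers the blood flow index CBFi (cm²/s) and
coherence factor β, using the FDNIRS-derived μa(850) and, by default, the
fixed cohort-average μs′(850) = 6.4 cm⁻¹.

**Derived hemodynamics and statistics.** With arterial saturation SaO2
from pulse oximetry, OEF = (SaO2 − SO2)/(γ·SaO2) and
CMRO2i = CBFi·(SaO2 − SO2). Group contrasts (sex, hemisphere, gestational
age) use linear mixed-effects models with random intercepts for subject
and variance components for hemisphere side and cortical lobe.

## Worked example

```python
import numpy as np
from nirsflow import (InstrumentConfig, fdnirs_forward, invert_measurement,
                      fit_chromophores, fit_scattering_model, evaluate_mie,
                      load_extinction_table)
from nirsflow.fdnirs import identity_calibration

cfg = InstrumentConfig()
table = load_extinction_table()
wl = np.array(cfg.fdnirs_wavelengths_nm)

# forward-simulate a tissue with HbO=37 uM, HbR=18 uM, a=13.7, b=1.43
mua = table.at(wl).mua(37.0, 18.0, water_fraction=0.75)
musp = evaluate_mie(13.7, 1.43, wl)
ac = np.empty((8, 4, cfg.n_fdnirs_samples)); ph = np.empty_like(ac)
for j in range(8):
    ac[j], ph[j] = fdnirs_forward(float(mua[j]), float(musp[j]), cfg)

spectrum = invert_measurement(ac, ph, identity_calibration(cfg), cfg)
chromo = fit_chromophores(spectrum.mua, wl, table, 0.75)
scatter = fit_scattering_model(spectrum.musp, wl)
print(f"HbO = {chromo.hbo:.2f} uM, HbR = {chromo.hbr:.2f} uM, "
      f"SO2 = {100*chromo.so2:.1f}%")
print(f"a = {scatter.a_500:.2f} cm^-1, b = {scatter.b_power:.3f}, "
      f"musp(850) = {evaluate_mie(scatter.a_500, scatter.b_power, 850):.2f} cm^-1")
```

prints

```
HbO = 37.00 uM, HbR = 18.00 uM, SO2 = 67.3%
a = 13.70 cm^-1, b = 1.430, musp(850) = 6.41 cm^-1
```

i.e. the noise-free inversion chain reproduces the generating hemoglobin
concentrations exactly, and the fitted Mie law extrapolates to the
6.4 cm⁻¹ scattering value used in the flow fit.

A full synthetic study — 30 infants, 7 cortical sites, 3 probe placements
each, with demographic and hemispheric effect structure — runs end to end
with:

```bash
nirsflow run --seed 1 --out out/
```

which writes `results.csv` (one row per measurement with QC flags) and
`stats.json` (mixed-model sex contrasts, GA trends, hemispheric percent
differences, demographic t-tests).

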