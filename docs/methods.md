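# Methods

## Scope and design

`nirsflow` implements the full analysis chain of a hybrid frequency-domain
near-infrared spectroscopy (FDNIRS) + diffuse correlation spectroscopy
(DCS) study of neonatal cerebral hemodynamics, together with a synthetic
cohort generator built on the same forward physics. The package is
organized so that every inverse step has a closed-form forward counterpart
in `forward.py`, which makes noise-free round trips exact and lets noisy
behavior be characterized by seeded simulation.

## Forward models and their assumptions

Both physics problems are solved in the semi-infinite homogeneous
reflection geometry with an extrapolated zero boundary; heterogeneous or
layered media, Monte-Carlo transport and realistic probe geometries are
out of scope.

* **Photon density waves.** The complex DPDW wavenumber follows from the
  frequency-domain diffusion equation; the two closed-form identities
  k_r² − k_i² = 3 μa μs′ and k_r·k_i = 3 μs′ ω / (2v) hold exactly and are
  enforced to 1e-12 in the test suite. The refractive index is fixed at
  n = 1.4 (soft-tissue convention), giving v = c/n.
* **Correlation diffusion.** The decay rate is
  K(τ) = sqrt(3 μa μs′ + 6 μs′² k0² CBFi τ) with k0 = 2π n / λ at
  λ = 850 nm — the standard red-blood-cell Brownian-motion form of the
  correlation-diffusion solution. The extrapolated boundary uses
  zb = (2/(3 μs′))·(1+R_eff)/(1−R_eff) with R_eff = 0.493 for n = 1.4.
* **Instrument response.** Amplitude units are arbitrary with per-channel
  gains and phase offsets; detector photon statistics are not simulated.
  Raw noise is modelled as additive Gaussian on ln(AC) and on phase
  (FDNIRS) and per-τ-bin Gaussian on g2 (DCS). A correlation-time-dependent
  noise model would be a pluggable refinement.

## Inversion chain

1. **Calibration.** Per (wavelength, distance) channel, the amplitude gain
   is model-predicted AC over the measured phantom median AC and the phase
   offset is measured minus predicted phase, so calibrated phantom data lie
   exactly on the diffusion model.
2. **Temporal reduction.** Medians over the ~100 samples of a 10 s
   acquisition; the *phase noise* QC statistic is the per-channel standard
   deviation of the phase samples (the quantity is not standardized in the
   field; the worst channel in the fit is compared to the threshold).
3. **Slope fits.** Unweighted OLS of ln(AC·ρ²) and phase against ρ.
   Measurements are kept when phase noise ≤ 0.05 rad and both R² ≥ 0.95
   (inclusive comparisons; thresholds configurable). The slope-to-(μa, μs′)
   inversion uses the exact algebraic identities; no small-absorption
   correction to μs′ is applied because none is needed under
   D = v/(3 μs′).
4. **Spectral fits.** Water-corrected nonnegative least squares over
   (HbO, HbR) — concentrations are constrained nonnegative because
   negative concentrations are unphysical — and a log-log linear fit of
   the Mie power law (slope = −b, intercept = ln a), chosen over nonlinear
   original-scale fitting for exactness on noise-free data (the nonlinear
   fit serves as a cross-check in the tests). Fit quality uses R² and the
   regression F-test p-value; both fits must satisfy p ≤ 0.03 and R² ≥ 0.6.
5. **DCS fit.** Nelder–Mead over (log CBFi, β) — the log parameterization
   enforces positivity — initialized at CBFi = 1e-8 cm²/s and
   β = mean(first three g2 bins) − 1, tolerances 1e-10, max 2000
   iterations. The τ window is the full grid by default with optional
   clipping. μa(850) comes from the per-measurement spectral extrapolation;
   μs′(850) defaults to the fixed cohort-average 6.4 cm⁻¹ with a
   per-measurement mode for sensitivity analyses (underestimating μs′
   overestimates CBFi, and vice versa — covered by a dedicated test).
   Curves with no measurable decay (intercept ≤ 1) are flagged degenerate
   rather than fitted.
6. **Hemodynamics.** SvO2 = (SO2 − (1−γ)SaO2)/γ,
   OEF = (SaO2 − SO2)/(γ SaO2), CMRO2i = CBFi (SaO2 − SO2). The venous
   fraction γ defaults to 0.75 — a field convention, not a measured
   quantity — and is carried in every record; CMRO2i is reported without
   hemoglobin scaling unless the user supplies HGB (g/dL), in which case
   CaO2 = 1.34·HGB·SaO2 and an absolute CMRO2 are added.

## Synthetic cohort

The generator emulates the measurement campaign: 19 male / 11 female term
infants (GA truncated-normal 39.2 ± 1.2 weeks on [37, 42]), seven cortical
sites (left/middle/right frontal, left/right temporal and parietal), three
probe placements per site, 10 s acquisitions at 10 Hz (FDNIRS) and 1.2 Hz
(DCS). Baseline tissue state: HbT 54 μM, SO2 0.66, CBFi 2.1e-8 cm²/s,
a = 13.7 cm⁻¹, b = 1.43, β = 0.5, water 0.75.

Structure layered onto the baseline:

* **Sex effects** — multiplicative male/female ratios (defaults 1.10 on
  HbT, 1.05 on SO2, 0.90 on CBFi), split symmetrically (±√factor) so the
  cohort mean stays at baseline. Literature on term neonates establishes
  directions (males higher HbT and SO2, females higher CBFi) but not firm
  effect sizes; the defaults are modest values in those directions.
* **Hemisphere** — right/left CBFi ratio 1.152, split symmetrically;
  midline sites unaffected.
* **Gestational age** — additive slopes (7 μM/week on HbT, 0.06/week on
  SO2) centred on the mean GA, chosen so the subject-level Pearson
  correlation with GA is ≈ 0.49 at the default dispersion — the regression
  implied by that correlation together with the population SDs above.
* **Biological variability** — mean-one log-normal subject and
  repositioning (site) draws for HbT, CBFi and a; logit-normal for SO2;
  additive normal for b. Default dispersions reproduce population SDs of
  roughly 17 μM (HbT), 17 % (SO2), 0.8e-8 (CBFi), 3.5 (a) and 0.43 (b)
  when subject and site layers combine.
* **SaO2** uniform in [0.95, 0.99] per subject, the typical pulse-oximetry
  range for healthy term newborns; HGB absent by default.

What the generator does **not** emulate: motion artifacts and
crying/irritation exclusions, spatial correlation between repositioned
placements, detector count statistics, and layered-tissue partial-volume
effects. Passing recovery tests therefore demonstrate the correctness of
the estimator chain under the stated noise model, not robustness to every
failure mode of real neonatal data.

## Statistics

Repetitions are collapsed by median over QC-passed records per
subject × site (median, matching the robustness conventions used
throughout the pipeline). Mixed models use
statsmodels `MixedLM` with subject as the grouping factor, a random
subject intercept, and variance components for hemisphere side and
cortical lobe (crossed random effects are approximated by nesting within
subject — statsmodels has no crossed-design solver). Two inference details
differ deliberately from a naive `fitlme` transcription:

* p-values for subject-level fixed effects (sex, GA) use a t reference
  with n_subjects − 2 degrees of freedom; the Wald normal approximation
  was measurably anticonservative at n = 30 in null simulations.
* sex is **not** given a variance component in the GA model, although
  protocols of this kind often list it among the random effects: a
  2-level variance component is
  unidentifiable against the subject intercept and doubled the null
  rejection rate in simulation. Subject-level heterogeneity, including
  sex, is carried by the subject intercept.

With these choices the sex-contrast null rejection rate is nominal
(0.053 over 300 null cohorts at α = 0.05). The GA-trend test retains mild
anticonservativeness (≈ 0.08) traceable to the skewed log-normal subject
effects combined with plug-in REML standard errors; subject-means OLS on
the same nulls gives 0.057. This is disclosed rather than tuned away;
users testing GA trends on strongly skewed parameters may prefer the
subject-means fallback (used automatically on singular fits) or a log
transform.

Hemispheric asymmetry is summarized as 100·(mean_R − mean_L)/mean_L over
all lateralized records; no multiple-testing correction is applied across
the parameter × region grid; users comparing many regions should correct
accordingly.

## Extinction table

The bundled chromophore table (`data/extinction_coefficients.csv`) holds
HbO/HbR extinction coefficients (cm⁻¹ per μM, natural-log base) and pure
water absorption at the 8 instrument wavelengths plus 850 nm. Values are
approximate interpolations of the standard literature compendia. All
recovery results are invariant to the table's absolute values because
forward simulation and inversion share the table; for quantitative
real-data work an authoritative table should be substituted.

## Problem sizes and numerical conventions

The test suite and acceptance script use: full-size single measurements
(8 λ × 4 ρ × 100 samples; 12 g2 curves × 128 τ bins) for round trips;
30-infant cohorts for effect-recovery runs (20 seeds in the acceptance
script, 12 in the test suite); 500 null cohorts for the sex-contrast
type-I calibration and 60–120 for secondary null checks. Degenerate inputs
(flat g2, constant GA, single-sex cohorts, zero-variance correlations)
raise typed errors or return flagged records rather than failing silently.
Seeded runs are bit-reproducible; all randomness flows from
`numpy.random.default_rng` generators threaded through the call tree.
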