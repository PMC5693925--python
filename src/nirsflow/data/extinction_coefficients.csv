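# Chromophore extinction table, version 1.
# eps_hbo / eps_hbr: extinction coefficients of oxy-/deoxy-hemoglobin in
#   cm^-1 per uM, NATURAL-log base (molar base-10 values from the standard
#   literature compendium multiplied by ln(10)*1e-6).
# mua_water: absorption coefficient of pure water, cm^-1.
# Values are approximate interpolations of the standard compiled spectra
# (Gratzer/Prahl hemoglobin; Hale-Querry water) at the instrument
# wavelengths plus the 850 nm DCS wavelength. Adequate for synthetic
# round-trip work; substitute an authoritative table for quantitative
# real-data use.
wavelength_nm,eps_hbo,eps_hbr,mua_water
672,7.138e-4,6.447e-3,0.0040
689,6.678e-4,5.181e-3,0.0047
701,6.793e-4,4.260e-3,0.0060
724,8.174e-4,3.108e-3,0.0155
771,1.497e-3,3.178e-3,0.0250
783,1.681e-3,2.487e-3,0.0255
803,1.957e-3,1.796e-3,0.0220
829,2.234e-3,1.600e-3,0.0290
850,2.441e-3,1.589e-3,0.0430
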