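# Molar (decadic) extinction coefficients of hemoglobin in water, cm^-1 M^-1,
# from the standard tabulated compilation of hemoglobin absorption spectra
# (values at 735 nm linearly interpolated between the 730 and 740 nm entries).
wavelength_nm,eps_hbo2,eps_hhb
735,418.0,1109.04
850,1058.0,691.32
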