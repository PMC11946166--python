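# Nominal molar extinction coefficients of adult hemoglobin, 1/(M*mm),
# interpolated at the instrument wavelengths from the commonly used compiled
# HbO2/HHb absorption spectra (deoxy-dominant below the ~800 nm isosbestic
# point, oxy-dominant above it).
wavelength_nm,eps_hbo,eps_hbr
762,60.2,158.4
842,110.8,73.0
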