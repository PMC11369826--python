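# Molar extinction coefficients of haemoglobin, 1/(mM*cm), for the
# wavelengths used by continuous-wave NIRS instruments.  Values are the
# standard compiled spectra (W.B. Gratzer / S. Prahl compilation, as
# distributed with the Homer processing packages), converted from
# 1/(M*cm) by dividing by 1000.
wavelength_nm,chromophore,epsilon_per_mM_cm
690,HbO,0.3123
690,HbR,2.1382
760,HbO,1.4866
760,HbR,3.8437
830,HbO,2.3273
830,HbR,1.7917
850,HbO,2.5264
850,HbR,1.7986
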