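wavelength_nm,hbo_cm_per_uM,hbr_cm_per_uM
760,0.000586,0.00154852
850,0.001058,0.00069132
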