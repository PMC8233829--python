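# High-energy (Born-regime) proton excitation channels of liquid water:
# two Gaussian discrete channels (A1B1, B1A1) and the collective plasmon
# channel with a sigmoid-derivative profile.
#   f0     : channel oscillator strength (dimensionless)
#   alpha  : profile width parameter (eV^-2 for Gaussian, eV^-1 for plasmon)
#   w_eV   : profile centre (eV)
#   smooth : coefficient applied to the integrated cross-section so the
#            high-energy model connects continuously to the low-energy
#            semi-empirical model at the 500 keV switch energy
# Integration bounds for the total cross-section:
w_min_eV: 2.0
w_max_eV: 50.0
channels:
  A1B1:    {kind: gaussian, f0: 0.0187, alpha: 3.0, w_eV: 8.4,  smooth: 1.23}
  B1A1:    {kind: gaussian, f0: 0.0157, alpha: 1.0, w_eV: 10.1, smooth: 3.5}
  plasmon: {kind: plasmon,  f0: 0.7843, alpha: 0.6, w_eV: 21.3, smooth: 0.339}
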