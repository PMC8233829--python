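# Rudd-model fit parameters for proton-impact ionization of the five
# molecular orbitals of liquid water.  binding_eV is the orbital binding
# energy B_i, n_electrons the occupancy N_i, alpha the size parameter of the
# sigmoid cutoff, and A1..E1 / A2..D2 the F1/F2 fit coefficients.  A shell is
# treated as "inner" when its binding energy exceeds twice the smallest
# binding energy; with these values that selects 1a1 and 2a1.
shells:
  1b1: {binding_eV: 12.61, n_electrons: 2, alpha: 0.64,
        A1: 1.02, B1: 82.0, C1: 0.45, D1: -0.80, E1: 0.38,
        A2: 1.07, B2: 14.6, C2: 0.60, D2: 0.04}
  3a1: {binding_eV: 14.73, n_electrons: 2, alpha: 0.64,
        A1: 1.02, B1: 82.0, C1: 0.45, D1: -0.80, E1: 0.38,
        A2: 1.07, B2: 14.6, C2: 0.60, D2: 0.04}
  1b2: {binding_eV: 18.55, n_electrons: 2, alpha: 0.64,
        A1: 1.02, B1: 82.0, C1: 0.45, D1: -0.80, E1: 0.38,
        A2: 1.07, B2: 14.6, C2: 0.60, D2: 0.04}
  2a1: {binding_eV: 32.2, n_electrons: 2, alpha: 0.66,
        A1: 1.25, B1: 0.5, C1: 1.0, D1: 1.0, E1: 3.0,
        A2: 1.10, B2: 1.3, C2: 1.0, D2: 0.0}
  1a1: {binding_eV: 539.7, n_electrons: 2, alpha: 0.66,
        A1: 1.25, B1: 0.5, C1: 1.0, D1: 1.0, E1: 3.0,
        A2: 1.10, B2: 1.3, C2: 1.0, D2: 0.0}
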