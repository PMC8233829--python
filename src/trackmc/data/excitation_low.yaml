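# Low-energy (< 500 keV) proton excitation of liquid water: five discrete
# channels with Miller-Green-form semi-empirical total cross-sections
#
#   sigma_j(Ek) = sigma0 * za^omega * (Ek - E_j)^nu / (J^(omega+nu) + Ek^(omega+nu))
#
# with Ek in eV and sigma0 in m^2.  E_j is the discrete energy loss of the
# proton for channel j.  Parameter values follow the Miller-Green
# parameterization for water as adopted in the Dingfelder lineage of
# track-structure codes (and in Geant4-DNA's proton excitation model); they
# are configuration, not constants baked into the code.
channels:
  A1B1:    {E_eV: 8.4,   sigma0_m2: 1.0e-20, za: 8760.0,  J_eV: 19820.0, omega: 0.85, nu: 1.0}
  B1A1:    {E_eV: 10.1,  sigma0_m2: 1.0e-20, za: 20840.0, J_eV: 23490.0, omega: 0.88, nu: 1.0}
  RydAB:   {E_eV: 11.26, sigma0_m2: 1.0e-20, za: 13730.0, J_eV: 27770.0, omega: 0.88, nu: 1.0}
  RydCD:   {E_eV: 11.93, sigma0_m2: 1.0e-20, za: 6920.0,  J_eV: 30830.0, omega: 0.78, nu: 1.0}
  diffuse: {E_eV: 14.1,  sigma0_m2: 1.0e-20, za: 9000.0,  J_eV: 33080.0, omega: 0.78, nu: 1.0}
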