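# Water-radiolysis chemistry for the step-by-step chemical stage.
#
# Diffusion coefficients D (m^2/s) and bimolecular rate constants k
# (L mol^-1 s^-1) are the standard literature set used by step-by-step
# radiolysis codes.  Reaction radii are derived at load time as
# Rc = k / (4 pi N_A D12) with D12 the sum of the reactant diffusion
# coefficients.  Products named "H2O" (bulk water) are dropped.
species:
  e_aq:  {D_m2_s: 4.9e-9}
  OH:    {D_m2_s: 2.8e-9}
  H:     {D_m2_s: 7.0e-9}
  H3O+:  {D_m2_s: 9.0e-9}
  H2:    {D_m2_s: 4.8e-9}
  OH-:   {D_m2_s: 5.0e-9}
  H2O2:  {D_m2_s: 2.3e-9}
reactions:
  - {reactants: [e_aq, e_aq],  products: [H2, OH-, OH-], k_L_mol_s: 0.50e10}
  - {reactants: [e_aq, OH],    products: [OH-],          k_L_mol_s: 2.95e10}
  - {reactants: [e_aq, H],     products: [H2, OH-],      k_L_mol_s: 2.65e10}
  - {reactants: [e_aq, H3O+],  products: [H],            k_L_mol_s: 2.11e10}
  - {reactants: [e_aq, H2O2],  products: [OH, OH-],      k_L_mol_s: 1.41e10}
  - {reactants: [OH, OH],      products: [H2O2],         k_L_mol_s: 0.44e10}
  - {reactants: [OH, H],       products: [H2O],          k_L_mol_s: 1.44e10}
  - {reactants: [H, H],        products: [H2],           k_L_mol_s: 1.20e10}
  - {reactants: [H3O+, OH-],   products: [H2O],          k_L_mol_s: 14.3e10}
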