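# Radical-DNA reaction rates (L mol^-1 s^-1) for the concurrent transport of
# radicals in the presence of the voxelized DNA geometry.
#
# per_base holds the rates against the four individual bases; the simulation
# uses their average (base) because the geometry does not distinguish base
# types.  A negative rate means no reaction between that radical and that
# substructure.  Histone proteins scavenge every radical species with
# probability scavenge_probability on contact (reaction radius zero).
per_base:
  OH:   {A: 6.1e9, G: 9.2e9, C: 6.4e9, T: 6.1e9}
  e_aq: {A: 9.0e9, G: 14.0e9, C: 18.0e9, T: 13.0e9}
rates:
  OH:   {base: 6.95e9, sugar: 1.9e9}
  e_aq: {base: 13.5e9, sugar: -1.0}
scavenge_probability: 1.0
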