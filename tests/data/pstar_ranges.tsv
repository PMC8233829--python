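# Proton CSDA ranges in liquid water transcribed from the NIST PSTAR
# database (https://physics.nist.gov/PhysRefData/Star/Text/PSTAR.html),
# converted from g/cm^2 at unit density to metres.
Ek_eV	range_m
1.0e6	2.458e-5
5.0e6	3.623e-4
1.0e7	1.230e-3
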