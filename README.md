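# trackmc

A CPU reference implementation of event-by-event (track-structure) Monte
Carlo transport of protons and heavy ions in liquid water, coupled to a
step-by-step water-radiolysis chemical stage in which the radicals diffuse,
react with each other, and react *concurrently* with a voxelized DNA
geometry.  The package computes the standard microdosimetric observables
(unrestricted LET, range, radial dose, secondary-electron phase space,
G-values) and scores radical-induced DNA damage as single- and double-strand
breaks (SSB/DSB).

It is aimed at computational radiation biophysicists who want a transparent,
fully deterministic, pure-Python reference for the physics and chemistry
kernels that GPU track-structure codes implement, at desk scale.

## Models

**Ionization (protons).**  The Rudd semi-empirical model for the five
molecular orbitals of water (1b1, 3a1, 1b2, 2a1, 1a1).  The singly
differential cross-section in the scaled ejected-electron energy
w = E<sub>e</sub>/B<sub>i</sub> is

    dσ_i/dw = S_i · (F₁(ν) + w F₂(ν)) / [(1+w)³ (1 + exp(α(w−w_i)/ν))]

with S<sub>i</sub> = 4πa₀²N<sub>i</sub>(E<sub>R</sub>/B<sub>i</sub>)², the
relativistic scaled velocity ν² = (mc²/2B<sub>i</sub>)(1−γ⁻²), and the
per-shell fit functions F₁, F₂.  Totals are adaptive quadratures over
[0, w<sub>m</sub>], w<sub>m</sub> = E<sub>m</sub>/B<sub>i</sub> with the
relativistic maximum energy transfer E<sub>m</sub>.

**Excitation (protons).**  Above 500 keV, a Born-regime three-channel model
(Ã¹B₁, B̃¹A₁ Gaussian profiles and a plasmon channel) with
dσ<sub>j</sub>/dW = ρ(W)·W·f<sub>j</sub>(W)·ln(4T/W) integrated over
W ∈ [2, 50] eV; below 500 keV, a five-channel semi-empirical (Miller–Green
form) model with discrete energy losses.  Channel-wise continuity
coefficients (1.23, 3.5, 0.339) connect the two regimes at the switch
energy.

**Effective charge and heavy ions.**  The Booth empirical model
Z<sub>eff</sub> = Z(1 − exp(−1.316y + 0.112y² − 0.065y³)),
y = 100·β·Z<sup>−2/3</sup>.  An ion (Z, A, E<sub>k</sub>) uses the proton
cross-sections at E<sub>k</sub>/A scaled by Z<sub>eff</sub>².

**Chemical stage.**  Brownian dynamics with per-species diffusion
coefficients; bimolecular reactions occur on contact within the Smoluchowski
radius R<sub>c</sub> = k/(4πN<sub>A</sub>D₁₂) and, between step endpoints,
with the Brownian-bridge probability
P = exp(−(d₁−R<sub>c</sub>)(d₂−R<sub>c</sub>)/(D₁₂Δt)).  Pair search uses a
uniform grid with cell edge twice the largest reaction radius (same/adjacent
cells), or an equivalent KD-tree.

**DNA geometry and damage.**  A synthetic nucleus built from 55-nm voxels,
each either empty or crossed by a chain of spheres (bases, two helical
sugar-phosphate strands, histones), with a ≥2-nm clearance from every voxel
face the chain does not cross.  That contract makes a two-voxel search
(own voxel + across the closest face) exact at reaction distances.  During
the chemical stage a radical–DNA check runs every t<sub>i</sub>; histones
scavenge with probability P<sub>s</sub>; recorded sugar damages convert to
strand breaks (p = 0.4) and opposite-strand breaks within 10 bp pair into
DSBs.

## Worked example

```python
import numpy as np
from trackmc import (build_tables, charge_correction_threshold,
                     transport_primary, ParticleState, csda_range,
                     reaction_radius)

y_star, ek = charge_correction_threshold(1, 1)
print(f"5% effective-charge correction: y* = {y_star:.3f} at {ek/1e6:.3f} MeV (proton)")

table = build_tables()                      # 10 eV .. 1 TeV, 0.01 log10 step
tracks = []
for s in np.random.SeedSequence(42).spawn(10):
    state = ParticleState(Z=1, A=1, Ek_eV=1e6, position_nm=np.zeros(3),
                          direction=np.array([0.0, 0.0, 1.0]))
    tracks.append(transport_primary(state, table, cutoff_eV=1e3,
                                    rng=np.random.default_rng(s)))
mean_r, sd_r = csda_range(tracks)
print(f"1 MeV proton range: {mean_r*1e6:.2f} +/- {sd_r*1e6:.2f} um")
print(f"OH-base reaction radius: {reaction_radius(6.95e9, 2.8e-9)*1e9:.3f} nm")
```

prints

```
5% effective-charge correction: y* = 2.172 at 0.221 MeV (proton)
1 MeV proton range: 23.71 +/- 0.37 um
OH-base reaction radius: 0.328 nm
```

The threshold says a proton slower than ~0.22 MeV carries an apparent charge
below 0.95 e because it drags medium electrons along.  The simulated 1 MeV
range sits a few percent below the tabulated CSDA reference (see
`docs/methods.md` for the known stopping-power offset of this cross-section
set).  The OH–base radius is the contact distance at which the encounter
rate of a diffusion-limited reaction reproduces the tabulated rate constant.

A command-line interface mirrors the library:
`trackmc build-xs | run-physical | run-chemical | run-concurrent | classify | sweep`,
each taking a YAML config and a seed; outputs are tab-separated tables and
JSON reports stamped with the seed and a config hash.

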