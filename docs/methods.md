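# Methods

This note documents the physical models, the numerical choices and the
deliberate design decisions behind trackmc, and states what the synthetic
generators and reduced-scale experiments do and do not demonstrate.

## Physical stage

### Ionization

Proton-impact ionization of liquid water uses the Rudd semi-empirical model
for the five molecular orbitals, with the liquid-phase binding energies
(12.61, 14.73, 18.55, 32.2, 539.7 eV) and the inner/outer fit-parameter
split (an orbital is "inner" when its binding energy exceeds twice the
smallest one, which selects 2a1 and 1a1).  The relativistic forms are used
at all energies: the maximum energy transfer
E_m = 2mc²(γ²−1)/(1 + 2γm/M + (m/M)²) and the scaled velocity
ν² = (mc²/2B)(1−γ⁻²); both reduce to the classical 4(m/M)E_k and T/B below
~1 keV to 0.1%.

One typographic ambiguity in the printed model had to be resolved: the
quadratic fit term H₂ is implemented as A₂/ν² + B₂/ν⁴ (the standard Rudd
form).  The alternative multiplicative reading diverges with energy and
would make the cross-section unbounded.

Total cross-sections are adaptive quadratures (relative tolerance 1e-6,
with the sigmoid cutoff w_i registered as a breakpoint).  The lookup table
covers 10 eV to 1 TeV in 0.01 steps of log10(E): 1101 nodes per channel,
linear interpolation in log10(E), exact at nodes, and bit-identical on
rebuild.

### Excitation

Above the 500 keV switch energy the Born-regime three-channel model is used
with the simplified energy-loss density dσ/dW = ρ(W)·W·f(W)·ln(4T/W) on
W ∈ [2, 50] eV.  The Bethe prefactor is taken dimensionally as
ρ(W) = 8πZ²a₀²Ry²/(mu²W²) (the only arrangement with units of area per
energy³ × W² → m²/eV).  Below the switch the five-channel semi-empirical
model σ(E) = σ₀(Za)^Ω(E−E_j)^ν/(J^(Ω+ν)+E^(Ω+ν)) with discrete losses E_j
applies; its parameter values are configuration, shipped in
`data/excitation_low.yaml`, transcribed from the Miller–Green
parameterization for water used in the Dingfelder-lineage track codes.  The
transcription is corroborated by an internal consistency check: the printed
channel-continuity coefficients 1.23 (Ã¹B₁) and 3.5 (B̃¹A₁) connect the two
models at 500 keV to 0.03% and 1.1% with these values, and the plasmon
coefficient 0.339 connects the totals to 0.8%.  An optional mode extends
the low-energy model to 80 MeV.

### Effective charge and transport

The Booth model supplies Z_eff with the velocity-form scaling variable
y = 100βZ^(−2/3); the 5% correction point (y* = 2.172, ~0.22 MeV for
protons, ~17.5 MeV/n for iron) is reproduced by root-finding and used as an
anchor test.  Heavy-ion cross-sections are the proton values at E_k/A scaled
by Z_eff².

Design decision: the Z_eff² scaling is applied to ions with Z ≥ 2 only.
The Rudd parameterization is an empirical fit to proton data and already
contains the low-energy charge-exchange physics; rescaling the proton by
its own Booth factor (< 1 below ~0.2 MeV) double-counts electron capture
and visibly inflates sub-MeV ranges (+55% at 1 MeV in a direct experiment).
A flag restores the literal scaling for protons.

Transport is event by event: exponential free flight with mean
1/(n σ_t), n = ρN_A/M_w ≈ 3.343×10²⁸ m⁻³; channel choice proportional to
the per-channel cross-sections; the primary is never deflected.  Ejected
electrons are sampled by closed-form inversion of the smooth Rudd factor
(normalization N_c has a closed form, checked against the analytic 3/8
fixture) with sigmoid rejection; their polar angle follows binary-encounter
kinematics cosθ = √(E_e/4T) above the binding energy and is uniform in θ
below it.  Excitation losses are sampled from the Gaussian profiles
(resampled, not clipped, into [2, 50] eV) or the closed-form plasmon
inversion, with g(W) = ln(4T/W)/W rejection.  Rejection loops carry a 1e5
guard and raise rather than spin.

Bookkeeping: the binding energy (ionization) or energy loss (excitation) is
deposited at the interaction point; secondary electrons are recorded to a
phase-space stack with their energy, position and direction and are *not*
transported (electron track structure is outside this package's scope);
residual energy below the 1 keV cutoff (configurable) is deposited at the
endpoint.  Every track satisfies the exact balance
E_k(0) = Σ deposits + Σ secondary energies (+ carried-out residual when the
particle leaves the region of interest) to 1e-6 relative, and the endpoint
displacement equals the summed free paths exactly.

### Observables

The unrestricted, track-length-averaged LET is Σε_i/Σs_j; the path-weighted
mean of ε_i/s_i is identically the same ratio.  A fixed-energy estimator
draws independent single-collision (ε, s) pairs.  Range is the mean
straight-line start-to-end distance of cutoff-terminated primaries (mean
path length and projected range coincide because the primary is never
deflected).  Radial dose histograms energy into 1-nm annuli around the
initial direction inside an axial window, conserving energy exactly; since
secondaries are untransported point deposits, the radial profile is a
qualitative smoke test only.  Dose is Σ E/m with liquid-water density;
G-values are 100 × count / E_dep(eV).

### Known accuracy limits of the physical stage

The instantaneous stopping power implied by this cross-section set is ~4%
above the tabulated CSDA reference at 1–10 MeV, so simulated ranges run
~3.5–4% short of the NIST PSTAR values there (measured −3.9%, −4.0%, −3.4%
at 1, 5, 10 MeV with 50/30/20 primaries); below ~10 keV the model
cross-sections are small and the last micron of slowing is overestimated
(+~0.9 µm, visible only below ~0.5 MeV).  The range test in the acceptance
suite applies the nominal 1% tolerance and therefore documents this offset
as a failure rather than hiding it; all relative and structural range
properties (energy ordering, straggling, straight-line identity) hold.

## Chemical stage

Radicals take isotropic Gaussian steps with per-axis variance 2DΔt.
Diffusion coefficients and the nine-reaction mutual-reaction set are
configuration (`data/radiolysis_chemistry.yaml`), with the standard
literature values used by step-by-step radiolysis codes.  Reaction radii
derive from Smoluchowski, R_c = k/(4πN_A D₁₂), with k converted from
L mol⁻¹ s⁻¹.  For identical-reactant channels (OH+OH, e_aq+e_aq, H+H) the
radius uses 2k: tabulated rate constants for 2A → P follow the
−d[A]/dt = 2k[A]² convention, and only the doubled encounter rate
reproduces that decay law (verified: the fitted rate is 1.02k with the
doubled radius, 0.51k without).

Each step runs (1) a contact sweep cascaded until stable, so products can
react immediately; (2) diffusion of all survivors; (3) a bridge sweep in
which pairs now within the search radius react with certainty on contact or
with P = exp(−(d₁−R_c)(d₂−R_c)/(D₁₂Δt)) otherwise.  Conflicts resolve
nearest-pair-first with radical-id tie-breaks; products are placed at the
reactant midpoint; all of this is deterministic for a fixed seed.  The
bridge formula is the exact 1-D first-passage probability for the
separation coordinate; in 3-D at separations comparable to R_c it
overestimates re-encounters (up to ~2× at d = 2R_c, where the neglected
Bessel outward drift matters).  This approximation is shared by
step-by-step radiolysis codes and is mitigated by keeping the per-step RMS
displacement at or below R_c, where contact reactions dominate.

Pair search restricts candidates to separations within twice the largest
reaction radius, found on a uniform grid over same/adjacent cells (the
algorithmic contract) or a KD-tree; both enumerate exactly the same pair
set, verified bit-for-bit against an all-pairs sweep.  Boundaries: open
(default), periodic box (used by the rate-law experiment), or an absorbing
sphere standing in for a nucleus surface.

The default time-step plan is Δt = 0.1 ps up to 10 ps, then Δt = t/10
capped at 10 ns — fine while spurs are dense, coarse later; it is a plain
data object and fully configurable.

### Rate-law recovery experiment

A dilute OH+OH → H₂O₂ system (6000 radicals, 87-nm periodic box, 3-ps
steps) recovers the tabulated k within 10% when the 1/N(t) slope is fitted
after 1 ns.  The early-time window is excluded deliberately: the transient
Smoluchowski term k(t) = k(1 + R_c/√(πDt)) inflates the apparent rate by
>10% before ~0.5 ns, which is physics, not a solver artifact.

## Synthetic generators

**Spur source.**  The radical distribution at the start of the chemical
stage (~1 ps) is emulated by Gaussian clusters ("spurs") along a line
segment: configurable count, spacing, RMS radius, and species fractions
defaulting to the standard ~1 ps picture (OH : e_aq : H₃O⁺ : H : H₂ ≈
5.5 : 4.7 : 4.7 : 0.6 : 0.15), with a nominal energy deposit of 6.4 eV per
radical for G-value normalization.  It reproduces requested counts exactly
and the requested RMS radius and proportions statistically.  What it does
*not* emulate: the correlated track structure of real electron/ion
radiolysis (spur size and occupancy distributions, the physico-chemical
branching), so chemical-stage results are method verifications, not
predictions of absolute G-values.

**Nucleus geometry.**  Voxels of 55 nm arranged on a deterministic
serpentine walk; each occupied voxel carries a straight chain from its
entry to its exit point (face centres), with one 0.5-nm base sphere per bp
on the axis, two 0.35-nm sugar spheres per bp wound helically at 1 nm
radius (36°/bp, random phase per voxel), 0.34-nm rise, and a 3.3-nm histone
sphere replacing the bp elements every 200 bp by default (50 bp in the
damage experiments).  Elements never extend outside their voxel and keep
≥2 nm clearance from every face the chain does not cross; elements whose
sphere would violate the contract near the crossing faces are skipped.
Under this contract a query of the radical's own voxel plus the voxel
across its closest face (entered only within 2 nm of that face) returns the
global nearest element whenever the true surface distance is below the
largest radical–DNA reaction radius (< 1 nm); this is verified against a
global brute-force scan on 10⁴ random points.  The geometry is a structural
stand-in for a full cell-nucleus chromatin model: element sizes and
spacings are B-DNA/nucleosome-scale conventions, not a fit to any specific
nucleus, so absolute damage yields are not comparable to cell experiments.

## Concurrent radical–DNA transport

Radicals created inside any DNA element sphere are removed before the
chemical stage without recording damage.  During the stage a radical–DNA
check runs after the first chemistry step whose end time is ≥ t_i since the
last check, and once more at the end of the stage; t_i ≥ t_c therefore
reduces the simulation to the overlay method (chemistry first, a single
end-of-stage check), which is asserted bit-for-bit.  Each check takes the
nearest element only (the search contract above): base and sugar channels
react on contact within R + R_c or via the Brownian bridge over the elapsed
interval (evaluated only within the 2-nm window, with the radical's
position at the previous check as the start point; products born since then
use their birth position).  Rates are the base-type-averaged literature values
(OH: 6.95×10⁹ and 1.9×10⁹; e_aq: 13.5×10⁹ and none, L mol⁻¹ s⁻¹ against
base and sugar-phosphate); a non-positive rate disables a channel.
Histones scavenge any species on volume contact with probability P_s
(default 1), with no damage record and no bridge (their reaction radius is
zero by construction).

## Strand-break scoring

Indirect sugar-phosphate damages convert to strand breaks with probability
0.4; direct energy deposits (when supplied) convert with a linear ramp from
5 to 37.5 eV; base damages are tallied but never break.  Breaks on opposite
strands within 10 bp pair into DSBs by a greedy left-to-right walk along
the chain, which equals maximum matching for this on-a-line problem
(verified exhaustively against an independent matching oracle); remaining
breaks are SSBs.  Random draws are consumed in site order, so classifying a
time-prefix of a damage log is prefix-consistent — the property the
relative-yield experiment relies on.

## Reduced-scale damage experiments

The sweep experiments run on a 3×3×3-voxel block (~4300 bp, histones every
50 bp) with an 800-radical spur track laid along the chain axis of the
first voxel row, 20 replicates with paired seeds, t_i = 1 ps unless swept.
Problem sizes were chosen so the whole suite runs in minutes on one CPU
while each trend remains larger than its replicate noise.  Observed trends
at these conditions: the OH yield falls monotonically as the stage duration
grows (more consumption by DNA and mutual reactions); relative DSB yields
R_t = N_DSB(t_c)/N_DSB(1 ns) satisfy R(10 ns) ≥ R(2.5 ns) ≥ 1 (damage only
accumulates under concurrent checking — per-replicate monotonicity is
structural, because sites accrue over time and greedy pairing is monotone
under break addition); and the DSB yield is non-increasing in the histone
scavenging probability.  These are qualitative reproductions of the
method's behaviour at reduced scale; absolute DSB yields per Gy per Gbp
require the full nucleus geometry, electron transport and the
physico-chemical stage, all outside this package's scope.

## Degenerate inputs and guards

Zero or negative energies, cross-sections, volumes and probabilities raise
immediately with the offending quantity named.  Sampled losses are clamped
to the remaining kinetic energy (a near-stopped primary deposits everything
locally).  log(0) draws in the exponential sampler are redrawn.  The
rejection-loop guard (1e5) converts inconsistent parameters into a hard
error rather than a silent hang.  Reaction tables validate species
references and reject duplicate channels; the geometry generator re-verifies
its own containment contract after construction.
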