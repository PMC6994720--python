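# Methods

This note documents the models implemented in `ctquench`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Fluctuation estimators for Marcus parameters

The package treats the vertical excitation energies of the locally excited
(LE, Chl\* Q_y) and charge-transfer (CT, Lut⁺Chl⁻) states of a Lut/Chl
dimer as stationary Gaussian processes sampled along a trajectory. Under
linear response, the free energy of the minimum of state X is

    G_X = ⟨E_X⟩ − σ_X²/(2 k_B T),

the driving force is ΔG = G_CT − G_LE, and the reorganization energy of
the LE→CT radiationless transition is λ = σ_ΔE²/(2 k_B T) with ΔE the
per-snapshot CT−LE gap. Both estimators use the unbiased (n−1) sample
variance. Confidence intervals on state means are the normal
approximation 1.96·s/√n; snapshots pooled over the three monomers of the
trimer are treated as independent (block labels are carried but no block
correction is applied).

The charge-separation rate is the classical (high-temperature,
nonadiabatic) Marcus expression, evaluated entirely in wavenumber units:

    k = (2π/ħ) V² (4π λ k_B T)^(−1/2) exp[−(ΔG + λ)²/(4 λ k_B T)]

with fixed constants k_B = 0.695035 cm⁻¹/K and ħ = 5.30886×10⁻¹² cm⁻¹·s
(values frozen for bit-reproducibility; a unit test cross-checks the rate
against an independent SI-unit implementation). The coupling V enters as
the ensemble root-mean-square, i.e. a Condon average over conformations.
No quantum vibrational (Marcus–Levich–Jortner) correction is applied; in
this activation regime (|ΔG| ≪ λ) the classical form is the standard
choice and reproduces the reference rates (33.8 and 4.9 ns⁻¹ at 300 K
from V = 240/279 cm⁻¹, λ = 5405/5052 cm⁻¹, ΔG = −82/+951 cm⁻¹).
Temperature defaults to 300 K everywhere and is configurable.

**Estimator uncertainty.** The variance terms dominate the sampling error
of ΔĜ: s.e.(σ̂²/2k_BT) ≈ √(2/n)·σ²/(2k_BT), about 550 cm⁻¹ for the CT
state at n = 240. A single 240-snapshot replicate therefore pins λ to
~±10% but leaves ΔĜ uncertain by several hundred cm⁻¹ — and because the
lifetime is steep in ΔG₁ near the reference point, a lifetime computed
from one replicate's estimates ranges from tens of ps to ~2 ns across
seeds. The acceptance checks accordingly separate the deterministic
network (reference rate inputs) from the stochastic estimator-recovery
checks (distributions over 200 replicates).

## Kinetic model of excitation quenching

Five transient states: a lumped pool of six chlorophylls (degeneracy 6),
Chl a612, Chl a603, CT1 = Lut1⁺a612⁻, CT2 = Lut2⁺a603⁻. Three absorbing
sinks: intrinsic decay from every chlorophyll state, and charge
recombination from each CT state. Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| exchange time | 5 ps | elementary pool→Chl excitation hop; results insensitive in the fast-exchange regime |
| recombination time | 10 ps | CT → ground/dark-state sink |
| intrinsic lifetime | 4 ns | unquenched Chl a excited state (canonical value) |
| Q_y energies | degenerate, 15567.5 cm⁻¹ | see below |
| p₀ | (6/8, 1/8, 1/8, 0, 0) | excitation equally partitioned over the 8 Chl a |

Every reversible edge obeys detailed balance against effective free
energies (pool degeneracy absorbed as −k_BT ln 6), so the sink-free
network relaxes to the Boltzmann distribution — a tested invariant.

The Q_y manifold is degenerate by default: the a612/a603 site-energy
difference (39 cm⁻¹ between the reference ensemble means) is below both
k_BT and the sampling uncertainty of those means, and an equal initial
partition is an equilibrium state only of a degenerate manifold. With
this choice and the reference charge-separation rates the model yields
τ_complex = 277.1 ps with 90.4% of the excitation quenched through CT1
and 2.9% through CT2; per-state Q_y energies remain arguments of
`build_network` for sensitivity studies.

Solvers: (i) closed form, τ = 1ᵀ(−K)⁻¹p₀ with per-sink fractions
r_s(−K)⁻¹p₀ (K is the transient-block generator; unreachable-sink states
are detected and named before inversion); (ii) matrix-exponential
propagation of the survival curve; (iii) a vectorized stochastic-jump
(Gillespie) simulator. The three agree within quadrature/Monte-Carlo
error in the test suite. The lifetime integrates *total* transient
population, CT states included (they hold <1% of the integral under the
defaults). A fast-equilibrium reduction (chlorophylls lumped into one
Boltzmann-weighted state) provides the analytic limit of the exchange
dynamics; at a 0.1 ps exchange time the full network matches it within
1%.

The ΔG₁ scan recomputes the L1 rate through the Marcus expression at
fixed V and λ, rebuilds the network, and reports the lifetime; a linear
interpolation locates the ΔG₁ at which a target lifetime (default 2 ns,
the unquenched-membrane value) is crossed — ≈ +840 cm⁻¹ under the
defaults, with a >4-fold lifetime increase already at +700 cm⁻¹.

## Geometric descriptors

**BLA.** Mean single-bond minus mean double-bond length over a tagged
conjugation path. Paths are data (serial-number lists with bond tags in a
YAML sidecar), not code; bonds farther apart than 2.0 Å are rejected as
unbonded.

**Density overlap.** Sum over cross-pigment pairs of the two annotated
atom sets of the intersection volume of equal spheres of radius R
centred on the atoms, V(d) = π(2R−d)²(4R+d)/12 for d < 2R. Default
R = 1.7 Å (carbon van der Waals radius), configurable; the closed form is
validated against rejection-sampling Monte Carlo. A Gaussian-density
variant (σ = R/2, amplitude scaled to keep Å³ units) is provided behind
the same interface for users who prefer a smooth descriptor; the hard
sphere is the default because it is exactly testable and vanishes beyond
contact. The absolute overlap scale depends strongly on R and on the
chosen atom sets, so only *relative* overlap variation is meaningful.

**Ring frame.** Orthonormal frame from three annotated ring atoms (origin
at the first, x toward the second, y Gram–Schmidt-orthogonalized toward
the third); the reported (x, y) is the projected centroid of the lutein
overlap set. Translation-invariant and equivariant under rigid rotation;
collinear frame atoms are an error.

**Variance decomposition.** Hierarchical OLS (statsmodels): R² of the
four-BLA block, then the incremental R² of the intermolecular block
(overlap, x, y). Shares plus residual sum to one; the incremental share
is order-dependent by construction (shared variance is credited to the
earlier block), and the intramolecular-first order is fixed as the
scientific convention here: fast bond-stretching coordinates are
conditioned on before slower inter-pigment motion. Rank-deficient designs
are rejected with the offending columns named. The
overlap-to-CT-energy extrapolation (`ct_shift_from_overlap`) is a
deliberate linear-response estimate: slope × Δoverlap, with the slope
supplied by the user's regression.

## Synthetic-data generator

**Energy ensembles.** Four jointly Gaussian states per site, i.i.d.
across snapshots; monomer block labels are carried but blocks are
statistically identical (the three monomers are pooled symmetrically).
The LE/CT spreads and their correlation are solved in closed form from
three conditions: σ_CT = 2σ_LE (CT states couple more strongly to
environment polarization), the population gap variance equals 2k_BTλ,
and the population ΔG equals the reference driving force. This gives
(σ_LE, σ_CT, ρ) = (813, 1625, 0.397) cm⁻¹ for L1 and (797, 1594, 0.421)
for L2. The solution is consistent but not unique — per-state variances
and LE/CT correlations are not independently constrained by the reference
statistics, and the chosen σ ratio implies mean-CIs slightly wider than
the reference ones (the two constraint sets cannot hold simultaneously
under a fixed ratio). Spreads of the two states that do not enter λ/ΔG
(Lut\* S₂ and Lut⁻Chl⁺) are back-solved from their reference CIs.
Couplings are zero-mean Gaussian with scale equal to the target RMS
(signs fluctuate; only |V|² is physical), with a constant-coupling switch
for degenerate tests.

**Structures.** The chlorin proxy is a planar 16-carbon ring whose
alternating chord lengths are solved (bisection on the angular step, to
machine precision) so the ring BLA hits its target exactly; the lutein is
a planar zigzag polyene of 18 bonds built from 1.40 ± BLA/2 Å bonds,
split into two independently targeted conjugation paths. Geometry only —
no element types beyond carbon, no hydrogens, no chemistry: every
descriptor downstream depends on coordinates alone. Jitter (default 0)
adds isotropic Gaussian noise after the exact construction; jittered BLAs
remain centred on their targets. Structures are written as standard PDB
(HETATM, one chain per pigment, occupancy 1.00) with annotations in YAML.

**Descriptor tables.** CT energy = linear function of the four BLA
columns and the overlap column plus Gaussian noise, coefficients scaled
so the population variance shares match the request (default 0.55 BLA /
0.20 intermolecular); the overlap coefficient is negative (larger overlap
stabilizes the CT state). BLA fluctuation scale 0.01 Å about 0.08 Å,
overlap 0.012 about 0.07 Å³, CT total SD 1600 cm⁻¹ — magnitudes chosen
once to match the scales of the ensemble statistics and of conjugated
bond-stretch fluctuations. The (x, y) columns are noise with zero true
coefficient; including them in the intermolecular block costs two degrees
of freedom and is immaterial at n = 240.

**What passing tests show — and don't.** The generator draws i.i.d.
Gaussian snapshots; real trajectory data are autocorrelated, multimodal
where conformational substates exist, and the monomers of a real trimer
are not statistically identical. Recovery of λ, ΔG and variance shares
here therefore validates the *estimators and plumbing* under the stated
statistical model, not the linear-response assumption itself, and the
normal-approximation CIs will undercover on correlated real data. The
synthetic structures are descriptor fixtures, not chemically meaningful
pigments.

## Problem sizes and numerical choices

Default problem sizes used throughout (tests, pipeline, acceptance
script): 240 snapshots per ensemble (80 per monomer block), 200-replicate
estimator-recovery studies, 50-replicate regression studies, 10⁵
trajectories for the jump-simulation oracle, ~4000-point time grids for
quadrature. These reproduce every reference quantity within its sampling
error while keeping the whole suite fast.

Degenerate inputs are handled explicitly: zero spreads give exact-mean
ensembles (eigen-decomposition instead of Cholesky for the covariance
root); zero variance gives λ = 0; spheres beyond contact give exactly
zero overlap; a channel rate of zero removes that quenching pathway
cleanly. Seeded `numpy.random.default_rng` streams (one fixed substream
per generator) make every output bitwise reproducible; pipeline outputs
embed the seed and a SHA-256 configuration fingerprint.

## Known limitations

* Energies and couplings are inputs (or synthetic); the package computes
  no electronic structure, no diabatization, and no polarizable-embedding
  environment shifts. The ~300 cm⁻¹ differential environmental
  stabilization between the sites is outside its scope.
* The kinetic model has no excitation-energy-transfer (Q_y → S₁) channel;
  an extra sink edge can emulate one but no microscopic EET rate is
  computed.
* The intrinsic 4 ns decay and 5 ps exchange time are canonical defaults,
  not fitted quantities; the pipeline logs a warning naming them (and the
  overlap radius) on every run.
* CI coverage statements assume independent snapshots; block-correlated
  data need a block-bootstrap the package does not implement.
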