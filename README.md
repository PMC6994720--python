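# ctquench

Charge-transfer (CT) quenching analysis for plant light-harvesting antenna
complexes, centred on the major complex LHCII of Photosystem II.

Under excess light, plants dissipate chlorophyll excitation through
nonphotochemical quenching. One candidate mechanism is electron transfer
from a carotenoid to an adjacent chlorophyll a — in LHCII, from lutein to
Chl *a612* (site L1) or Chl *a603* (site L2) — followed by fast charge
recombination. `ctquench` implements the complete analysis chain for this
mechanism:

1. **Fluctuation-based Marcus parameters** (`ctquench.marcus`). From an
   ensemble of per-snapshot vertical energies of the locally excited (LE)
   state Chl\* Q_y and the CT state Lut⁺Chl⁻, the adiabatic free energy of
   each state, the driving force and the reorganization energy follow from
   linear response:

       G_X = ⟨E_X⟩ − σ_X²/(2 k_B T)        (X = LE, CT)
       ΔG  = G_CT − G_LE
       λ   = σ_ΔE²/(2 k_B T),   ΔE = E_CT − E_LE  (per snapshot)

   The charge-separation rate is the classical Marcus expression

       k_CS = (2π/ħ) V² (4π λ k_B T)^(−1/2) exp[−(ΔG + λ)²/(4 λ k_B T)]

   with the electronic coupling V entering as the ensemble RMS. Reverse
   rates follow from detailed balance, k_rev = k_CS·exp(ΔG/k_BT).

2. **Coarse-grained excitation kinetics** (`ctquench.kinetics`). A
   five-state network — a pool of six chlorophylls in fast exchange with
   a612 and a603, each of which feeds its CT state — with three absorbing
   sinks (intrinsic Chl decay, recombination out of each CT state). The
   mean excitation lifetime has the closed form τ = 1ᵀ(−K)⁻¹p₀; matrix
   exponential propagation and a Gillespie jump simulator serve as
   independent oracles. A ΔG₁ scan quantifies how the protein can switch
   quenching on and off by tuning the CT-state energy.

3. **Geometric descriptors and variance decomposition**
   (`ctquench.descriptors`). Bond-length alternation (BLA = mean single −
   mean double bond length) along four conjugation paths, a simplified
   inter-pigment overlap of atom-centred spheres (closed-form lens
   volumes), the lutein position in the chlorin-ring frame, and a
   hierarchical OLS decomposition attributing CT-energy variance to the
   intramolecular (BLA) block first and the intermolecular block
   incrementally.

4. **Synthetic data** (`ctquench.synthetic`). No trajectory data ship with
   the package; a calibrated generator emulates them. Its defaults
   reproduce, in population, the reference ensemble statistics of the two
   lutein sites (state means; λ = 5405/5052 cm⁻¹; ΔG = −82/+951 cm⁻¹;
   coupling RMS 240/279 cm⁻¹ for L1/L2), plus idealized dimer geometries
   with exactly constructed BLA and descriptor tables with controlled
   variance shares.

## Worked example

Solve the default quenching network (Marcus rates recomputed from the
reference couplings, reorganization energies and driving forces at 300 K)
and scan the L1 driving force:

```sh
$ ctquench kinetics lifetime --scan dg1=-100:1500:100 --out out/
tau = 277.1 ps; fractions {'intrinsic': 0.0669..., 'rec_CT1': 0.9041..., 'rec_CT2': 0.0289...}
dG1 crossing 2000 ps: 839.6002240515743
```

The complex decays in 277 ps — deep quenching compared with the ~4 ns
intrinsic chlorophyll lifetime — with 90% of the excitation drained
through the Lut1⁺a612⁻ CT state and under 3% through Lut2. The scan table
(`out/dg_scan.csv`) shows the switch behaviour:

```
 dg1_cm1  k_cs1_ns      tau_ps  frac_CT1  frac_CT2
  -100.0 35.218629  265.358467  0.908317  0.027684
   200.0 17.039465  557.727140  0.803525  0.059200
   700.0  4.649358 1655.317418  0.410124  0.177516
  1200.0  1.135431 2577.315696  0.079658  0.276904
```

Raising ΔG₁ from −82 cm⁻¹ toward +700…+840 cm⁻¹ slows charge separation
enough to restore a ~2 ns lifetime: a modest change in the CT-state
energy, well within the protein's electrostatic reach, toggles the
complex between light-harvesting and quenching regimes.

The full pipeline — generate ensembles, estimate Marcus parameters from
them, solve the kinetics, compute descriptors and the regression — runs as

```sh
$ ctquench run --seed 0 --out out/
tau_complex = 323.4 ps
  intrinsic: 0.079
  rec_CT1: 0.899
  rec_CT2: 0.022
...
```

Here the lifetime differs from 277 ps because the kinetic stage uses λ̂
and ΔĜ *estimated* from one 240-snapshot synthetic replicate; the
fluctuation estimators carry substantial sampling noise at that size (see
`docs/methods.md`).

As a library:

```python
from ctquench import MarcusParams, marcus_rate, build_network, mean_lifetime

k1 = marcus_rate(MarcusParams(coupling=240, reorganization=5405, driving_force=-82))
k2 = marcus_rate(MarcusParams(coupling=279, reorganization=5052, driving_force=951))
res = mean_lifetime(build_network(k1, k2, dg1=-82, dg2=951))
print(round(res.tau_ps, 1), round(res.fractions["rec_CT1"], 3))  # 277.1 0.904
```

## Layout

```
src/ctquench/
  constants.py    physical constants in wavenumber units
  synthetic.py    calibrated generators (ensembles, structures, tables)
  marcus.py       fluctuation estimators and Marcus rates
  kinetics.py     quenching network, lifetime solvers, oracles
  descriptors.py  BLA, density overlap, ring frame, regression
  io.py           CSV/PDB/YAML formats
  pipeline.py     end-to-end driver
  cli.py          `ctquench` command-line interface
```
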