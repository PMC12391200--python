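# discbiphasic

Regional biphasic (poroelastic) characterization of cervical
intervertebral disc tissue as a tested, end-to-end pipeline:

* **Confined-compression theory** — closed-form series solutions for
  step/ramped creep and ramp-and-hold stress relaxation of a laterally
  confined cylindrical specimen draining through one face
  (`biphasic_core`), validated against an independent finite-difference
  consolidation solver (`consolidation_fd`).
* **Per-specimen estimation** — swelling pressure from the relaxation
  equilibrium load over the 19.63 mm² specimen area, and (aggregate
  modulus `H_A`, hydraulic permeability `k`) by trust-region
  least-squares on the creep trace in log-parameter space (`creep_fit`).
* **Composition** — porosity from buoyancy weighings and the solid
  volume fraction used by the FE model (`composition`).
* **Donnan swelling** — ideal osmotic pressure from fixed charge
  density, with deformation-dependent concentration (`donnan_swelling`).
* **Disc finite elements** — quasi-static u–p (displacement/pressure)
  trilinear hexahedral solver for an idealized three-region half-disc
  (nucleus pulposus, annulus fibrosus, cartilaginous endplates) under
  ramped unconfined compression, with and without Donnan swelling;
  validated against the classical unconfined-compression series solution
  for a homogeneous cylinder (`disc_fem`).
* **Synthetic cohorts** — fully reproducible generator of specimen
  geometry, ground-truth parameters, quantized (1 µm / 1 mN) DMA traces
  and buoyancy weights (`synth_experiment`).
* **Regional statistics** — one-way ANOVA, pairwise Welch t tests with
  Bonferroni–Holm adjustment, pooled Pearson correlations with porosity,
  and the pipeline orchestration (`cohort_pipeline`).

## Command line

```bash
# generate a synthetic dataset (default cohort: AF 16 / NP 10 / CEP 10)
discbiphasic simulate --out data/ --n-af 16 --n-np 10 --n-cep 10 --seed 17

# fit every specimen; write a cohort CSV
discbiphasic fit --traces data/ --out fits.csv

# full pipeline: fits + porosity merge + regional statistics
discbiphasic analyze --data data/ --out results/

# three-region disc FE simulation (biphasic or biphasic-swelling)
discbiphasic fem --config examples/disc.yaml --out fem_out/
```

A dataset directory contains `specimens/<id>.json` sidecars,
`traces/<id>_relaxation.csv` and `traces/<id>_creep.csv`
(columns `time_s, displacement_um, force_mN`; instrument conventions),
`weights.csv` and `ground_truth.csv` (synthetic data only).

An example FE config:

```yaml
geometry: {ap_depth: 15.0, lat_width: 20.0, disc_height: 6.0, cep_thickness: 0.9}
materials:
  NP:  {HA_MPa: 0.44, nu: 0.2, k0_e-4mm4Ns: 2.96, phi_s0: 0.127, fcd_mM: 182.2}
  AF:  {HA_MPa: 0.57, nu: 0.2, k0_e-4mm4Ns: 2.75, phi_s0: 0.183, fcd_mM: 135.5}
  CEP: {HA_MPa: 1.19, nu: 0.2, k0_e-4mm4Ns: 1.93, phi_s0: 0.307, fcd_mM: 286.7}
protocol: {axial_strain: 0.10, ramp_duration: 10000.0, hold_until: 400000.0}
swelling: true
resolution: 8
```

Outputs: a `peak_table.csv` of region-wise peak von Mises stress, fluid
pressure, fluid flux and Lagrange strains at end-of-ramp and
near-equilibrium, plus legacy-ASCII VTK field snapshots.

## Conventions

All internal computation is SI (m, s, Pa, N); reporting units
(MPa, kPa, 10⁻¹⁶ m⁴ N⁻¹ s⁻¹ ≡ 10⁻⁴ mm⁴ N⁻¹ s⁻¹, µm, mN) appear only at
I/O boundaries. Compression is positive in the 1-D confined-compression
modules; the FE solver uses the usual tension-positive convention
internally and reports peak magnitudes.
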