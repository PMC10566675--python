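# tpcvibe

Coupled simulation/measurement analysis of a fixed-base resonant bone
structure: a multi-material tetrahedral finite-element modal solver with
material sweeps, uniform scaling and component ablation, plus a
tap-excitation spectral pipeline and a mode-matching stage that compares
measured amplitude maps with simulated surface-normal displacement.
Everything runs on synthetic meshes and synthetic recordings with known
ground truth.

## Modules

| module | what it does |
| --- | --- |
| `tpcvibe.geometry` | labeled tet meshes (T4/T10): Gmsh MSH 4.1 + legacy VTK IO with CSV label sidecars, scaling, component removal, fixed-base node selection, boundary-surface extraction |
| `tpcvibe.modal_fem` | isotropic linear-elasticity stiffness/consistent-mass assembly (exact for affine elements), shift-invert Lanczos for the lowest modes, MAC mode tracking, material sweeps, surface-normal displacement, strain-energy fractions, HDF5/CSV persistence |
| `tpcvibe.tap_spectra` | tap-onset detection, cross-correlation-aligned coherent summation, per-channel power spectra normalized at 15 kHz, linear-domain averaging, prominence-based peak picking, per-location/mic amplitude maps |
| `tpcvibe.mode_matching` | tap-location-to-surface mapping, Spearman spatial correlation against normal-displacement fields, order-preserving peak-to-mode-range matching, left/right frequency offsets |
| `tpcvibe.synthetic_data` | structured beam and multi-component toy meshes on a welded lattice (conforming by construction), modal-superposition tap-recording synthesis with ground-truth bundles |
| `tpcvibe.cli` | `tpc` command-line pipeline |

## CLI

All subcommands take a YAML config (`-c`); unknown keys are rejected with
exit code 2. Outputs embed the config hash and seed, so reruns with the
same config are bit-identical.

```sh
tpc synth    -c config.yaml   # toy structure -> WAV recordings + manifest + truth
tpc simulate -c config.yaml   # modal solves per scale factor / ablation
tpc sweep    -c config.yaml   # factorial material sweep
tpc analyze  -c config.yaml   # recordings -> spectra, peaks, amplitude maps
tpc match    -c config.yaml   # peaks vs simulated mode ranges, L/R offsets
```

A minimal round trip:

```yaml
# synth.yaml
seed: 1
output_dir: out/synth
modes: 12
```

```yaml
# analyze.yaml
seed: 1
output_dir: out/analysis
spectra:
  manifest: out/synth/manifest.csv
  window_s: 0.25
  refractory_ms: 400
```

```sh
tpc synth -c synth.yaml && tpc analyze -c analyze.yaml
```

## Notes on conventions

- Coordinates are stored in meters; readers accept `unit="mm"`.
- Quadratic (10-node) tets are the default element; linear meshes can be
  promoted with `geometry.to_quadratic`. Element matrices assume
  straight-sided (affine) tetrahedra and are then integrated exactly.
- Constraints are imposed by dof elimination; eigensolves use a seeded
  start vector and are deterministic for a fixed mesh and materials.
- Spectra are averaged in the linear power domain; peak frequencies are
  nearest-bin readouts (the bin width is recorded in outputs).
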