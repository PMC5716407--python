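# protondose

Simplified Monte Carlo (SMC) and pencil-beam (PBA) proton dose engines on
heterogeneous voxel phantoms, used to compute LET-dependence correction
factors for solid-state (MOSFET-type) in vivo dosimetry.

Both engines consume a measured/synthetic broad-beam depth-dose curve (the
ionization-chamber truth, DD) and a depth-output curve (the LET-suppressed
detector response, DO):

- **SMC** (`protondose.smc`): tracks individual protons characterised by
  position, direction and residual range; energy loss via the
  water-equivalent model (step length x relative stopping power), deposits
  read off the depth curve at the depth matching the residual range, Highland
  multiple-Coulomb-scattering kicks per step. Every trajectory is scored
  twice (DD and DO), so the two grids are exactly paired.
- **PBA** (`protondose.pba`): a regular grid of entrance pencils, each
  looking up the depth curve along its own straight axis and spreading as a
  single lateral Gaussian — fast and deterministic, but blind to lateral
  heterogeneity.

The correction factor at a point is the ratio of the computed dose grid to
the computed output grid there (`protondose.correction`); multiplying the
raw detector dose by it removes the LET dependence. Supporting modules
provide materials/Bethe LET (`materials`), Bragg/SOBP curve synthesis and
the calibrated response model (`curves`), voxel phantoms including a
synthetic heterogeneous head-like fixture (`phantoms`), and reproducible
end-to-end experiments (`experiments`).

## CLI

```sh
protondose gen-curves --energy 190 --sobp 50 --out-dd dd.csv --out-do do.csv
protondose gen-phantom --kind head --seed 7 --out phantom
protondose run-smc --phantom phantom --dd dd.csv --do do.csv \
    --range 237.6 --sobp 50 --shifter 7.5 --n 1e6 --seed 7 --out grids.h5
protondose run-pba --phantom phantom --dd dd.csv --do do.csv \
    --range 237.6 --sobp 50 --shifter 7.5 --out pba.h5
protondose correct --grids grids.h5 --points points.csv --method smc --out results.csv
protondose experiment bragg
protondose experiment points --seed 1 --n 5e5
```

Curves are two-column CSV with a metadata header; phantoms are a flat raster
plus JSON sidecar; grids are HDF5 with geometry attributes.

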