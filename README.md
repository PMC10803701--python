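# gridspect

Digital phantoms with grid-modulated activity for quantitative SPECT, plus a
simplified simulation/reconstruction chain to characterize them.

3D-printed phantoms can fake non-uniform activity distributions with a single
stock solution: a periodic grid of solid walls inside a container reduces the
local fillable volume, so the imaged concentration is modulated by the
fillable-volume fraction (FVF) of the grid, provided the grid spacing stays
well below the scanner resolution. `gridspect` is a digital twin of that
workflow:

* **gridgen** — parametric wall grids, containers, FVF accounting three ways
  (analytic, voxel counting, mass/density), binary STL export.
* **phantoms** — grid spheres in a Jaszczak-type cylinder, two-compartment
  kidneys (cortex / grid medulla / cold pelvis), two-lobe thyroids with
  hot-spot voids; `grid_resolved` mode (walls as geometry) or
  `compartment_averaged` mode (FVF-scaled concentrations); voxelized
  activity and attenuation maps.
* **projector** — rotation-based parallel-beam forward model with
  attenuation, distance-dependent Gaussian collimator response, system
  sensitivity and Poisson noise. Forward and backprojection are exact
  adjoints. Primary photons only (ideal scatter rejection).
* **recon** — OS-EM with attenuation compensation, optional resolution
  recovery (PSF in the system model), Gaussian post-filter, and conversion
  to MBq/mL via a simulated calibration factor.
* **metrics** — modulation contrast C_M, C_M-vs-FVF regression, activity
  recovery coefficients, threshold–volume curves, coronal profiles, MIPs.
* **microct** — synthetic micro-CT of printed grids with injectable printing
  defects; segmentation by moment-preserving (Tsai) thresholding, 3×3×3
  morphological cleaning and shell exclusion via an analytic sphere fit;
  grid volume and central/peripheral uniformity metrics.
* **experiments** — end-to-end sphere / kidney / thyroid experiment runners
  with acquisition presets and seeded noise.

## Quantitative reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline numbers from scratch (about 3–4 minutes on one CPU):
the Pearson r of the C_M–FVF fit across grid spheres, recovery coefficients
of uniform 130/190 mL spheres with and without resolution recovery, kidney
phantom recoveries (%), and the thyroid correct-volume threshold (% of the
image maximum).

## CLI

```bash
gridspect run spheres --seed 1 --out out/           # C_M vs FVF experiment
gridspect run kidneys --seed 1 --out out/           # recovery + profiles
gridspect run thyroids --seed 1 --out out/          # threshold-volume curves
gridspect microct verify --fvf 0.48 --uniform-scale 0.05
gridspect recon --proj proj.nii.gz --mu mu.nii.gz --rr --out recon.nii.gz
```

## Conventions and limitations

* Arrays are `(z, y, x)`; lengths in mm, volumes in mL, activity in MBq/mL,
  attenuation in 1/cm. Volumes read/write NIfTI.
* The scatter-free projector stands in for full Monte Carlo transport;
  reconstruction without a scatter term is equivalent to a perfect scatter
  correction. Organ shapes are procedural (superellipsoid kidney with cone
  medulla cluster and cap pelvis; two-ellipsoid thyroid), not anatomical
  templates. Collimator response constants and orbit radii are presets,
  tunable within physical ranges; matrix, pixel size, angle counts, times,
  iteration/subset counts and the 8.8 mm post-filter follow the reference
  protocol.
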