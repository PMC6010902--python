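# nanoholo

A synthetic, fully self-contained re-implementation of a hard X-ray
nanoholotomography neuroimaging pipeline:

1. **phantom** — 3D brain-tissue phantoms (neuropil background, ellipsoidal
   somata with nucleus / nuclear envelope / nucleolus compartments), paired
   ground-truth labels, blur/noise/binning degradations, step-edge targets
   for resolution estimation, and a synthetic H&E-style RGB image.
2. **holography** — acquisition geometry (magnification `M = (D1+D2)/D1`,
   Fresnel-scaled effective distances, photon budgets), paraxial Fresnel
   propagation of multi-distance in-line holograms with Poisson noise,
   flat-field normalization + magnification alignment, weak-object
   contrast-transfer-function (CTF) phase retrieval, and filtered back
   projection.
3. **detection** — multi-scale 3D Hessian (vesselness) filtering with the
   reference parameters (α = 0.5, β = 0.1, γ = 60 on 8-bit-scaled data,
   radii 15–25 step 2, threshold 0.01), object-size and border filtering.
4. **levelset** — sparse-field level-set active contours (Chan–Vese-type
   region force + ζ-weighted mean-curvature smoothing, numba-accelerated
   narrow band): fully automated two-step segmentation (slice-wise 2D then
   3D), seeded slice-propagating semi-automated mode, and running-mean
   region growing for subcellular structures.
5. **metrics** — CNR from a two-Gaussian histogram fit, edge-based nMTF
   resolution (10% crossing, half-period convention), object sensitivity
   S = TP/T, elliptical curvature R = a²/b, NCC translation registration
   with subvoxel peak fit, running median over slices, histology color
   transfer.
6. **io_cli** — TIFF / MHD+RAW volume I/O, strict YAML configuration, the
   hierarchical `run` pipeline (prescan → ROI selection → fine scan →
   segmentation → metrics report + provenance manifest), and the CLI.

Everything is generated programmatically; no external data are required.
Voxel convention: 0-based `(z, y, x)` indices, isotropic spacing in nm.

## CLI

```bash
nanoholo --help
nanoholo simulate-phantom --config cfg.yaml --out vol.tif --labels-out lab.tif
nanoholo simulate-holo    --config cfg.yaml --phase phase.tif --out holo.tif
nanoholo retrieve-phase   --holo holo.tif --out phase.tif
nanoholo reconstruct      --sinogram sino.tif --out vol.tif
nanoholo detect           --volume vol.tif --out mask.tif --gamma 0.235
nanoholo segment          --volume vol.tif --out labels.tif --mode auto
nanoholo evaluate         --volume vol.tif --out report.json
nanoholo render-hne       --volume vol.tif --slice 10 --out slice.png
nanoholo run              --config cfg.yaml
```

A config file is the YAML form of `nanoholo.config.PipelineConfig`
(sections `phantom`, `geometry`, `frangi`, `sfm`, plus `roi_shape`,
`prescan_bin`, `output_dir`, `seed`); unknown keys are rejected. Write a
template with:

```python
from nanoholo.config import PipelineConfig
PipelineConfig().to_yaml("cfg.yaml")
```

Note on `gamma`: the structureness cutoff is quoted for 8-bit-scaled data;
for unit-range phantoms use `FrangiParams.for_gray_range(1.0)`
(γ = 60/255 ≈ 0.235).

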