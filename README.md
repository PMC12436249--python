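# cellmech

Quantitative image analysis for cellular mechanotransduction studies.
`cellmech` is aimed at labs measuring how cells sense and exert mechanical
force: it turns multichannel 2D fluorescence micrographs into three
per-cell readouts —

1. **Nuclear/cytoplasmic (N/C) ratio** of a shuttling transcription factor
   (e.g. YAP): nuclei segmented from DAPI by Canny edge detection, the
   cytoplasmic signal read from a 5-pixel ring just outside each nucleus,
   and cell area from thresholded F-actin.
2. **Three-cube FRET index** of a molecular tension sensor (e.g. in
   talin), with spectral bleed-through calibrated from single-fluorophore
   samples and averages restricted to focal adhesions:

   `FRET index = (I_f − dL·I_d − aL·I_a) / I_a = F_c / I_a`

   where I_f, I_d, I_a are the corrected FRET, donor and acceptor channel
   intensities, and dL, aL are the donor- and acceptor-leakage fractions
   (regression slopes on donor-only / acceptor-only cells). For a tension
   sensor the index falls as force rises.
3. **Traction stresses** by regularized Fourier-transform traction
   cytometry (FTTC): bead displacements between loaded and relaxed
   (post-lysis) gel images estimated by two-pass PIV, then inverted
   per wavevector under the Boussinesq half-space model with zeroth-order
   Tikhonov regularization, `t(k) = (GᵀG + λ²I)⁻¹ Gᵀ u(k)`, with
   E = 10 kPa, ν = 0.5 and λ = 1e-4 as typical settings.

Every stage is backed by a ground-truthed synthetic-scene generator
(`cellmech.synthetic`) that renders cell triples, FRET channel triples
with known efficiency and leakage, and bead image pairs deformed by known
force-balanced traction fields — so the whole pipeline is testable against
known truth. See `docs/methods.md` for models, parameters and design
choices.

## Worked example

Render a scene with three cells whose true N/C ratio is 2.0, run the full
pipeline (segmentation, cell-free-ROI background subtraction, ring
construction, measurement):

```python
import numpy as np
from cellmech import SceneConfig, NoiseParams, make_cell_scene
from cellmech.ncratio import nc_ratio_pipeline, measurements_to_frame
from cellmech.synthetic import random_cell_specs

cells = random_cell_specs((512, 512), 3, np.random.default_rng(0), nc_ratio_true=2.0)
cfg = SceneConfig(shape=(512, 512), seed=0, cells=cells,
                  noise=NoiseParams(gaussian_sd=15, poisson=True, background=20))
dapi, factin, yap, truth = make_cell_scene(cfg)
df = measurements_to_frame(nc_ratio_pipeline(dapi, factin, yap))
print(df[["label", "nuclear_area_um2", "cell_area_um2", "nc_ratio"]].round(3))
```

prints

```
 label  nuclear_area_um2  cell_area_um2  nc_ratio
     1            78.691        522.316     2.004
     2            78.902        522.738     2.003
     3            79.113        523.478     2.001
```

Each row is one cell: nuclear area in µm² (20×12 px semi-axis ellipse at
0.325 µm/px ≈ 79.7 µm² true), whole-cell area from F-actin, and the
measured N/C ratio, recovering the configured 2.0 to within 0.2% despite
Poisson + Gaussian camera noise.

The same flows are available from the shell:

```
cellmech simulate cell --seed 3 --n-cells 3 --out scene/
cellmech segment --dapi scene/dapi.tif --factin scene/factin.tif --pixel-size 0.325 --out seg/
cellmech nc-ratio --signal scene/yap.tif --dapi scene/dapi.tif --factin scene/factin.tif \
    --pixel-size 0.325 --out nc.csv
cellmech fret-index --donor d.tif --fret f.tif --acceptor a.tif \
    --calibration calib.json --pixel-size 0.325 --ia-floor 100 --out fret/
cellmech tfm --loaded loaded.tif --relaxed relaxed.tif --mask mask.tif \
    --pixel-size 0.103 --youngs 10000 --out tfm/
```

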