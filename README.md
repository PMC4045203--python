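# cryoclem

High-precision registration of fluorescence and electron cryo-microscopy
images using two independent kinds of fiducial beads, with a per-object
error budget.

## The problem

Electron cryo-tomography can resolve macromolecules inside vitrified whole
cells, but first the event of interest — say, a fluorescently labelled virus
particle — has to be found on a 3 mm grid. Fluorescence cryo-microscopy
(cryoFM) provides that targeting, yet a naive overlay of FM and EM images is
only accurate to roughly the width of the optical point spread function
(~450 nm). This package implements a bead-based workflow that brings the
correlation down to tens of nanometres and, crucially, attaches an
uncertainty estimate to every predicted position:

1. **Localization.** Point-like emitters are detected by an iterative
   CLEAN-style peak search on a background-flattened image and refined by a
   Levenberg–Marquardt fit of a 2D Gaussian with a linear background. The
   covariance of the fit gives the localization accuracy of each object,
   σᴱ.
2. **Channel alignment.** TetraSpeck microspheres fluoresce in the red,
   green and blue channels, so any spot present in all three (within a
   500 nm coincidence radius) identifies itself as an alignment fiducial.
   The global drift between channels is the mean of the per-bead
   displacements; their standard deviation is the alignment accuracy σᴬ.
3. **FM→EM transform.** Blue, electron-dense FluoSpheres are visible in
   both modalities and serve as control points for a linear conformal
   (similarity) transform, fitted in closed form (Procrustes/Umeyama). Its
   accuracy σᶜ is estimated by leave-one-out: refit without each bead in
   turn, predict it, and average the prediction displacements.
4. **Error budget.** The three terms are independent, so the total
   uncertainty of a predicted EM position is

   σᵀ = √( (σᴬ)² + (σᶜ)² + (σᴱ)² )

   reported per event, and usable as the radius of a search circle on the
   EM image.

A synthetic-scene generator (`cryoclem.simulate`) renders tri-channel fields
of TetraSpecks, FluoSpheres and dim virus-like emitters with
pixel-integrated Gaussian PSFs, Poisson noise, per-channel drift and an
EM-side similarity transform with positional jitter — so the entire pipeline
is testable without microscope data.

## Worked example

Simulate a field with an extreme stage drift (red channel displaced by
(3098, 787) nm versus blue), align the channels through the coarse manual
pick that such a drift requires, and correlate to the EM frame:

```bash
cryoclem simulate --preset fig2-large-shift --seed 42 --out scene
cryoclem align-channels --red scene/red.tif --green scene/green.tif \
    --blue scene/blue.tif --threshold 45 \
    --rough-pick-red 22759,12466 --rough-pick-green 20104,11836 \
    --rough-pick-blue 19651,11678 --out aligned
```

```
INFO cryoclem: 10 TetraSpeck triple(s) matched
INFO cryoclem: red vs blue: shift (3094.7, 789.6) nm, sigma_A = 11.10 nm (n=10)
INFO cryoclem: green vs blue: shift (445.9, 146.0) nm, sigma_A = 10.66 nm (n=10)
```

The injected drifts — (3098, 787) nm red and (449, 148) nm green — are
recovered to a few nanometres, with an alignment precision σᴬ ≈ 11 nm from
10 beads. Correlating the aligned blue FluoSphere positions with their EM
coordinates and budgeting each green event:

```bash
cryoclem correlate --fm-points fm_table.csv --em-points scene/em_points.csv \
    --shift-json aligned/shift_green.json --out corr
```

```
INFO cryoclem: transform: scale 28.2204, rotation 0.2967 rad, sigma_C = 48.47 nm (n=10)
INFO cryoclem: event green010: sigma_T = 53.5 nm
INFO cryoclem: event green011: sigma_T = 52.2 nm
```

The fitted scale 28.22 is exactly the ratio of the FM (103 nm) and EM
(3.65 nm) pixel sizes used by the generator, and each virus-like event gets
its own total error σᵀ: here ~52–54 nm, dominated by σᶜ (which includes the
FM localization error magnified 28× into the EM frame) and the dim event's
σᴱ. A single budget can also be computed directly:

```bash
$ cryoclem report --event-id case1 --sigma-a 7.75 --sigma-c 12.2 --sigma-e 49
case1: sigma_T = 51.1 nm (A=7.75, C=12.2, E=49.0)
```

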