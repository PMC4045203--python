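# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `cryoclem`, including the places where the design was
genuinely open and a choice had to be fixed.

## Coordinate and unit conventions

Images are 2D arrays indexed `(row, col)`; continuous positions are
`(x, y)` with `x = column`, `y = row`, 0-based, and the centre of pixel
`(r, c)` at `(x=c, y=r)`. All positions crossing a module boundary are in
nanometres. This matters because the pipeline mixes frames with pixel sizes
two orders of magnitude apart (fluorescence ≈103 nm/px, EM 2.10–3.65 nm/px);
carrying nm everywhere makes the FM→EM composition unit-safe. MRC input is
read-only (via gemmi); all outputs are TIFF, CSV or JSON.

## Spot detection and localization (σᴱ)

**Detection** runs on a background-flattened copy of the image (original
minus a Gaussian blur of σ = 2× the fit window, ≈22 px at defaults — much
broader than the PSF, so point sources survive while illumination gradients
and cell-body glow are removed). The peak search is an iterative CLEAN-type
loop: take the global maximum, fit a plain Gaussian in its window and
subtract the fitted model (gain 1); if that fit fails, mask the window
instead. The loop stops when the residual maximum drops below the detection
threshold. Candidates closer than one window to an accepted candidate, or
nearer than half a window to the border, are not accepted.

**Localization** fits
`A·exp(−((x−x₀)²/(2σx²) + (y−y₀)²/(2σy²))) + b₀ + b₁x + b₂y`
over an 11×11 px window (≈ ±2.9 PSF σ at 103 nm/px — wide enough to
constrain the background plane) by Levenberg–Marquardt. Widths are fitted
independently per axis because the cryo-stage integration times (seconds)
can smear the PSF anisotropically; the anisotropy statistic is
`1 − min(σx,σy)/max(σx,σy)`.

Standard errors of the centre come from the Jacobian-based covariance of
the converged solution scaled by the residual variance — an unweighted
least-squares error model with no camera gain term. The scalar event
localization accuracy is the RMS of the two axes,
`σᴱ = √((sₓ² + s_y²)/2)`, chosen because downstream reports need a single
number and RMS treats the axes symmetrically.

A fit is rejected (and the spot excluded, with a log entry) when the solver
fails, the centre leaves the window, amplitude or widths are non-positive,
a fitted width exceeds the window, or the estimated position uncertainty
exceeds the window extent — an "uncertainty" larger than the search region
carries no information and in practice flags noise peaks.

Monte-Carlo calibration (tests): over 500 replicates of a 450 nm-FWHM
emitter with 1500 photons on a 200-photon background, the mean reported
standard error matches the empirical scatter of fitted centres to within a
few percent. At very high photon counts the unweighted error model
underestimates mildly (the Poisson noise is then strongly heteroscedastic);
this is inherent to the least-squares error model and documented rather
than corrected.

## Multi-channel alignment (σᴬ)

The inter-channel displacement is modelled as a **pure global translation**:
a vitrified specimen is a rigid body, a single detection path rules out
rotation, and local chromatic differences are neglected. TetraSpeck beads
are identified by triple-channel coincidence: greedy nearest-neighbour
association seeded from the blue channel in decreasing intensity, accepting
only triples complete within a 500 nm radius, then discarding both members
of any accepted pair whose blue positions are closer than 500 nm (crowded
beads bias the statistics). Blue is the reference channel because the blue
FluoSpheres carry the FM→EM correlation, so aligning red/green onto blue
keeps the error chain shortest. Shifts above the 500 nm radius require a
coarse manual pre-alignment: one bead picked in each channel, whose offsets
bootstrap the automated matching.

The shift estimate is the mean per-bead displacement; σᴬ is the per-axis
sample standard deviation (ddof = 1), scalarized as the mean of the X and Y
components for the σᵀ roll-up. An outlier pass drops any bead whose
displacement deviates from the **jackknifed** mean of the others by more
than 3 of their per-axis standard deviations, on either axis, in a single
pass. The jackknife matters at the small bead counts typical here (3–20): a
single gross mismatch inflates a pooled SD enough to mask itself, whereas
it cannot contaminate the statistics of the remaining beads. On clean data
the rule is idempotent. Shifts estimated from fewer than 3 beads are
flagged low-confidence.

## FM→EM transform and leave-one-out accuracy (σᶜ)

The map between the aligned FM frame and the EM projection is a
**similarity transform** (uniform scale, rotation, translation): angle
preserving, which is what "conformal" requires, and sufficient because a
vitrified grid does not deform between microscopes (no
plastic-section shrinkage correction is needed). Reflection is excluded by
default — the common mounting does not flip the grid — but can be allowed
with an explicit flag, in which case the best-fitting improper map is
accepted and flagged. The fit is the closed-form Procrustes/Umeyama
solution; degenerate geometry (coincident points) is an error and
near-collinear control points produce a warning.

σᶜ is estimated honestly by leave-one-out: each control bead in turn is
excluded, the transform refitted, the bead's EM position predicted, and the
Euclidean displacement recorded; σᶜ is the arithmetic mean of the
magnitudes. By construction the in-sample residual RMS never exceeds σᶜ.
Note that σᶜ, measured in EM-frame nanometres, contains the FM-side picking
and localization error *magnified by the transform scale* (≈28× at the
5600× EM setting) on top of the EM-side picking jitter — which is why σᶜ of
tens of nm coexists with nm-scale FM localization.

Before fitting fiducials on real images, a high-pass filter with a smooth
70 px cut-off removes cell-scale background. It is implemented as a
Gaussian unsharp mask whose blur kernel has FWHM equal to the cut-off; the
original implementation's exact filter family is not recoverable, so the
choice is recorded here and the cut-off is configurable. The filter shifts
an isolated point source's centroid by < 0.01 px while attenuating
structures broader than ~200 px by > 80%.

## Error budget (σᵀ)

The three accuracies arise from disjoint measurements (TetraSpeck
displacements, FluoSphere leave-one-out, the event's own fit) and are
treated as independent, so they combine as a root sum of squares,
`σᵀ = √(σᴬ² + σᶜ² + σᴱ²)`, computed at full precision and rounded half-up
to 1 decimal (nm) only for presentation. σᵀ is homogeneous of degree 1,
monotone and permutation-symmetric in its components, and bounded between
the largest component and the component sum; these are tested as
properties.

## Synthetic scenes: what they emulate, and what they do not

The generator renders 256×256 px fields at 103 nm/px with three species:

| species     | channels        | photons/channel | emulates                      |
|-------------|-----------------|-----------------|-------------------------------|
| tetraspeck  | red+green+blue  | 40 000          | 200 nm 4-colour beads         |
| fluosphere  | blue            | 60 000          | 100 nm electron-dense beads   |
| event       | green           | 1 500           | a labelled virus particle     |

Defaults: 10 + 10 + 3 emitters (the workflow's recommended 5–15 beads of
each kind per field), PSF FWHM 450 nm (green/blue) and 560 nm (red),
background plane 200 photons with a mild gradient, pure Poisson noise
(optional Gaussian read noise, off by default — no camera statistics are
assumed), minimum emitter separation 1.2 µm, and per-bead channel jitter of
15 nm SD on red/green relative to blue — the residual local error that
makes σᴬ non-zero, set at the middle of the observed 5–33 nm alignment
envelope. The brightness ordering (FluoSphere > TetraSpeck ≫ virus) mirrors
the real samples; 1 500 photons puts the default virus event at
σᴱ ≈ 15–20 nm, and the dim-virus studies in the tests use 500 photons,
which lands σᴱ at the ~50 nm scale. Beads are rendered as PSF-convolved
points: the finite bead size is absorbed into the per-species effective
FWHM, matching how bead PSFs are measured in practice.

PSFs are **pixel-integrated** Gaussians (erf differences per axis), not
point samples — at 103 nm pixels under a 450 nm FWHM PSF the difference is
small but systematic, and integration is what a detector does. The EM side
is generated as `T(fm) + N(0, jitter²·I)` for the electron-dense species
only; the green event deliberately has no EM-side truth marker, mirroring
the real problem. Everything is reproducible bit-for-bit from the seed.

Not emulated: field-dependent chromatic aberration, stage drift *during*
an exposure, ice contamination and cellular clutter, detector gain/offset
structure, and EM image formation beyond optional flat disks. Passing tests
therefore demonstrate estimator correctness and calibration under the
assumed noise model, not robustness to every real-world artefact.

## Numerical and scale choices in the tests

Tests run on one CPU in well under a minute apart from the Monte-Carlo
calibrations (a few seconds each). Problem sizes: 500 replicates for the
σᴱ calibration, 1000 replicates for the leave-one-out oracle comparison
(5 fiducials, 10 nm jitter), 300 per bracketing setting for the σᶜ range
check, four full rendered scenes for the alignment envelope. The
leave-one-out oracle is an independent linear-least-squares route
(parameterized by `s·cosθ, s·sinθ, tx, ty`), agreeing with the SVD-based
fit to ~1e-7 relative — the two routes share no code. The similarity fit is
additionally cross-checked against `skimage.transform` at 1e-9 relative.

## Known limitations

- The least-squares error model (unweighted, residual-variance scaled)
  underestimates σᴱ by up to ~25–30% in the extreme high-SNR regime; a
  weighted or maximum-likelihood fit would fix this but is out of scope.
- The inverse-√N brightness law holds in the shot-noise-limited regime; on
  a strong background σᴱ improves *faster* than √N because the
  background-noise term falls as 1/N.
- A 4-point similarity fit spreads a single-point perturbation across all
  residuals (leverage ≈ 0.5); residual-based identification of a bad
  control point is only reliable from ~6–8 points.
- Detection near threshold on large fields produces occasional false
  positives; the workflow assumes an operator (or downstream filter)
  curates the event list, as in the manual targeting it reproduces.
- No affine or local warp correction: if the specimen does deform, σᶜ will
  absorb (and report) the model error, but the transform cannot correct it.
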