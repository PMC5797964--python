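# Methods

`oospindle` quantifies meiotic spindle morphogenesis in mouse oocytes from
three-channel 3D z-stacks: a bright-field channel showing the cell, a
microtubule-reporter channel (GFP-EB3 or SiR-Tubulin type) showing the
spindle, and an aMTOC-marker channel (mCherry-Plk4 or pericentrin type)
showing the acentriolar microtubule-organizing centres. Because oocytes
lack centrioles, spindle poles are organized by dozens of aMTOC foci that
are progressively *sorted* to the two poles and *clustered* into compact
pole structures during meiosis I; the package measures exactly that
process, together with spindle shape and microtubule turnover.

## Coordinate and unit conventions

All physical quantities are micrometres, axis order `(z, y, x)`, origin at
the volume corner, voxel centres at `(index + 0.5) * voxel_size`. The
default grid is 40 × 192 × 192 voxels at (1.0, 0.25, 0.25) µm — a 4:1
axially anisotropic sampling typical of spinning-disk stacks. Filter
parameters are specified in pixel units like the interactive tools they
mirror, but every reported distance, position and volume is physical.

## Segmentation chain

1. **Oocyte boundary** (bright-field): a local-variance filter turns
   cytoplasmic texture into high response and flat background into ~0; the
   256-bin histogram of the response is thresholded with the triangle
   method; the largest 26-connected component is kept and internal holes
   are filled. The variance window half-width (default 3, in units of the
   finest voxel edge) is scaled per axis so the boundary dilation it causes
   is physically isotropic.
2. **Spindle body** (microtubule channel): Gaussian smoothing with radius 2
   in-plane pixels — again scaled per axis so the blur is isotropic in µm
   rather than in voxels; on a 4:1 anisotropic grid a voxel-isotropic
   sigma would smear the spindle by ~2 µm axially and visibly degrade both
   the segmented surface and the recovered pole positions — followed by
   Kapur maximum-entropy thresholding of the histogram of in-mask voxels
   and retention of the largest 26-connected component.
3. **aMTOC spots** (marker channel): difference-of-Gaussians band-pass
   (sigmas 1.5 and 3 voxels, clipped at zero), max-entropy threshold of the
   in-mask response, 26-connected labeling, and a minimum-volume filter
   (default 0.1 µm³) to suppress single-voxel noise. Centroids are
   intensity-weighted on the DoG response.

Both automatic thresholds operate on 256-bin histograms built after a
linear min–max rescale of the considered voxels (the 8-bit convention of
classic ImageJ-style tools); thresholds are mapped back to
intensity units for binarization, and ties break toward the lower bin.

## Morphometry

Spindle **poles** are the extremities of the object's largest caliper
(Feret) diameter, computed exactly on boundary-voxel centres via the
convex hull (with an all-pairs fallback for tiny or degenerate objects)
with a lexicographic tie-break; **length** is the pole-to-pole distance.
**Widths** are slab-based: voxels are projected onto the pole axis and the
central width is twice the maximal radial distance within a slab of
fractional half-width 0.1 around the midpoint; each pole width uses the
slab covering the outer 10% of the axis, and the reported pole width is
the mean of the two. The slab fractions replace an interactive 3D
measurement with a reproducible surrogate and are configurable; widths are
maximal radial extents of the segmented surface, not intensity FWHMs.

Per-aMTOC metrics: minimum Euclidean distance to the two poles; the
**normalized position** — that distance divided by spindle length (0 at a
pole, 0.5 at the equator; values slightly above 0.5 are possible for
off-axis foci and are kept); and a signed **border distance** to the
nearest spindle surface voxel, negative inside. The per-oocyte **sorting
SD** is the sample (n−1) standard deviation of the normalized positions —
high for scattered aMTOCs, low once they are sorted to the poles — and is
flagged missing (NaN) below two aMTOCs. Clustering is summarized by the
aMTOC count and total volume per oocyte.

Reported aMTOC volumes are the volumes of the thresholded DoG support.
For foci near the diffraction limit this overstates the physical focus
volume (the segmented support includes the blur halo); counts, centroids
and relative volume comparisons are unaffected.

## Photometry and FRAP

Whole-cell intensities are totals of background-subtracted pixels inside a
circle of one fixed diameter shared by an entire compared batch (the mean
oocyte diameter), with background estimated as the median intensity
outside the oocyte mask; negatives clip to zero. Group ratios are ratios
of group means, reported with group sizes and SDs.

FRAP traces (one pre-bleach frame, then frames every 5 s for 125 s by
default) are normalized affinely so the pre-bleach value is exactly 1 and
the first post-bleach value exactly 0, making fits invariant to expression
level and camera gain. The recovery model is `F(t) = A (1 − exp(−k t))`
with t = 0 at the first post-bleach frame; the pre-bleach sentinel is
excluded from the fit. Fitting is bounded least squares with deterministic
multi-start over half-times of 10, 60 and 300 s, keeping the best residual
sum of squares; `t_half = ln 2 / k` exactly. The plateau A is fitted (not
fixed at 1) so an immobile fraction is representable, and bounded at 1.5
to guard against pathological extrapolation.

## The synthetic scene generator

No imaging data accompanies the analysis chain, so a generator provides
ground truth for every stage. A scene is: an oocyte sphere (default radius
20 µm, the grid spanning 40 × 48 × 48 µm — a scaled-down oocyte so the
default volume stays ~1.5 M voxels); a spindle that is either a
**ball** (equal-volume sphere, emulating early prometaphase) or a
**bipolar** solid of revolution with radius profile
`r(s) = R sin(pi s / L)` tapering to the poles (default L = 32 µm,
R = 8 µm, inside the 22–54 µm range of real meiosis-I spindles and giving
a 16 µm central width); and 0–40 aMTOC foci placed at controllable axial
fractions (scattered ~ U(0, 0.5), pole-sorted ~ U(0, 0.05)) with a radial
jitter bounded at 0.5 µm — kept small so the axial fraction remains an
accurate reference for the Euclidean normalized position (jitter/L
≈ 0.016) — and an optional minimum pairwise separation for detection
studies.

Rendering: the microtubule channel is background (40 counts) plus a
diffuse cytoplasmic reporter (15% of the 500-count spindle signal,
modulated by a smooth multiplicative mottle of 10% relative SD and ~1.5 µm
grain, emulating organelle exclusion of the soluble reporter — without it
the background histogram is a single spike and entropy-based thresholds
behave unlike on real images) plus uniform spindle signal, blurred by a
Gaussian PSF (sigma 0.8 µm axial, 0.3 µm lateral). aMTOC foci are rendered
as Gaussians whose per-axis sigma folds the PSF in analytically
(`sqrt(radius² + psf²)`), so each blob's integral has a closed form used
by the conservation tests. Bright field is a textured disc over the
oocyte. Noise is Poisson on expected counts followed by additive Gaussian
read noise (SD 10); setting the read-noise SD to 0 disables the whole
noise model for analytic checks. At the defaults the peak
signal-to-noise ratio is ≈ 500/√(540 + 100) ≈ 20. One seed drives
placement and noise; rendering is a pure function of the truth record.

What the generator does **not** emulate: spherical aberration and
depth-dependent PSF broadening, photobleaching, camera offset drift,
intensity gradients within the spindle, chromosomes, and the O-shaped
sub-structure of real pole aMTOC clusters. Passing recovery tests
therefore demonstrates correctness of the measurement chain on idealized
geometry at realistic sampling and noise, not robustness to every optical
artifact of real data.

## Numerical choices and degenerate inputs

- Histograms: 256 bins, min–max rescale; a constant region is a
  degenerate histogram and raises (or, for spot detection, yields zero
  objects).
- Boundary handling: whole-sample symmetric reflection for all filters,
  which conserves total intensity under Gaussian smoothing to float
  precision.
- Connectivity: 26-neighborhood throughout.
- Feret on a single-voxel object: coincident poles, zero length, a
  degenerate flag, and no downstream positional metrics.
- Empty width slabs raise rather than silently returning zero.
- FRAP fits require ≥ 5 post-bleach samples; a trace whose pre-bleach
  value does not exceed the first post-bleach value is a
  no-bleach-detected error.
- All batch outputs embed a SHA-256 hash of the configuration actually
  used; re-running a batch is byte-identical.

## Problem sizes used in the shipped studies

The test suite and the acceptance script regenerate everything they
measure: 1,000 (tests) / 400 (script) random histograms per threshold
oracle, 100/50 random blobs for the Feret oracle, 20/10 synthetic scenes
for geometry and detection recovery, 50/25 paired scenes for the sorting
statistic, and 200 simulated traces for the noisy FRAP study. These sizes
give stable statistics while keeping a full run in the low minutes on one
core.

## Known limitations

- Kapur's threshold on a tapered body sits below the 50% edge contour, so
  the segmented spindle carries a thin blur halo; length recovery is ~2%
  and surface Dice ~0.8 against the geometric truth at the default
  conditions.
- Spot volumes are support volumes (see above); absolute volumes of
  sub-micron foci are resolution-limited.
- aMTOC foci closer than the DoG resolution merge into one object — the
  documented behaviour of the detection chain, and biologically the same
  signature as clustering.
- The pipeline analyzes single time points; it does not track aMTOCs
  across frames or call the bipolarization time automatically.
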