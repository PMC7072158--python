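# Methods

## Scope and model

`pmbind` quantifies (i) plasma-membrane localization of a fluorescently
tagged protein from 2-D confocal images and (ii) its in-vitro membrane
binding from co-sedimentation densitometry and SPR. All image statistics
are ratios of regional mean intensities for a single cell; all SPR
analysis assumes a 1:1 Langmuir interaction between a protein analyte at
concentration [P] and a lipid-vesicle surface.

## Annulus procedure

Segmentation thresholds the image (Otsu default; a fixed threshold is
available for reproducing manual workflows), binarizes, fills holes (so a
dim nucleus cannot spawn an internal annulus), and keeps the largest
8-connected component (`segment_cells` iterates all components above a
minimum area when several cells share a frame). The plasma-membrane
annulus is the set difference between the cell mask and the same mask
eroded *n* times with a 3×3 square structuring element — one pixel of rim
per erosion, 8-connected, matching ImageJ's binary-erode semantics. The
classic protocol also duplicates and dilates the binary image, but only
the eroded mask enters the subtraction that defines the annulus, so the
dilated copy is not materialized here.

*n* defaults to `round(0.4 µm / pixel_size)` clipped to [2, 4]: the rim
should span roughly 400 nm — the optical-resolution scale of a confocal
membrane profile — at any zoom. The interior (eroded) region is the
cytoplasm by default; averaging *k* seeded square ROIs inside it is
available (`cytoplasm_mode="rois"`) to mirror the practice of sampling a
couple of cytosolic patches per cell, but the whole-interior mean is less
operator-dependent and is the default. Nuclei and puncta are not excluded
from the cytoplasm; no exclusion rule is part of the procedure.

%PM and the PM index are gain-invariant but not offset-invariant: adding a
constant to every pixel pulls %PM monotonically toward 50. Background
subtraction (mean outside the cell mask) is therefore available but off by
default, since the underlying protocol does not include it. The
dissociation index is oriented before/after, so displacement from the
membrane reads as an index above 1; the orientation is configurable
because the convention is an assumption.

## Synthetic data: what it emulates, and what not

The generator paints a filled ellipse (optional low-order harmonic
boundary perturbation for irregular outlines) with a uniform-width
membrane rim, diffuse cytosol, optional nucleus and intracellular puncta
(placed strictly inside the interior so vesicle staining cannot
contaminate the rim), over an additive camera offset. Noise follows the
standard fluorescence-camera model: Poisson on the expected signal, then
additive Gaussian read noise, clipped at zero. Time series relax the
membrane intensity exponentially toward the cytosolic level,
`M(t) = C + (M0 − C)·e^(−kt)`, optionally redistributing the lost signal
uniformly over the interior so total painted fluorescence is conserved.
Every generator takes an explicit seed; there is no global random state.

**Rim band definition.** `rim_metric="chebyshev"` (default) realizes the
rim as the band of pixels within `round(rim_width/pixel_size)` 8-connected
steps of the boundary — the same band an erode-and-subtract annulus
selects — so ground-truth metrics and pipeline measurements are
commensurable and parameter-recovery tests measure estimation error, not
band-definition mismatch. `rim_metric="euclidean"` paints a band of
uniform physical width instead; against it, the square-element annulus
over-erodes along diagonals (average Euclidean depth ≈ 1.12× the erosion
count) and %PM carries a systematic low bias of roughly 4 points at the
default geometry. That bias is intrinsic to square-element annulus
protocols on real images too, and the euclidean option exists to expose
it.

Defaults: 256×256 px at 0.1 µm/px (16-bit on export; acquisition bit depth
and pixel size of the original instrument are not public, so these are
stated assumptions), cell radius 8 µm, rim 0.4 µm, membrane 200 / cytosol
50 / background 5 AFU, Gaussian SD 2 AFU — SNR well above 10. Time series
default to 60 frames at 5 s (a 5-minute experiment). Sensorgram defaults
(k_a = 1e5 1/(M·s), k_d = 0.034 1/s → K_d = 340 nM, 150 s dissociation)
mirror the bench settings of the SPR assay the package targets.

Not emulated: 3-D/z-stacks, photobleaching, realistic PSF convolution,
cell motion, segmentation-confounding clutter. Passing recovery tests
therefore shows the estimator chain is unbiased and noise-stable under
this model, not that segmentation is robust to arbitrary real-world
imagery.

## Binding analytics

Percent binding is `100·pellet/(pellet+supernatant)`; the control
correction subtracts the control lane's raw percent and floors at zero —
"relative to control vesicles" is not formulaic in the source protocols,
so this simple difference is a documented assumption. The charge-matching
table defaults to the phosphate-count proxy (mono 1, bis 2, tris 3), the
only table consistent with the printed 5 ↔ 3.3 mol% design; a
physiological net-charge table (−3/−4/−6) is provided as an alternative.

Isotherm fitting uses `scipy.optimize.curve_fit` with data-driven starts
(`R_max ← 1.1·max(R_eq)`, `K_d ←` concentration nearest half of that),
positivity bounds, and a warning when the fitted `K_d` falls outside the
sampled concentration range (ill-conditioned design). `R_eq` extraction
averages the final 10% of the association phase (min 5 samples) — biased
low on non-plateaued curves, which is documented behaviour. Kinetic fits
assume the 1:1 model (the evaluation software behind published constants
is a black box; 1:1 is the standard assumption): per-curve
single-exponential fits initialised from log-linear slopes and
half-rise times, `k_d` averaged across curves, `k_a` from the
`k_obs`-vs-[P] regression slope. Standard errors are reported from the fit
covariance; replicate spread is a separate, caller-level concern.

## Statistics

SEM is `sd(ddof=1)/√n`, undefined (NaN, flagged) for singletons. One-way
ANOVA computes the classical F from explicit between/within sums of
squares; per-group flags against a reference come from Welch t-tests at
the caller's alpha, uncorrected by default to match single-threshold
figure-caption reporting (Bonferroni optional). Two-way ANOVA uses a type
II OLS decomposition with interaction; effects with numerically zero sum
of squares are reported as F = 0, p = 1 so noiseless additive or constant
data behave sensibly, and a zero residual with a real effect reports
F = ∞, p = 0.

## Numerical choices and problem sizes

Masks are 0/1 grids in row-major, 0-based pixel coordinates. Determinism
is bit-exact for fixed seeds. Test-suite simulations are sized for
interactive runs: 50 cells for %PM recovery (median absolute error
observed ≈ 0.02 points, bound at 2), 20 seeds × 10 frames for the
null dissociation series, 8-point isotherms, 3-concentration kinetic sets;
the full suite completes in well under a minute of compute.

## Known limitations

- Single 2-D section per cell; no touching-cell separation or tracking.
- Otsu can split rim-vs-interior rather than cell-vs-background on images
  whose cytosol is dimmer than the noise floor; a fixed threshold is the
  escape hatch.
- The Langmuir machinery fits neither mass-transport-limited nor bivalent
  binding; curved or heterogeneous sensorgrams will show it in residuals.
- Gel densitometry is consumed as tabular band densities; extracting them
  from gel images is out of scope.
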