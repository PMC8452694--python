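# Methods

## Measurement model

Every pixel spectrum is modelled as a non-negative linear combination of K
invariant pure component spectra (Beer–Lambert-like additivity):
`D = C·Sᵀ + E` for the unfolded (pixels × channels) matrix of one cube,
and block-wise for a multiset of several samples and platforms. The model
assumes (i) component spectra do not vary with location or concentration,
(ii) signals add linearly across components, and (iii) after
preprocessing, residual instrumental structure (baseline, spikes,
saturation) is negligible. No mean-centering is applied anywhere: the mean
spectrum is itself chemical signal under an additive model, so rank
estimation and the ALS both operate on the raw (preprocessed, balanced)
matrix.

Fit diagnostics are the lack of fit `LOF(%) = 100·√(Σe² / Σd²)` and the
explained variance `r² = 1 − Σe²/Σd²`; the identity `r² = 1 − (LOF/100)²`
holds exactly and is enforced in the result object.

## Pipeline

Stages run in a fixed order, each persisting its outputs so a run can be
resumed or stopped per stage:

1. **preprocess** — per platform: saturation masking (IR), spectral
   cropping, cosmic-spike repair and AsLS baseline subtraction (Raman),
   Savitzky–Golay derivative (IR), pixel binning (fluorescence).
2. **resample** — area-weighted rebinning of every cube onto the
   reference platform's (coarsest) pixel grid; supports non-integer size
   ratios such as 2 µm → 3 µm.
3. **align** — global intensity map per cube, binarization, and
   Nelder–Mead minimization of the binary sum-of-squared-differences over
   (dx, dy, θ); the moving cube is then resampled onto the reference grid.
4. **fuse** — per sample, the logical AND of all validity masks defines
   the common pixels; each (sample, platform) block is unfolded, divided
   by its Frobenius norm, and assembled into the augmented matrix with
   full block bookkeeping.
5. **unmix** — constrained MCR-ALS (below).
6. **report** — CSV spectra per platform, float-TIFF maps per sample, and
   a plain-text run log with the LOF trace and block layout.

## Registration

The transform model is: rotate the moving image about its centre by θ
(degrees), then shift by (dx, dy) pixels; coordinates are (row = y,
col = x), 0-based, y increasing downward. The objective is evaluated on
bilinearly interpolated binary values so it is piecewise smooth for the
simplex; squared differences over the common (mutually defined) pixels
are scaled to the full reference pixel count so the optimizer cannot
lower the error by shrinking the overlap, and solutions covering less
than `min_overlap` (default 0.5) of the reference foreground are vetoed
with an infinite cost. Because binary-contour objectives have local
minima in θ, the simplex is restarted from a coarse angle grid (default
±10° in 5° steps) and the best result returned; it is never worse than
the initial guess.

Binarization defaults to Otsu's criterion on square-root-compressed
intensities (`otsu-sqrt`). Plain Otsu finds the largest between-class
separation, which for tissue images whose in-sample dynamic range rivals
the sample/background contrast can split "bright structures vs the rest"
instead of "sample vs background"; the square-root compression (a
variance-stabilizing transform for count-like data) restores the intended
sample/background split. Intensity maps sum raw values per pixel, unless
the negative-signal mass exceeds a quarter of the positive mass (i.e. the
data are derivative spectra), in which case absolute values are summed so
the lobes do not cancel.

Under the default phantom conditions (40×40 reference grid), registration
recovers known misalignments to about 0.3 px and well under 1°. The
accuracy is contour-information-limited: at coarser grids (e.g. 30×30 or
20×20 reference pixels) the angular error of single-contour binary
registration grows to ~1–2°.

## MCR-ALS

* **Rank**: `estimate_rank` reports uncentered singular values and
  cumulative variance; the choice of K is the user's.
* **Initialization**: SIMPLISMA pure-pixel selection. Purity of row i is
  `std_i / (mean_i + offset)` with `offset = noise_alpha% · max(mean)`
  (default 5%), damping noise-dominated low-intensity rows; after the
  first pick, candidates are weighted by the Gram determinant of the
  normalized selected rows plus the candidate, suppressing collinear
  picks. Selection is deterministic with ties broken to the lowest row
  index.
* **Updates**: the unconstrained least-squares solution is computed
  first; only vectors violating non-negativity are re-solved exactly
  (NNLS when all K components are constrained, bounded least squares for
  mixed constraints), then zero-mask entries are hard-set to 0. A fast
  clipping mode is available (`nonneg_solver="clip"`).
* **Scale/sign convention**: after every spectral update each component's
  full augmented spectrum is normalized to unit Euclidean norm, the
  inverse factor absorbed into C; components unconstrained in sign in
  both modes are flipped so their largest-magnitude spectral entry is
  positive.
* **Convergence**: iteration stops when the absolute change in LOF falls
  below `tol_pct` (default 0.1 percentage points; a relative mode is a
  config option) or at `max_iter` (default 50); the lowest-LOF iterate is
  returned, which also guards against oscillation under constraints. For
  unconstrained runs the trace is provably non-increasing.
* **Degenerate cases**: a constraint set that zeroes a component's entire
  augmented spectrum is rejected up front; a component whose spectrum or
  abundance profile collapses to zero during the run raises a
  component-death error naming the component.

The solver is shaped as a scikit-learn estimator (`MCRALS`, with
`fit`/`transform`, `get_params`/`set_params` and trailing-underscore
fitted attributes) so it composes with sklearn tooling; `run_mcr_als` is
a thin functional wrapper returning the full `MCRResult` record.

## Constraints

`ConstraintSet` holds non-negativity and zero (selectivity / local rank)
rules addressed per component, per mode (C or S) and per block (sample
for C, platform for S); `None` means "all". Spectral zero ranges are
given in the platform's axis units and `"all"` zeroes a component's whole
sub-signature — the "platform does not detect this component" case.
Masks are materialized against a concrete multiset layout, at which point
out-of-axis ranges and fully-zeroed components are rejected.

## Balancing

"2-norm" is read as the Frobenius norm (the chemometric block-scaling
convention); the induced spectral norm is available as an option.
Balancing is per (sample, platform) block; multiplying each block by its
stored weight reconstructs the unbalanced multiset exactly. Recovered
spectra therefore carry a per-platform scale of 1/weight;
`balanced_truth_spectra` applies the same scaling to ground-truth spectra
before correlation so comparisons are like-for-like.

## Phantom generator

The generator emulates the statistical structure the pipeline assumes,
on a leaf-cross-section-like scene:

* **Geometry**: a soft-edged, lobed tissue outline (the deliberate
  angular irregularity makes image orientation identifiable during
  registration, as real tissue outlines are); inside it, localized
  component maps (blob, vein network, ring, blob) and a ground-tissue
  "matrix" component that covers the whole section and is attenuated, but
  not absent, where the localized components dominate. All per-sample
  scenes are right-angle rotations of one rendered scene — spatially
  distinct, yet sharing the component Gram matrix, so 2-norm balancing
  preserves exact bilinearity in the clean limit (the master oracle for
  the pipeline).
* **Spectra**: sums of Gaussian bands per component and platform, with a
  leaf-like default palette (chlorophyll-like 682 nm emission;
  lignin-like 487/512 nm emission plus 1601/1631 cm⁻¹ Raman bands;
  carotene-like 1157/1525 cm⁻¹ Raman doublet; lipid-like 2848/2916 cm⁻¹
  IR pair; protein/cellulose-like matrix visible in all three). A zero
  amplitude makes a component invisible to a platform; every component
  must be visible somewhere.
* **Resolution hierarchy**: maps are rendered on a fine grid (0.25 µm by
  default) and area-downsampled to each platform's pixel size (defaults
  0.25, 2 and 3 µm), mirroring how one physical scene is sampled by
  instruments of different resolution.
* **Degradations**: rigid misalignment per sample × platform (applied to
  the abundance maps, which commutes with mixing); additive Gaussian
  noise with standard deviation `rms(clean signal)/snr` — scaled to the
  clean signal, never to artifact-inflated data; a broad
  tissue-autofluorescence Raman baseline proportional to local signal;
  cosmic spikes at a Binomial(pixels, rate/1000) count with uniformly
  random channel; IR saturation driving a fraction of *signal-carrying*
  pixels to a hard ceiling. Everything is reproducible from one seed and
  the truth bundle records maps, spectra, transforms, spike and hot-pixel
  positions.

What the phantom does **not** emulate: instrument point-spread functions
and detector response curves, spectral axis miscalibration between
instruments, spatially correlated noise, and scattering artifacts.
Passing tests therefore demonstrate correctness of the algorithmic chain
under the stated model, not robustness to all real-instrument effects.

A genuine fusion effect the phantom does reproduce: because each
platform's maps travel a different downsample → misalign → re-align path,
their effective spatial blurs differ slightly, so the blocks of one
sample are not exactly consistent with a single shared C. This is why a
noiseless but misaligned multiset converges to a few percent LOF rather
than zero, while the congruent-grid phantom reaches LOF ~1e-14.

## Problem sizes and runtime

Defaults were chosen so the full test suite and the acceptance script
each run in a few minutes on one CPU: congruent phantoms use 20×20 pixel
grids (1200 multiset rows × 324 channels), the misaligned study a 120 µm
scene (40×40 reference grid, ~4700 rows after common-area masking), and
seed-sweep recovery checks use 20 seeds at 16×16. Larger scenes only
improve registration accuracy and conditioning.

## Known limitations

* Registration is rigid (shift + rotation) only; scale is assumed fixed
  by the upstream pixel-size matching, and non-rigid deformation is out
  of scope.
* Zero-mask entries are imposed after the least-squares step rather than
  solved as equality-constrained LS; with conflicting data this is a
  projection, not the constrained optimum.
* Incomplete multisets (missing sample × platform cells) and components
  present in non-shared image areas are not supported.
* The ENVI reader/writer covers the common text-header + BSQ binary
  dialect only; vendor-proprietary formats are assumed converted
  upstream.
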