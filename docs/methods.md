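# Methods

## Generative model

A scan `I` with `J` voxels is modelled voxelwise: the label `L_j` is drawn
from the categorical distribution given by a probabilistic atlas `A` warped
by a deformation `φ` (affine pre-alignment composed with a dense
displacement), and the log-intensity by a Gaussian mixture of the label's
tissue class plus a smooth additive bias field `Σ_b c_b Ψ_b(x_j)`
(multiplicative before the log transform).  The deformation carries a
membrane-energy prior (sum of squared spatial gradients of the displacement,
central differences with replicate boundary, voxel units).  `generative.py`
implements the joint objective and per-voxel class responsibilities as
*diagnostics*: the fast pipeline never optimises this objective directly —
it visits each parameter group once, in a fixed order, using the coarse
whole-brain segmentation as a guide.

Log transform: `Ĩ = log(max(I, ε))` with `ε = 1e-6 ×` the 99.5th-percentile
intensity; voxels with `I ≤ 0` are dropped from the mask.  Mixture densities
are evaluated in log space with log-sum-exp.

## Bias field

The field is a linear combination of separable basis functions: 3D DCT-II
products (`dct`, the default), monomials `x^a y^b z^c` with `a+b+c ≤ order`
on [−1, 1] coordinates (`polynomial`), or DCT in-plane × monomial
through-plane for thick-slice data (`hybrid`).  DCT columns are orthonormal
over the fitting grid and evaluated analytically at any resolution, so the
fit can run on a downsampled grid (≤ 2 mm for large images; native below
400k voxels) and the field be applied at full resolution.

Two choices keep the single-M-step estimate identifiable and deserve
explanation:

* **FOV-scaled order.** The default per-axis order is one DCT mode per
  ~33 mm of field of view, clipped to [2, 6]; a whole head (~200 mm) gets
  order 6 (343 functions).  On small fields of view a fixed order 6 would
  put the coarsest basis wavelength *below* the anatomical structure scale,
  at which point smooth fields can imitate per-structure intensity offsets
  and the decomposition into "bias" and "class means" is no longer unique —
  the alternation then drifts along that degenerate subspace.
* **Interior voxels only.** The fit uses voxels whose largest blurred
  one-hot responsibility is ≥ 0.99.  Boundary partial-volume voxels violate
  the single-class intensity assumption; with fixed (segmentation-derived)
  responsibilities they bias the class moments and leak anatomy into the
  field.  Restricting to interior voxels is the eroded-mask practice
  standard in bias-correction tools.  The soft maps are built at native
  resolution and passed through the same anti-aliasing operator as the
  image, so "interior" means the voxel's blurred intensity is single-class.

The alternation (closed-form precision-weighted moments ↔ ridge-stabilised
least squares, ridge `1e-8 × trace`, numerical only) stops when the field
changes by < 1e-4 of the robust intensity range, or after 50 rounds; the
fixed-responsibility lower bound is tracked and non-decreasing.  Correction
re-centres the field so the masked median intensity is preserved exactly.

## Contrast synthesis

Per-structure statistics are the median and 1.4826 × MAD (the multiplier
that makes the MAD consistent for a Gaussian σ); structures with < 10 voxels
are unusable and their recipe weight is redistributed over the remaining
terms.  The synthetic anatomical volume is the *expectation* image
`Σ_c p_c(x) μ_c` (background mean 0): sampling Gaussian noise would add
nothing, because the registration similarity is invariant to local affine
intensity changes.  Class standard deviations (used only to seed the final
EM) are absolute-weight averages of structure MAD-stds.  Resolution matching
uses a Gaussian PSF whose FWHM equals the target spacing, then trilinear
resampling; slice-profile simulation is out of scope.

## Registration

Greedy, non-symmetric, compositive: loss `−(LNCC + 2.5 · softDice)` on the
fixed grid; per iteration the analytic loss gradient with respect to the
displacement is masked (brain mask dilated 3 voxels), smoothed (σ = 1.0
voxels), one Adam step (lr = 0.5) is composed into the running field, and
the composed field smoothed (σ = 0.25 voxels).  There is no explicit
regularisation term; smoothness comes from the two smoothings and the
coarse-to-fine pyramid (start ~4 mm, halving to the native spacing, both
sides of the similarity anti-alias blurred to each level's resolution).
Affine initialisation is a mass-weighted least-squares fit of atlas structure
centroids to coarse-segmentation centroids (similarity-transform fallback if
rank-deficient).

Numerical choices that differ from a naive transcription, each adopted after
the naive variant measurably failed on phantom recovery experiments:

* **LNCC** is the mean over masked voxels of the *squared* local correlation
  with box-window moments (window 7, variance floor `1e-6 ×` global
  variance).  Its gradient is the exact derivative of the masked window sum
  (the per-window coefficient fields are box-filtered), verified against
  finite differences.
* **Soft Dice** uses the squared-denominator form
  `2Σpq / (Σp² + Σq² + ε)`.  The plain-sum denominator is not maximised at
  alignment for probabilistic maps (the self-overlap of a soft map is
  `Σp²/Σp < 1`), so it rewards warps that *concentrate* probability mass
  rather than align it; the squared form is maximised exactly at
  proportional overlap (Cauchy–Schwarz) and coincides with the plain form on
  binary maps.  For the same reason the pipeline blurs the one-hot coarse
  targets by 1 voxel so both sides of the Dice term have matched sharpness.
* **Adam's second moment is pooled to a scalar** over the field and the step
  is capped at lr voxels per iteration.  Per-voxel normalisation turns
  noise-level gradients into full-size steps, which roughens the warp
  (folding) and stalls convergence; the pooled variant preserves the spatial
  coherence of the smoothed gradient.
* **Keep-best with early stopping** (patience 25): the per-iteration warp
  smoothing acts as a diffusion term that slowly erodes the field once the
  data force anneals, so each level returns its best-loss iterate.
* **Iteration budget**: 100 iterations at every level by default (a
  coarse-to-fine sequence may be given instead); early stopping trims levels
  that converge sooner.

The Jacobian determinant of `id + u` (central differences) is positive on
≥ 99.9% of the mask after registration; it can be saved as a log10 map.

## Final EM and redistribution

With bias and deformation fixed the lower bound is maximised globally at
each iteration (plain EM): E-step responsibilities over the 16 grouped
classes, closed-form weighted M-step per mixture component, stop at 1e-5
relative change of the mean log-likelihood or 100 iterations.  `--skip n`
subsamples voxels with stride n for the M-step only; the final E-step runs
on the full working grid.  Multi-component classes are seeded by splitting
the recipe mean at ±0.5 σ with equal weights; variances are floored at
`1e-4 ×` the squared robust intensity range.  Voxels whose warped foreground
prior sum is below 0.5 are left to the background; above it, class priors
are renormalised.  Class posteriors are redistributed to constituent ROIs in
proportion to the warped atlas (`p_jk = r_jc · A_kj / Σ_{k'∈c} A_k'j`),
which conserves per-voxel mass exactly; hard labels are the argmax over ROIs
and background (ties to the lowest label id), and volumes are soft
(expectation) volumes in mm³.

Working resolution defaults: 0.4 mm in vivo; min(0.2 mm, scan resolution)
ex vivo.

## Phantom study conditions

The phantom generator defines the conditions under which the pipeline is
validated, chosen to be a faithful miniature of the intended use:

* 64³ grid at 1 mm; an ellipsoidal "brain" containing 24 Voronoi-seeded,
  smoothly-bounded ROIs (transition ~1 voxel, matching real partial-volume
  widths at 1 mm) partitioned into 6 tissue classes, so each class is
  several structures scattered across the volume — the property that makes
  bias identifiable from anatomy, and the stated reason tissue grouping
  exists.
* log-intensity class means 3.6–4.6 (max intensity ratio ~e, MRI-like
  contrast) with σ = 0.035–0.05 (3.5–5% intensity noise).
* a random order-2 DCT bias field scaled to ±0.15 log units (~15%
  inhomogeneity).
* a deformation of σ = 8 voxels smoothed white noise scaled to a 4-voxel
  maximum displacement (6 voxels in the registration-recovery experiment),
  verified diffeomorphic before sampling.
* the coarse segmentation is the protocol projection of the sampled labels
  with 5% of boundary voxels flipped to a neighbouring label.

All randomness flows through explicit seeds; regeneration is bit-identical.
The end-to-end study runs EM at the phantom's native 1 mm resolution (the
working-resolution machinery is exercised separately), and the default
FOV-scaled bias order gives order 2 on this 64 mm volume.

What the phantom does *not* emulate: real neuroanatomy and its
characteristic shapes, lesions, multi-component class intensity structure,
scanner noise correlations, slice profiles, and the upstream neural
coarse-segmentation model (replaced by the controllable corruption above).
Passing phantom tests therefore demonstrates correct inference under the
model's own assumptions, not clinical performance.

Two measured limits of the study conditions are worth recording.  The
sampled ground-truth labels are stochastic at class boundaries, so even the
Bayes-optimal segmentation (argmax of the true generating posterior) attains
only ~0.9–0.97 Dice per ROI against them; pipeline Dice is judged as the
mean over large ROIs.  Likewise the synthetic-to-sampled registration inside
the pipeline is information-limited by boundary label speckle to a mean
endpoint error of ~1 voxel — pushing the similarity higher does not reduce
it — whereas the registration-recovery experiment (deform the image by a
known field, register it back) recovers the field to ~0.2 voxels at default
settings.

## Known limitations

* Single-channel intensities only (no RGB / multispectral covariance model).
* The greedy first-order optimiser has no convergence guarantee; quality is
  monitored through the loss histories and the Jacobian map.
* The sparse atlas format stores one compressed sub-volume per ROI; very
  large ROI counts imply many small files.
* Hemisphere splitting relies on the coarse segmentation's labels; no
  template-space laterality model is included.
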