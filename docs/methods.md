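# Methods

This note documents the models, conventions and numerical choices behind
`lvscar`, in the spirit of a package's methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Short-axis slicing protocol

The LV long axis is the first principal component of the epicardial vertex
cloud.  PCA leaves the axis sign free; the base end is taken as the end
nearer the valve annulus markers when present, otherwise as the end with
the larger endocardial cross-sectional (cavity) area, sampled at 15 %/85 %
of the axis extent.  Near-spherical meshes (leading eigenvalues equal to
within 1e-9 relative) are resolved by the fixed, deterministic ordering of
the symmetric eigendecomposition, with a warning; rank-deficient vertex
clouds are an error.

Twenty-five planes normal to the long axis are placed by the `linspace`
convention — both endpoints included — from 20 % of the axis length above
the apex to the base.  The fixed protocol is the default; a seeded
uniform jitter of up to half the plane spacing is available as a training
augmentation flag.  A plane is valve-contaminated when it passes within
2 mm of a valve marker (about two pixels at the raster resolution;
configurable) or when its epicardial intersection is not a single closed
curve.  Contour self-intersection is tested with the standard simplicity
predicate on the closed polyline.

Rasterization fills a 256×256 grid at 1 mm/pixel centered on the epicardial
area centroid.  A pixel is foreground iff its center lies inside an
epicardial contour and outside every endocardial contour by the even-odd
rule, with pixel-center sampling; a center exactly on a contour counts as
inside that contour.  The rule is deterministic and bit-stable.  Slices
whose myocardium mask holds fewer than 50 foreground pixels (strict) are
excluded; the count is myocardium-only, not myocardium + cavity — chosen
because the exclusion exists to drop unusable near-apex slivers, and the
cavity area says nothing about wall visibility.

A slice's ground truth is 1 iff its plane intersects the closed scar
sub-mesh (vertex signed distances straddle zero; touching counts).  An open
scar mesh is an error naming the number of boundary edges.

## Polar encoding

The polar origin is the blood-pool centroid: background connected
components touching the raster border are outside the heart, the remaining
enclosed background is cavity.  Apical cap discs have no cavity and fall
back to the foreground centroid with a warning.  Output pixel (r, θ)
samples the Cartesian mask at `center + r·(cos θ, sin θ)` by nearest
neighbour — bilinear interpolation would break the binary alphabet — with
1 mm radial and 360/256° angular steps; rows beyond the sampled extent are
zero-padded at the large-radius end to 256.  "Large-radius end" is our
reading of padding "at the base": the stated rationale (centroids near an
edge shorten the reachable radius) only makes sense on the radial axis.
θ = 0 lies along +x of the mask frame, counter-clockwise; the encoding is
not anchored to an anatomical landmark, and a random circular column shift
is available as augmentation since rotation is a column shift in this
representation.

## Focal loss and the class weight

The loss primitive is FL(p_t) = −α (1 − p_t)^γ log(p_t) with p_t clamped at
1e-7 before the log, reduced by the batch mean.  A single constant α cannot
by itself counteract class imbalance (it scales every sample equally), so
during training the weight is applied per class: α for positives, 1 − α for
negatives, the convention of the original focal-loss formulation.  With
γ = 0 and α = 1 the primitive reduces exactly to cross-entropy.  Defaults
are the tuned values LR 0.009, momentum 0.73, batch 10, γ 1.560, α 0.6,
with 100 epochs per CV fold and 500 for the final retrain (both reduced in
the synthetic experiments; see below).

## Network architectures

Both classifiers are sequential numpy networks (3×3/pad-1 convolutions via
im2col + BLAS, ReLU, 2×2 max pooling, dense head, single sigmoid logit):

* `vgg16` — the 13-convolution VGG16 topology adapted to one input channel
  and one output logit, no pretrained weights (the masks are binary;
  transfer from natural images has nothing to offer them).
* `vgg_small` — the same topology class at desk scale: a stem that crops to
  the first 64 radial rows (LV epicardial radii stay well under 64 mm, so
  the far field of a polar mask is empty) and average-pools angle 16×,
  followed by four blocks of two 3×3 convolutions with widths
  (8, 8, 16, 16, 32, 32, 64, 64), each block ending in 2×2 max pooling,
  then dense 64 → 1.  Radius is kept at full 1 mm resolution because wall
  thickness — the discriminative signal — lives on the radial axis, while
  angle is heavily oversampled at 256 columns.  This variant trains in
  minutes on one CPU core; the full `vgg16` is retained behind the
  architecture flag.

Initialization is He-normal from a seeded generator; training is plain SGD
with classical momentum and seeded shuffling, so a (seed, data) pair
reproduces loss traces exactly.  Probabilities are thresholded at 0.5 with
ties called positive.

## Cross-validation and tuning

Folds are patient-wise: every slice of a patient shares a fold.  Patients
are ordered by descending scar-slice count and dealt greedily — fold
patient counts kept within one, and among the smallest folds each patient
goes to the one holding the fewest scar slices.  This balances both fold
sizes and scar proportions even when half the cohort is scar-free; a fold
whose scar fraction deviates more than 10 % (relative) from the global
fraction triggers a warning rather than an error, since some cohorts make
perfect balance infeasible.  Out-of-fold predictions cover each slice
exactly once and are pooled before scoring.

Hyperparameter search is global-best particle swarm optimization with the
standard constricted coefficients (inertia 0.729, cognitive = social =
1.49445, 20 particles), positions clamped to the bounds, batch size rounded
to an integer, objective = cross-validated accuracy at a reduced epoch
budget (default 10).  These PSO details are this package's own
reconstruction of a standard global-best swarm; the bounds ship wide enough
to contain the tuned defaults above.

## Registration and label transfer

Paired meshes are aligned by point-to-point ICP on epicardial vertices:
initialization rotates the source long axis onto the target's, resolves the
roll about the axis from the first valve-marker correspondence, and
translates apex to apex; iterations alternate nearest-neighbour
correspondence (k-d tree) with a least-squares rigid refit (Kabsch/SVD),
stopping when the RMS closest-point distance changes by less than 1e-4 mm
or after 200 iterations.  RMS is tracked because the alternating
minimization is monotone in it.  A full rigid transform is fitted even
though a translation often suffices for paired scans of one heart — the
axis/valve initialization implies rotational alignment somewhere — and a
translation-only mode is available in the configuration.  Non-convergence
returns the best transform with a warning flag.  Scar transfer maps the
scar vertices through the fitted transform, topology unchanged.

## Synthetic cohorts

The generator emulates segmentation-tool output, not myocardial mechanics.
An LV is a truncated prolate spheroid (truncation at 110° polar angle, flat
basal cap, transverse semi-axis 0.36× the apex-base length) with smooth
low-order shape perturbation (products of cosines up to order 3 in angle
and 2 axially, ~2 % radial amplitude).  The endocardium is the epicardium
offset inward along the reference-surface normal by a thickness field:
a base thickness drawn from 8–12 mm per patient, modulated by ~5 % smooth
noise, and — for scarred patients — multiplied inside a patch by the
thinning factor with a plateau-and-cosine taper.  Scar defaults: 75°
angular by 0.35 axial-fraction extent, thinning factor 0.5, patch center
re-sampled per patient (axial fraction 0.30–0.62, angle uniform).
Localized thinning is the anatomical biomarker the classifier is meant to
learn; thinning factors near 1 model recent scar with minimal remodeling.
The closed scar sub-mesh fills the mid-wall 30–70 % depth band of the
patch, so slice labels and the thinned appearance are generated by the
same geometry.  Valve markers sit at three asymmetric angles on the basal
rim (asymmetry makes the ICP roll initialization unique).

Each patient is a pair: the "CTA-like" mesh re-uses the patient's anatomy
(length, base thickness, scar placement) with independent shape noise, an
isotropic scale drawn so the paired blood-volume difference |ΔV|/V is
half-normal with mean 0.19, and a random rigid displacement (5–25°, up to
15 mm) that registration must undo.  Both meshes carry their own native
scar labels; the test flow ignores the target's and estimates them by
transfer, so transferred-versus-native agreement is measurable.

What the generator does not emulate: papillary muscles and trabeculation,
non-ischemic (e.g. hypertrophic) remodeling, scar transmurality variation,
acquisition artifacts, and non-rigid inter-modality anatomy differences
beyond a global volume change.  Passing tests therefore demonstrate that
the pipeline recovers a thinning signal it planted itself — an internal
consistency check, not clinical validity.

## Experiment sizes

The end-to-end recovery experiment (tests and acceptance script) uses 60
patients at 50 % scar prevalence, 5-fold patient-wise CV, and 30 epochs per
fold with `vgg_small` — sizes chosen so the whole experiment, in pure numpy,
completes in about 12 minutes on a single core while leaving a clear
separation between chance, the thickness baseline, and the CNN.  At this
scale roughly 1440 slices survive exclusion, ~21 % scar-positive.  The
headline clinical-scale settings (10 folds, 100/500 epochs) remain the
configuration defaults.

## Evaluation conventions

Accuracy is pooled correct/total over out-of-fold predictions.  ROC curves
come from a threshold sweep (scikit-learn), AUC by the trapezoidal rule;
tied scores step diagonally, matching the Mann–Whitney statistic with
half-credit ties.  Bootstrap intervals resample (probability, label) pairs
with replacement (default 2000 resamples), redraw single-class resamples,
and report the 2.5/97.5 percentiles; a ±1 SD band is available instead.
Fleiss' kappa follows the 1971 definition and is an explicit error when
expected agreement is 1.  Region roll-up bins slices by thirds of
normalized apex-to-base position; a region is positive if any retained
slice in it is positive, and indeterminate when it holds no retained
slice.  The minimum-wall-thickness baseline scores a slice by the smallest
per-column foreground extent of its polar mask; its decision threshold is
fitted by maximizing training accuracy, while its AUC is threshold-free.

## Known limitations

* Pure-numpy training limits feasible network width/depth; `vgg_small`'s
  accuracy ceiling on real data is unknown.
* The synthetic scar is always transmural and thinning-based; classifiers
  trained on it will not detect scars that remodel differently.
* ICP is rigid; real MRI→CTA anatomical differences beyond volume scaling
  are absorbed into ground-truth noise rather than corrected.
* Legacy VTK support covers ASCII triangulated polydata only.
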