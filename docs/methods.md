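# Methods

`busseg` detects and segments suspicious focal lesions in 8-bit grayscale
breast-ultrasound frames in two stages: it first classifies *normal*
tissues with a random forest and treats the pixels the forest cannot
confidently explain as lesion candidates, then extracts the lesion contour
by radial brightness-gradient analysis around the candidate center.  This
note documents the model, its tunable parameters, the numerical choices,
the synthetic phantom the package is validated on, and the limits of what
that validation shows.

## Stage 1 — normal-tissue classification and candidate detection

### Features

Each pixel is described by a 17-dimensional vector:

* **Multi-scale Hessian eigenvalues.** The frame is Gaussian-smoothed at
  scales σ ∈ {1, 2, 4, 8, 16, 32, 64, 128} px (a doubling schedule capped
  at 128; configurable).  At each scale the 2×2 Hessian is formed from
  second-order central differences of the smoothed image (reflect borders)
  and its two eigenvalues are computed in closed form, ordered
  algebraically λ₁ ≥ λ₂.  These encode local curvature — blob vs ridge vs
  flat — at eight scales: 16 features.
* **Local binary pattern (LBP).** The 8 neighbors in a 3×3 aperture are
  compared with the center; bit p (weight 2^p, neighbors clockwise from
  top-left) is set iff neighbor − center ≥ 0.  The frame is
  replicate-padded so border pixels receive codes.  One feature, an
  integer in [0, 255], computed on the raw 8-bit values.

Note neither feature sees absolute intensity — derivatives and LBP are
offset-invariant.  This matters for how unknown pixels behave (below).

### Forest and the unknown rule

A random forest (default N = 50 trees, Gini criterion; scikit-learn's
`RandomForestClassifier`) is trained on balanced per-class pixel samples
(default 2000 per class per image) from annotated lesion-free frames.
Default classes: skin, fat, fibrous tissue, fibrous bands, glandular
tissue, artifacts (configurable; some datasets merge the fibrous types).

At inference each tree casts one hard vote per pixel and the **vote
fractions** are the class probabilities (this differs from scikit-learn's
`predict_proba`, which averages leaf frequencies; with fully grown trees
the two coincide).  The pixel label is the argmax class — or *unknown*
when the best class receives less than `unknown_threshold` of the votes
(default 0.20).

**Calibrating the unknown threshold.**  An absolute vote-fraction cut-off
is tied to one data distribution.  Two structural facts constrain it: the
maximum of C vote fractions is at least 1/C (0.167 for six classes), and a
forest of fully grown trees partitions the whole feature space, so even
far-out-of-distribution pixels are absorbed into some class with
substantial agreement — in our experiments the per-pixel maximum vote
fraction never fell below ≈ 0.35 on *any* input, including white noise.
A fixed 0.20 threshold therefore transfers poorly across data sources.
What is robust is that lesion pixels are systematically *less* confidently
classified (maximum vote fraction ≈ 0.45–0.55) than normal-tissue pixels
(≈ 1.0).  `calibrate_unknown_threshold` exploits this: given lesion-free
frames from the target distribution it returns the q-quantile (default
q = 0.5%) of the per-pixel maximum vote fraction, i.e. the threshold at
which about that fraction of normal pixels is left unannotated.  The
calibration is specificity-based and lesion-blind.  The phantom study and
the acceptance script run with the calibrated threshold; the constructor
default remains 0.20.

### Mask refinement and candidate objects

The unknown mask is cleaned by a median filter (default 5×5) and then
dilated (disk, default radius 2).  Filtering *before* dilating removes
sparse isolated unknowns so they are not inflated into spurious blobs;
dilation then merges the surviving dense clusters.  8-connected components
of at least `min_object_area` pixels (default 300 at the 256×256 phantom
scale — roughly a lesion of radius 8 px after refinement) become candidate
objects.  Components that look like reflection artifacts — mean intensity
> 93 **and** eccentricity > 0.9 **and** perimeter/area > 0.1, all three
strictly — are removed.  Eccentricity is the standard second-moment
ellipse eccentricity √(1 − b²/a²) (it can reach 1.0 for one-pixel-wide
components); the perimeter is the length of the marching-squares boundary
polygon.  Each survivor gets its contour mass center (the arithmetic mean
of its boundary points) and an ROI box: the bounding box expanded by
`pad_fraction` (default 0.15) per side, clipped to the frame.

### Ray seeding

The candidate's contour mass center localizes the lesion only roughly:
the unknown mask carries a halo of depressed-confidence pixels around the
lesion (large-σ features of nearby normal pixels are perturbed by it),
which biases the mass center by 10–30 px — outside the contour stage's
basin of attraction.  Because the lesion is by assumption the most
hypoechoic structure in its ROI, the pipeline re-seeds before casting
rays: the ROI is thresholded at its darkest `core_quantile` percent
(default 10%), the connected component with the lowest mean intensity (at
least `core_min_area` = 50 px) is taken as the hypoechoic core, and rays
start from its centroid with maximum radius `radius_factor` (default 2.0)
times the core's equivalent radius.  `seed_mode="object-center"` restores
seeding at the mass center.  The *reported* lesion center of a detection
is always the mass center of the final segmented contour.

## Stage 2 — contour extraction

From the seed, `T = 360/step` rays are cast (default step 0.5° → 720
rays), each sampled at unit radial steps with bilinear interpolation until
`max_radius` or the frame border.  Along each ray the brightness gradient
is measured with a sliding window of size S (default 5 samples):

    ΔP_i = Σ_{j=1..S} P_{i+j} − Σ_{j=1..S} P_{i−j},   i = S … N−S.

The boundary radius on a ray is the sample with the **largest positive**
ΔP — the strongest dark-to-bright transition, as expected when looking
outward from a hypoechoic interior; ties resolve to the smallest radius.
Rays that are too short or show no positive gradient are filled by
circular linear interpolation from their neighbors; if *every* ray is
featureless the stage raises an empty-contour error.

The polar boundary r(φ) is smoothed by sliding cubic regression: the first
M₀ points (default 180) are appended beyond 360° so the fit sees the
closure, least-squares cubics are fitted on every window of M points
(default 180) advanced by stride W (default 10), and each point's smoothed
radius is the mean prediction over all covering windows (wrapped copies
fold back to their source index).  Window abscissae are shifted to start
at 0 rad to condition the fit; predictions are shift-invariant.

Outliers are then corrected with a Niblack threshold: with
Δr_j = |r̄_j − r_j| and B = mean(Δr) + k·std(Δr) (population standard
deviation over all T rays; k = 0.2), every point with Δr_j > B keeps its
angle but has its radius replaced by circular linear interpolation between
the nearest surviving neighbors.  The absolute deviation is used because a
signed Δr would never flag points far outside the regression curve on one
side.  The corrected polygon (T vertices, closed, star-shaped about the
seed, hence simple) is rasterized to the lesion mask.

Coordinates throughout: (x, y) = (column, row), 0-based, y down; ray
angles counterclockwise on screen from +x.

## Evaluation metrics

For a predicted region A and ground truth B:

* nearest-point contour distance: for each point of the candidate contour
  the Euclidean distance to the nearest reference point; reported as mean
  d̄ and population standard deviation σ.  The directed candidate→reference
  version is the primitive; repeated-tracing variability pools both
  directions of every unordered pair of contours.
* IoU = |A∩B| / |A∪B| (0 when both empty, by convention).
* truth-normalized overlap fractions TP = |A∩B|/|B|,
  FP = |A∪B − B|/|B|, FN = 1 − TP.  TP + FN ≡ 1 and FP may exceed 1 when
  the prediction spills far outside the truth; these are kept as defined
  because they are what the precision/recall/F1 arithmetic consumes.  The
  conventional pixel-count confusion matrix is exposed separately
  (`pixel_confusion`) under distinct names.
* precision = TP/(TP+FP), recall = TP/(TP+FN),
  F1 = 2PR/(P+R); any 0/0 is reported as 0 with a degenerate flag.
* upper-hemisphere restriction: echoes below a lesion are unreliable
  (posterior shadowing), so evaluation can clip both masks and contours to
  rows at or above the lesion-center row before computing any metric.

Batch evaluation reports per-frame rows, per-video means, the arithmetic
mean over rows, and a pooled recomputation over all pixels — labeled
distinctly, because averaging per-video metrics and recomputing from
pooled overlaps do not commute.

## The synthetic phantom

The generator renders what the pipeline assumes about breast ultrasound,
with full ground truth:

* six horizontal tissue bands (skin, fat, fibrous bands, glandular,
  fibrous tissue, artifact zone) whose thicknesses vary ±30% per frame,
  with undulating interfaces and 10–16 elliptical islands of other tissues
  at arbitrary depths, so class is not a simple function of depth;
* per-tissue multiplicative speckle: a Rayleigh field smoothed with a
  small per-class Gaussian grain, anisotropic for the streaky fibrous
  textures and the vertical artifact-zone reverberation;
* a star-convex lesion r(θ) = r₀(1 + Σ irregularity harmonics), default
  r₀ = 30 px with 12% third-harmonic irregularity — strongly hypoechoic
  (contrast −114 from its surround, i.e. nearly anechoic) with faint
  internal echoes (speckle strength 0.04) and a sharp boundary;
* an optional posterior acoustic shadow (attenuated columns below the
  lesion).

The 256×256 default frame preserves the proportions of a clinical scan
(1200×900 frames, σ_max = 128, lesions of order 100–300 px): the σ_max/
frame and lesion/frame ratios are comparable, which matters because the
coarse-scale features of a pixel see a neighborhood of several σ.

What the phantom does **not** model: wave propagation and point-spread
physics, attenuation with depth, real speckle statistics (fully developed
speckle is not a smoothed Rayleigh field), operator- and device-dependent
appearance, isoechoic or hyperechoic lesions, and ill-defined infiltrative
margins.  Passing the phantom study therefore shows the pipeline is
correctly assembled and recovers known geometry under the method's own
assumptions — not clinical performance.

## Study design and problem sizes

The validation study (also run by `scripts/acceptance.py`) trains on 10
lesion-free phantoms, calibrates the unknown threshold on 3 more, then
processes 20 lesioned phantoms with jittered lesion centers (detection =
reported center within 5 px of truth; segmentation quality = IoU against
the true lesion mask), 20 lesion-free phantoms (specificity), a 60-frame
video with the lesion visible in 40 frames and drifting 0.5 px/frame, and
stage-2-only radius recovery on anechoic disks of radius 15, 30 and 60 px
(20 seeds each).  These sizes keep the whole study under a few minutes on
one CPU while leaving each rate estimated from 20–60 trials.

A frame counts as *correctly detected* in video reports iff some ROI
contains the true lesion center (lesion frames) or no candidate was
reported (lesion-free frames); this criterion is a convention of this
package for phantom data.

## Numerical choices and degenerate inputs

* Smoothing/derivative borders: reflect; LBP borders: replicate.
* Eigenvalue ordering: algebraic, descending; ties harmless (λ₁ = λ₂).
* Gradient positivity uses a 1e−6 tolerance to absorb bilinear-
  interpolation round-off on flat profiles.
* Rays shorter than 2S+1 samples shrink S locally; rays with no positive
  gradient are interpolated from neighbors; an all-flagged contour raises.
* Argmax ties in classification resolve to the lowest class index.
* Cubic fits use `numpy.polynomial` least squares on shifted abscissae;
  a final window is added at the end of the extended array if the stride
  leaves a tail uncovered, so every point receives ≥ 1 prediction.
* Empty masks: IoU of two empty masks is 0; overlap fractions require a
  non-empty ground truth; hemisphere clipping that empties a contour
  raises a degenerate-geometry error.
* Model persistence is joblib with a format-version tag; training is
  deterministic given the seed, and inference has no randomness.

## Known limitations

* The unknown rule needs calibration on lesion-free material from the
  target distribution; the absolute 20% default is only meaningful for
  data resembling what it was originally tuned on (see above).
* Stage 2 assumes a star-convex, hypoechoic lesion and a seed inside it;
  strongly non-convex or isoechoic lesions violate the model.
* One lesion per candidate ROI; overlapping lesions are not separated.
* Frames are processed independently — no temporal smoothing across video
  frames.
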