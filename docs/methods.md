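# Methods

## Problem and data model

The beam walk measures balance and coordination in mice: an animal
traverses a 1-m narrow beam (16-mm square, 16-mm round or 9-mm square)
toward a goal box while a side-view camera records at a nominal 120 fps.
Marker-less pose estimation yields, per frame, `(x, y, likelihood)` for
18 keypoints: 13 body parts (nose, eye, forepaw, elbow, shoulder,
hindpaw, ankle, knee, hip, iliac crest, tail base, tail centre, tail
tip) and 5 static beam markers.  All analysis starts from these tables;
video is never touched.

Image coordinates are used throughout (y grows downward).  Heights are
reported up-positive as `surface_y(x) − y`, so a hindpaw below the beam
surface has negative height.  Frames are 0-based; the central analysis
region is the half-open pixel interval `[x_left, x_right)`.

### Beam geometry

The two vertical line markers sit at the extremities of the central
80-cm region.  Because the markers are static, their per-marker median
positions (robust to tracking jitter and dropouts) define the geometry:
region bounds from the median x's, pixel scale as `width / 800 mm`
(2 px/mm on the reference rig, which makes the 18-px slip threshold
equal 9 mm), and the beam surface as the straight line through the two
median points (slope forced to 0 when the markers' x-span degenerates
below 1 px).  Beam identity comes from the dot markers: a dot
confidently tracked (median likelihood ≥ the floor) on the right means
the 16-mm square beam, on the left the 9-mm square, neither the 16-mm
round.  Both dots confident is an error, not a guess.  The fifth (aux)
marker is carried through IO but enters no computation.

### Confidence gating

Body-part coordinates with likelihood below a floor (default 0.6,
configurable; pose-estimation output is conventionally filtered but no
universal cutoff exists) are replaced by linear interpolation between
the nearest confident frames, holding the nearest confident value at
the ends.  Likelihoods are never altered, and beam markers are not
gated — an absent dot is *supposed* to be low-confidence, and markers
are summarised by medians anyway.  A body part with no confident frame
at all is an error naming the part.

## Classical endpoints

**Time to cross** is the duration for the nose to enter the central
region and first pass the opposite boundary, `(exit − entry) / fps`.
Re-entries between first entry and final exit are ignored; the entry
side fixes the direction of travel.

**Foot slips** are downward hindpaw excursions: maximal runs of frames
with height below −18 px (≈9 mm; the threshold that best matched
experienced human raters on the reference rig).  Runs separated by
fewer than 32 intervening frames (≈250 ms, the lower 5% quantile of
human-scored inter-slip gaps) are amalgamated into one event whose
nadir is the deepest frame.  Detection is restricted to frames where
the hindpaw x lies inside the central region.  Both thresholds are
parameters (`DetectionParams`), in pixels and frames respectively.

The evaluation harness matches detected events to human-annotated slip
frames greedily, in increasing frame order, one-to-one within a
±30-frame tolerance (250 ms at 120 fps; configurable — precision and
recall against any particular set of human annotations depend on this
window, so the tolerance is an explicit parameter, not a claim).
Unmatched annotations are false negatives, unmatched detections false
positives; 0/0 precision or recall is reported as 0 with a flag.
Per-video count agreement between two raters uses Cohen's kappa on the
counts as categorical labels; the degenerate case of two identical
constant raters (chance agreement 1) is reported as kappa 1 with a
flag.

## Feature engineering

Each trial is condensed to one ordered vector governed by an explicit
manifest:

| block | count |
|---|---|
| pairwise body-part distances, C(13,2) = 78, × {mean, min, max, variance} | 312 |
| joint angles (elbow, ankle, knee, hip) × 4 statistics | 16 |
| body-part heights above the surface, 13 × 4 statistics | 52 |
| sex (F=0, M=1), weight (g) | 2 |
| number of foot slips, time to cross (s) | 2 |
| **total** | **384** |

Distances and heights are divided by the *reference dimension* — the
mean elbow–shoulder distance over in-region frames — which removes
body-size effects (it correlates strongly with body weight).  Angles
are interior angles in degrees at the named joint, computed from the
anatomically adjacent triplets (shoulder–elbow–forepaw,
knee–ankle–hindpaw, hip–knee–ankle, iliac crest–hip–knee); a frame with
a zero-length limb vector is interpolated from its neighbours.  All
statistics use the sample (n−1) variance.  Only frames inside the
nose-based crossing window contribute to any series, aligning every
feature with the 80-cm analysis window.

Numerical note: because heights follow the vertical convention
`surface_y − y`, the feature set is exactly invariant under uniform
scaling and translation of the camera frame (bit-for-bit under a
power-of-two zoom), while camera roll leaves distances and angles
invariant but rescales heights by the cosine of the roll angle — a
negligible 0.2% at a 2° roll, and real rigs are levelled.

## Group discrimination

The question "can the classifier tell group A from group B?" is
answered per beam with a random-forest classifier inside a two-stage
leave-one-mouse-out cross-validation.  Trials of one animal are never
split across training and testing:

1. **Outer loop** — each mouse in turn is held out entirely.
2. **Inner loop** — within the outer training set, each remaining mouse
   in turn becomes the validation animal.  Per inner split:
   z-scoring is fitted on the inner-training trials only (mean and n−1
   SD per feature; constant features map to 0; the binary sex column is
   passed through un-scaled); recursive feature elimination with a
   balanced random forest removes `ceil(0.05 × remaining)` features per
   round down to 50; the forest hyperparameters are grid-searched
   exhaustively, scored by accuracy on the validation mouse (ties keep
   the earlier grid entry); a second elimination round with the tuned
   hyperparameters runs over *all* features, and its 50 survivors,
   ordered by mean decrease in impurity of the final fit, form the
   split's ranked list.
3. **Aggregation** — ranked lists are merged into a consensus ordered
   by occurrence across lists (descending), then mean rank (ascending),
   then name; hyperparameters are aggregated per key by mode, ties
   broken toward the earlier value in the grid's declared order and
   flagged.  Aggregating by occurrence requires truncated lists, which
   is why each inner list is the 50 selected features rather than a
   ranking of all 384.
4. **Evaluation** — a forest with the consensus features and modal
   hyperparameters, z-scored with outer-training statistics, is trained
   on the outer training trials and scored on the held-out mouse's
   trials: per-animal accuracy in {0, ½, 1} with two trials.

Per-animal accuracies are tested against the chance level 0.5 with a
one-sample Wilcoxon signed-rank test: zeros dropped, W reported as the
sum of midranks of positive differences, and the two-sided p-value from
the exact sign-flip distribution (computed by convolution, so midrank
ties are handled exactly) for n ≤ 25, the tie-corrected normal
approximation above.

Cross-cohort transfer trains wholly within cohort A — a full inner
leave-one-mouse-out pass yields consensus features and modal
hyperparameters, scaling is fitted on all of A — and reports per-animal
accuracy on every mouse of cohort B.

Randomness: one master seed; every forest receives a seed derived from
(master, outer index, inner index, stage counter) through
`numpy.random.SeedSequence`, so results are reproducible end to end and
splits are statistically independent.

Genuinely open defaults, chosen once and exposed
in `CVConfig`: the hyperparameter grid (trees {100, 300}, max depth
{3, 5, unlimited}, min samples per leaf {1, 3}), the inner scorer (mean
per-trial validation accuracy), and the elimination count per round
(`ceil`, floor one feature, never overshooting the target).

## Overlap, enrichment and projection

Overlap between prioritized feature lists from independent experiments
is tested by bootstrap: every repetition redraws each list uniformly
without replacement from the 384-feature universe (all lists are
resampled, a documented choice) and counts members common to all lists;
`p = (1 + #{rep ≥ observed}) / (reps + 1)` (never exactly zero),
default 100,000 repetitions, pairwise overlaps evaluated in the same
repetitions.  For two lists the null overlap is hypergeometric, which
serves as an exact cross-check.

Category enrichment of a prioritized list — by statistic family
(mean/min/max/variance) or constituent family (distance/angle/height) —
uses the upper-tail hypergeometric test with the raw counts (k, n, K,
N) and fold enrichment `(k/n)/(K/N)` always reported, so any derived
percentage convention is recoverable.

Group separation is visualised by linear discriminant analysis (SVD
solver, library defaults, all manifest features, unstandardized by
default with an opt-in z-scoring switch): 1-D for two classes, the
first two discriminants otherwise.  Separability is quantified by
euclidean distances to a reference group's centroid — reference samples
to their own centroid (intra) versus other groups' samples to that
centroid (inter).

## Skeleton summaries

Per animal, frames pooled over trials: each body part is placed at
x = −(mean euclidean nose–part distance)/reference (nose at 0, body
trailing a rightward-walking nose — the sign is a display convention),
y = mean normalized height, with a vertical bar of ±√(variance of
normalized height), the axis where balance disturbances express
themselves.  Euclidean rather than x-axis distance from the nose is
used (the alternative reading; documented here).  Group skeletons are
unweighted means across animals, variance bars the mean of per-animal
variances.  Rendering is deterministic (fixed SVG hash salt, no
timestamps): identical inputs give byte-identical files.

## Synthetic data

The trajectory simulator emulates the statistical structure the
pipeline consumes, not the videos: a nose advancing linearly so that it
spends an exact, known number of frames inside the marked region; body
parts following a rigid posture template (body length ~115 mm, heights
1–40 mm above the surface, 2 px/mm) with sinusoidal gait oscillation on
the limbs (~4 Hz at 120 fps); planted hindpaw slips as rectangular dips
of configurable onset/duration/depth; Gaussian tracking jitter
(default SD 2 px); and likelihood dropouts (default rate 2%) that
displace the affected coordinates, as real tracking failures do.  Beam
markers are emitted consistently with the configured geometry and beam
type.  Group effects shift named template parts (mm) and/or multiply
their vertical variance; every perturbed part is recorded as ground
truth.  Per-mouse random effects are log-normal scale factors on body
size and speed (positive, mildly skewed) plus a whole-body height
offset, and weight is generated from the scaled elbow–shoulder template
length, reproducing the size–weight correlation the reference dimension
relies on.

What the simulator does **not** reproduce: pose-estimation error
structure (correlated, occlusion-driven, non-Gaussian), paw occlusions
by the beam, falls and pauses, learning across trials, or realistic
inter-feature correlations of a moving animal.  Passing tests therefore
demonstrate the *pipeline's* correctness and calibration on data of
known structure, not performance claims on recorded mice.

A second, feature-level generator draws trial × feature matrices
directly — per-mouse random intercepts (SD 0.5) plus unit trial noise,
with a mean shift of a chosen size (in total-SD units) on a known
informative subset; the informative positions are fixed by a separate
design seed so independent cohorts of the same design plant the effect
on the same features.  This is the right granularity for calibrating
the cross-validation, where trajectory realism is irrelevant but the
mouse-level dependence structure is essential.

## Problem sizes used in tests and the acceptance script

The nested cross-validation is quadratic in mice and linear in forest
fits, so the validation suite runs it at reduced sizes, chosen once:

* **null calibration** — 16 mice × 2 trials, 32 features, select 16,
  8-tree forests, single-point grid, elimination fraction 0.5,
  50 replicate seeds; the chance-level property does not depend on
  these sizes;
* **planted effect and transfer** — 96 features, select 50 (the
  method's standard selection width), 10 informative features shifted
  by 2 total SDs, 25-tree forests, 10 replicate seeds;
* slip-detector validation uses 100 simulated trials at the default
  noise conditions.

The method constants — 18-px threshold, 32-frame merge
gap, elimination fraction 0.05, 50 selected features, balanced class
weights, 100,000 bootstrap repetitions — are the package defaults;
the reduced values above are explicit arguments of the test and
acceptance code, never silent changes to the defaults.

## Known limitations

* Single side view: only one hindpaw is observable, and forepaw slips
  are out of scope.
* The slip threshold is resolution-specific (18 px ≡ 9 mm at 2 px/mm);
  rigs with other scales must re-derive it via the threshold sweep.
* Heights use the vertical (not perpendicular) distance to the surface
  line; on tilted beams the two differ by the cosine of the tilt.
* The manifest enumerates 384 features from the constructive rule
  (78 + 4 + 13 series × 4 statistics + 4 scalars); the manifest is the
  source of truth for all downstream statistics.
* With two trials per mouse, per-animal accuracy has support {0, ½, 1};
  the Wilcoxon test is correspondingly coarse for small cohorts and is
  skipped (reported as NaN) below 6 animals.
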