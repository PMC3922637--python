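# Methods

## Problem and scope

Myocardial perfusion SPECT produces stress and rest uptake images of the left
ventricle that are routinely summarized as bullseye *polar maps* (apex at the
center, base at the rim).  Clinical guidelines tie revascularization
decisions to the *amount of reversible ischemia*, usually expressed as a
percentage of the left ventricle, so the quantity of interest is the area of
myocardium that is hypoperfused at stress but recovers at rest.  `mpsquant`
implements the computational core of that workflow: automatic delineation of
reversible defects on stress/rest polar-map pairs, the two standard per-study
summaries (defect extent and 17-segment summed difference score), and the
statistics used to quantify agreement between multiple readers or programs.
Acquisition, reconstruction, gated function, and any interactive reading GUI
are out of scope.

## Polar-map model

A polar map is sampled on an `n_theta x n_r` grid (default 64 angular x 32
radial bins), rows running apex to base.  Angles are measured from 3 o'clock,
counterclockwise.  Each cell carries an area weight proportional to the
annulus sector it covers (the polar Jacobian, `(r_{j+1}^2 - r_j^2)/n_theta`,
normalized to sum 1).  Equal per-cell weighting would over-represent the
apex, and extent is defined as a fraction of LV area, so all extent sums are
area-weighted.  Commercial packages differ on this point; the weighting here
is explicit and tested.

Uptake maps are normalized to percent of their maximum cell before any
thresholding or scoring; the difference map is `rest - stress` of two
normalized maps, positive where perfusion is reversible.

The 17-segment model uses four radial bands at r = 0/0.25/0.5/0.75/1 (apex,
apical, mid, basal) with a 1/4/6/6 angular split.  Anchor angles are
published as a constant table (`mpsquant.polar.SEGMENT_ANCHORS`): 60-degree
sectors for basal/mid starting with anterior at [60, 120), and apical
quadrants anchored at 45/135/225/315.  No standard fixes these anchors at the
file-format level; any fixed documented layout supports the summed-score
arithmetic, and the partition property (every cell in exactly one segment,
per-segment weights summing to 1) is enforced by tests.

## Two-stage delineation

**Stage 1 - stress defects.**  Seed points are strict local minima of the
normalized stress map (8-neighborhood, angular wrap-around, plateaus
collapsed to their centroid cell) darker than `depth_threshold` (default 70%
of maximum).  From each seed a closed deformable contour of circular
topology is fit by greedy descent of the classical snake energy

    E = alpha * sum |v_{k+1} - v_k|^2  +  beta * sum |v_{k+1} - 2 v_k + v_{k-1}|^2
        - gamma_edge * sum |grad I(v_k)|  +  gamma_int * sum I(v_k)

with I the normalized uptake.  Two numerical choices matter:

* *Star-shaped parameterization.*  Vertices move radially along 32 fixed,
  evenly spaced ray directions from the seed.  The polygon is therefore
  always closed, non-self-intersecting, and contains the seed - invariants
  that a free 2-D greedy snake only satisfies approximately.
* *Initialization.*  The energy has no inflation (balloon) term, so a small
  circle started at the seed cannot expand across the flat interior of a
  wide defect: greedy descent sees no image gradient there and the internal
  terms oppose growth.  Each vertex is instead initialized at the half-height
  crossing along its ray (uptake halfway between the seed value and the
  normal plateau at 100%), which places it near the defect border; descent
  then settles it on the gradient ridge.
* *Units of the intensity term.*  The edge term is measured in percentage
  points per cell while the raw intensity is in percentage points; summing
  them at equal weights would let the intensity term (a ~60-point step
  across a defect border) drag vertices one cell into the dark interior,
  systematically eroding the boundary ring.  The intensity term therefore
  uses uptake as a fraction of maximum (0-1), keeping the gradient ridge the
  dominant attractor at defect borders while low uptake still breaks ties in
  flat regions.

Contours are rasterized by the even-odd rule on cell centers (angular wrap
handled by testing each center at theta and theta +/- n_theta); overlapping
masks are merged by union; regions below `min_area_cells` (default 4) are
discarded.  Non-convergence within `max_iter` flags the contour rather than
raising.

**Stage 2 - difference defects.**  The difference map is Gaussian-smoothed
(`sigma` = 2 cells, wrap-around in theta) and cells above `rev_threshold`
(default 10 percentage points) are selected *inside stage-1 masks only*; the
selection is split into connected components per parent defect, so every
reversible region is contained in a stress defect by construction.  The
threshold is absolute, not adaptive per defect; an adaptive variant would be
a config change, but the absolute rule is reproducible and is the one
tested.  On noise-free, sharp-edged defects this pipeline reduces exactly to
plain thresholding of the difference image: the smoothing bleed outside the
defect is clipped away by the stage-1 mask (verified cell-for-cell in
tests).  Known discretization limit: a 32-vertex contour can cut isolated
corner cells of strongly rectangular defects; defects enclosing the apex
center (full-circle at r ~ 0) are outside the star-shaped parameterization.

None of the stage-1/stage-2 constants (seed depth, snake weights, sigma,
threshold, minimum area) come from a published protocol; they are package
defaults, all overridable through `DelineationParams` or the TOML config.

## Per-study quantities

*Extent* is the area-weighted percentage of the LV covered by the union of
difference-defect masks (union prevents double counting).  *SD%* is the
summed difference score over the 17 segments - each segment scored 0-4 from
its area-weighted mean uptake, SDS = sum of positive per-segment
stress-minus-rest score differences - expressed as a percentage of the
maximum possible score 4 x 17 = 68.  The uptake-to-score bins (>= 70 -> 0,
55-69 -> 1, 40-54 -> 2, 25-39 -> 3, < 25 -> 4) are a transparent stand-in
for the normal-database scoring of commercial packages, configurable and not
calibrated to any population.  The two routes are deliberately independent:
a study can have SD% > 0 with zero delineated extent (a mild diffuse
reduction crossing a score bin while staying below the reversibility
threshold), which is also a pattern present in the packaged reference table.

## Agreement statistics

The inter-observer model is the two-way random-effects decomposition
`value_ij = mu + p_i + o_j + e_ij` (patients and observers random).  ICC is
estimated by ANOVA method of moments: `sigma2_e = MSE`, `sigma2_p =
(MSR - MSE)/k`, `sigma2_o = (MSC - MSE)/n`, negative estimates truncated to
zero, `ICC = sigma2_p / (sigma2_p + sigma2_o + sigma2_e)` - the
single-rater, absolute-agreement ICC(2,1).  The 95% CI is the Shrout-Fleiss
F-based interval with Satterthwaite degrees of freedom (an F-based interval
was chosen over profile likelihood; the estimator is method-of-moments
because the model, not the estimator, is what the agreement analysis fixes).
"SD between observers" is reported as the square root of the observer
variance component; the SD of per-observer means is exposed alongside it
(`observer_mean_sd`) since the phrase is ambiguous in common usage.

Bland-Altman limits are `bias +/- 1.96 * SD` of the per-pair differences
(test minus reference), with the per-point diagonal bound
`max(-2m, 2m - 200)` implied by extents living in [0, 100].  The Wilcoxon
signed-rank test drops zero differences, midranks ties, and computes the
two-sided p exactly by a dynamic program over all sign assignments for up to
20 nonzero pairs (equivalent to full enumeration), otherwise by normal
approximation with tie correction and continuity correction.  Method
contrasts are restricted to balanced complete designs, where the
mixed-model fixed-effect contrast reduces algebraically to the paired mean
difference with a paired-t p-value; unbalanced input raises rather than
being silently approximated.

## Synthetic data

`simulate_study` places parametric defects on a flat uptake baseline of 100:
separable raised-cosine profiles in angle and radius with given center,
half-widths, core severity, and reversibility (the fraction of the stress
reduction recovered at rest); overlapping defects combine multiplicatively.
Noise is multiplicative Gaussian (relative SD = `noise_level`), a stand-in
for count noise after reconstruction - adequate at this scale but without
the spatial correlation of filtered back-projection.  Ground-truth masks use
the full-width-half-maximum convention (profile > 0.5), so the true extent
is unambiguous and, for axis-aligned sharp defects, matches the closed-form
sector-annulus area to within grid quantization.  The generator does not
attempt anatomically realistic coronary-territory shapes, so passing
recovery tests demonstrates correct mechanics of the pipeline, not clinical
accuracy on patient data.

`simulate_rater_panel` draws extents directly from the two-way
random-effects model, clipping to [0, 100] and reporting (not hiding) the
clipping count, since clipping biases the ICC.

## Experiment conditions

The packaged experiments (`mpsquant.experiments`, also run by
`scripts/acceptance.py`) use these conditions:

* *ICC recovery*: 200 patients x 11 raters, patient/rater/error SDs
  15/5/5 percentage points (implied ICC 225/275 ~ 0.818), grand mean 50 so
  clipping stays inactive and the closed-form ICC is the true estimand;
  50 replicates.
* *Suggestion shrinkage*: 25 patients x 11 raters - the size of a realistic
  multi-reader panel - with SDs 15/7.8/10.8 (first-read ICC near 0.56).
  The second read is modeled as 0.5-weight shrinkage of each reading toward
  the patient's true value, the reading a deterministic program would
  suggest; this scales the non-patient variance by (1 - 0.5)^2 per component
  and should raise the recovered ICC in nearly every replicate.
* *Extent recovery*: 50 studies on the 64 x 32 grid, one mid-wall defect
  each with target extent ~ U(5, 40)% LV, angular half-width U(25, 75) deg,
  severity U(0.5, 0.8), full reversibility, edge softness 0.04, noise
  U(0, 0.05).  These sizes keep the full suite and the acceptance script in
  the low minutes on one core while leaving the Monte-Carlo errors well
  inside the asserted tolerances.

## Known limitations

* The snake cannot represent defects that enclose the bullseye center, and
  can clip isolated corner cells of sharply rectangular defects.
* Score bins are uncalibrated stand-ins; SD% values are internally
  consistent but not comparable to any commercial package's output.
* The noise model is spatially white; real reconstructed polar maps have
  correlated noise and anatomical variation (apical thinning, gender
  differences) that the generator does not emulate.
* Agreement machinery requires complete panels; general unbalanced
  mixed-model estimation is intentionally not implemented.
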