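# Methods

`smileframe` quantifies three layers of facial and dental aesthetics from 2-D
landmark coordinates digitized on frontal photographs: whole-face proportions
against the divine ratio (macro), the relationship of midline landmarks to
the facial and mouth midlines (mini), and the smile framework plus tooth
metrics (micro). Because raw photographic datasets of this kind are rarely
shareable, the package pairs the analysis with a synthetic cohort generator
whose ground truth makes every stage testable end to end.

## Coordinate model

All input is pixel coordinates with y increasing downward. Anatomical side
is carried by landmark name (`_R`/`_L` = subject-right/left), never inferred
from x ordering. Every reported ratio, relative value and classification is
scale-free; an optional mm-per-pixel calibration exists only for absolute
distances.

## The beauty frame and relative midline values

The frame is the rectangle bounded above by the line through the two
external canthi (LC_R, LC_L), laterally by the perpendiculars through each
canthus, and below by the parallel line through the lowest point of the
lower lip (LLI). Its vertical bisector is the operational facial midline.
With `u` the distance of a point from the subject-right lateral border and
`F` the half-width (half the inter-canthal distance):

* RFV_i = u(landmark_i) / F for nasion, pronasale, philtrum tip, dental
  midline; RFV5 = Cx / F where Cx is the u of the inter-commissure midpoint.
* RCV_i = u(landmark_i) / Cx.

A value of 1 is exact coincidence with the respective midline; < 1 deviates
toward the subject's right, > 1 toward the left. Because all quantities
share one origin and denominator chain, RCV_i x RFV5 = RFV_i holds to
machine precision, and all values are invariant under similarity transforms
of the image (rotation, scale, translation) and antisymmetric under
mirroring (rfv -> 2 - rfv).

The RCV denominator deserves a note: defining it as the distance from the
subject-right frame border to the commissure midpoint (Cx) is the only
reading under which perfect symmetry yields RCV = 1, so that is what the
package implements.

Landmarks are projected perpendicularly onto the canthal axis. On photos
taken without head rotation this equals the horizontal pixel distance; on
rolled inputs the projection remains well defined. The v-axis is oriented by
the raster convention (positive image-y component); an LLI on or above the
canthal line is rejected as degenerate geometry rather than silently
flipping the frame.

## Facial proportions

Nine vertical spans (TR-ME, LC-ME, TR-LC, TR-LN, LN-ME, LC-LN, LC-CH,
CH-ME, LN-CH) are perpendicular separations along the canthal-frame v-axis;
bilateral landmarks contribute their pair-mean v. Three transverse spans
(CH, LC, TS right-to-left; LN is measured too, for the CH:LN ratio) are
straight point-to-point distances, as the measurement diagrams draw them.
Ten named ratios are formed and each is expressed as a percent of the divine
proportion with 1.618 == 100% (the constant is fixed at 1.618 exactly, the
value the source arithmetic uses, not phi to machine precision). Cohort
roll-ups compute golden percents from unrounded means; published tables of
this kind often print percents computed from unrounded means that cannot be
regenerated from the rounded means shown beside them.

## Smile framework

* **Smile arc** — no numeric consonance rule is standard, so the package
  uses the minimal quantification of "the incisal curve follows the lower
  lip": least-squares quadratics v = a u^2 + b u + c are fitted to the
  incisal-edge and lower-lip polylines in frame coordinates, and the smile
  is consonant iff both curvature coefficients are below `-flatness_tol`
  (default 1e-4 px^-1; both arcs dip centrally). Direction alone decides;
  curvature magnitudes are not required to match.
* **Upper-lip curvature** — Delta = v(ULC) - mean v(commissures); up if
  Delta > `lip_tol_frac` x frame height (default 0.02, so sub-pixel noise
  cannot flip the class), down if below the negative band, else straight.
  The reference point is the center of the upper lip's lower margin, the
  Hulsey-style convention; comparing the corners to the lower lip's own
  margin would make the classification circular.
* **Smile line** — high iff the full clinical crown plus a continuous
  gingival band shows; medium iff 75–100% of the crown shows; low below 75%.
* **Smile width** — the FDI tooth-type digit of the most posterior visible
  tooth, mapped 4..7 to first premolar .. second molar. Narrower smiles are
  rejected as unsupported input.
* **Tooth shape** — DP% = crown length / maximum width x 100 with
  triangular < 43, oval 43–57 (boundaries inclusive), square > 57. This is
  implemented exactly as printed in the source convention even though the
  thresholds imply crowns roughly twice as wide as long, which is
  anatomically atypical; a config switch `dp_definition=width_over_length`
  offers the inverted reading.
* **Tooth size** — width-to-length ratio and its golden percent.

## Cohort statistics

Sex comparisons use a Pearson chi-square without continuity correction,
switching to the Fisher exact test when more than 33% of cells have expected
counts below five (2x2 via scipy; r x c by full fixed-margin enumeration,
validated against R's `fisher.test`). Continuous variables use the
two-sided Mann-Whitney U: exact enumeration of all group assignments for
pooled n <= 12 (midranks handle ties), otherwise the normal approximation
with tie correction and no continuity correction, matching common
statistical-package behaviour. Reliability is ICC(2,1) — two-way random
effects, absolute agreement, single measurement — computed from the two-way
mean squares and cross-checked against pingouin's ICC(A,1) in the tests;
this is the conventional form for test–retest of continuous measurements.
Percentages in category tables use the grand total as denominator. Display
rounding (1 decimal for percents, 2 for ratios, 4 for p-values) is applied
only when writing tables.

## Synthetic cohort generator

Defaults are the study conditions: 637 subjects (350 female / 287 male),
per-sex RFV means and SDs, per-sex facial-proportion ratio targets, per-sex
smile-category frequencies, and per-sex crown width/length ratio mean ± SD.

* Midline landmark u-offsets are drawn Normal(rfv_mean x F, rfv_sd x F),
  truncated at ±4 SD to keep geometry sane. RCVs are not independently
  parameterized — they are implied by rfv_i / rfv5, consistent with the
  algebraic identity.
* Rest-view vertical positions come from a template calibrated by nonlinear
  least squares on the log-ratio mismatch to the seven vertical ratio
  targets (TR and ME anchor translation and scale; 7 targets over-determine
  3 free positions, so the study targets leave a small residual). The three
  transverse ratios chain the four transverse widths exactly from the
  inter-canthal anchor.
* The inter-canthal width is 512 px (a power of two keeps the zero-noise
  u -> u/F round trip bit-exact) and the face height 1024 px, about twice
  the outer inter-canthal distance, which is anthropometrically realistic.
* Per-landmark Gaussian jitter (default SD 2.5 px, digitization scale) is
  applied to all landmarks except the canthi, which anchor the frame; their
  placement error is represented by the global pixel-noise term (default SD
  0.5 px). Keeping jitter at digitization scale makes ratio-mean recovery
  effectively unbiased; the printed between-subject ratio SDs are NOT
  emulated — they are not realizable from five independent vertical
  positions without the unpublished covariance, a documented limitation.
* Categorical attributes are drawn from the sex-specific multinomials and
  realized geometrically inside the drawn class's region (curvature signs
  with |a| = 3e-3 px^-1 >> flatness_tol, lip offsets at ±5% of frame height
  vs a 2% dead band, exposure fractions inside each smile-line band, crown
  quotients from the sex Normal truncated to the drawn shape class's
  interval), so the default classifiers recover the drawn class exactly at
  zero noise and overwhelmingly at default noise. The printed tooth-shape
  frequencies are incompatible with the printed width/length mean under the
  DP% formula (1.18 implies DP ~ 84%, always square); the generator gives
  the drawn class precedence, so the realized cohort w/l mean exceeds the
  printed 1.18.
* Head roll (±5°), scale (0.8–1.2x) and translation (±200 px) are drawn per
  view and applied last, then i.i.d. pixel noise. Ground truth stores the
  drawn values and pre-transform coordinates.
* Randomness: subject i uses an independent stream seeded by (seed, i), so
  growing n never reshuffles earlier subjects; identical seeds give
  byte-identical output files.

What passing tests show — and do not show — about real data: the generator
reproduces the *statistical shell* of a cohort (marginal RFV distributions,
ratio means, category frequencies, pose/noise nuisance) but not
inter-landmark covariance, asymmetric smiles, age effects, or landmark
identification ambiguity on real photographs. Pipeline correctness on this
cohort therefore validates the geometry and statistics, not photographic
digitization practice.

## Problem sizes and numerical notes

Simulation-based checks use cohorts of 100–2000 subjects, the scale at which
sampling error on means falls well below the effects being checked. At
n = 2000 the standard error of an RFV mean (~0.0019) exceeds the smallest
gaps between adjacent population means (0.0007–0.0017), so the full
five-landmark ordering by sample means is reproduced only in a fraction of
cohorts; rank stability of closely spaced landmarks requires far larger
samples than the original study design contemplates. Other numerical
choices: quadratic fits center and scale the abscissa before `polyfit`;
template calibration starts from a closed-form consistent-subset solution
and polishes with bounded trust-region least squares (tolerances 1e-15);
class boundaries at DP% = 43 and 57 belong to oval; the side classifier's
default tolerance is 0 (any deviation from 1 counts), configurable.
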