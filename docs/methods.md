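# Methods

## The model

The analysis treats each region of interest (ROI) of the emotional-control
loop — prefrontal cortex, striatum, hippocampus and thalamus, bilaterally —
as a time-activity curve (TAC): the per-frame SUVmax (hottest voxel, Bq/cc)
sampled at 11 time points, 15 minutes apart, 0–150 min after ¹⁸F-FDG
injection (dose = body weight in kg × 0.1 mCi).  Because cerebellar FDG
uptake is comparatively stable, each curve is standardized frame by frame by
the ipsilateral cerebellum's SUVmax before metrics are computed.  A curve is
summarized by three endpoint metrics: the peak, the mean uptake rate before
the peak `(peak − value at 0) / t_peak`, and the mean metabolic (washout)
rate after it `(peak − value at 150) / (150 − t_peak)`, both in SUV/min.
Peak ties resolve to the earliest frame; a peak at the first (last) frame
has pre-peak (post-peak) rate 0, so the metrics are total.

Groups are compared per ROI × metric with the pooled-variance two-sample t
from summaries (mean, SD, n), `df = n₁ + n₂ − 2`, two-sided p, α = 0.05.
Pooled rather than Welch variance is the default because it is the variant
that reproduces the published t-values exactly from the published summaries
(verified arithmetically in the tests); Welch and Bonferroni/BH corrections
are available but off by default, matching the source analysis.

## Synthetic data: what it emulates and what it does not

No raw patient data are deposited for this study, so every experiment runs
on synthetic inputs generated in-package:

* **Cohorts.** For each subject and ROI the three metrics are drawn
  independently from normal distributions with the published group means and
  SDs (n = 20 per group in the study; experiments may use any n).  The
  metrics are reported as separate summaries in the source tables, so no
  joint structure between them is imposed.  Curve endpoints are then derived
  by inverting the rate formulas at a nominal peak time.
* **Peak time.** The study never reports peak times; 60 min is used as the
  fixed default (configurable).  It only anchors curve rendering — the
  summary statistics depend on the drawn metrics, not on this choice.
* **Volumes.** The TAC shape is piecewise linear (rise to the peak, fall to
  the end value): the simplest curve for which the endpoint rate formulas
  are exact rather than approximate, which is what makes the round-trip
  tests meaningful at 1e-9.  One designated voxel per ROI carries the exact
  TAC; other ROI voxels carry a strictly lower fraction of it, so
  max-extraction is exact; the cerebellum is painted constant over time.
  Gaussian voxel noise is optional and never touches the designated voxel.
* **Scenes.** The saliency and segmentation stages are exercised on
  figure/ground color scenes (a disc of one color on a field of another,
  optional pixel noise) whose ground-truth mask is known exactly.

What passing tests therefore show: the formulas, the optimization and the
statistics behave as specified on data whose ground truth is known.  What
they do not show: robustness to real-PET effects — partial volume, scatter,
motion, anatomical variability, non-Gaussian between-subject structure —
none of which the phantom models.

### A unit inconsistency in the published summaries

The published pre/post-peak rates (≈0.05–0.45 Bq/(cc·min)) are arithmetically
incompatible with the published peaks (≈1.2–2.5) under the per-minute rate
formulas on a 150-min window: e.g. a pre-peak rate of 0.34 SUV/min over even
15 minutes exceeds the 2.41 peak, implying a negative start value.  (The
printed numbers are mutually consistent if "peak time" is counted in 15-min
frames.)  The package keeps the formulas exactly as published (per minute)
and handles the consequence explicitly: when inverting table-level rates
into curve endpoints, negative derived SUVs are clipped to 0 with a warning
(or raise, per configuration).  Group statistics are computed on the drawn
metric values themselves, which reproduce the published distributions
exactly; only rendered curves are affected by clipping.  The pipeline
exposes both routes (`metrics_source="rendered" | "sampled"`).

## Saliency

Blocks are n × n pixels (default 8), described by their mean LAB color and
diagonal-normalized center position.  Dissimilarity is
`D = d_color / (1 + c·d_position)` with c = 3 by default; single-scale
saliency averages D over the K = 64 most similar blocks
(`S = 1 − exp(−mean D)`), maps from the scale set {100%, 50%, 25%} are
averaged, and the context correction multiplies by `1 − d_foci`, where
d_foci is the Euclidean distance to the nearest attended
(above-threshold, default 0.8) pixel divided by the image diagonal.  The
correction can only decrease saliency, and attended pixels are unchanged.
Choices made where the model description is ambiguous: the reference set is
the K most *similar* blocks (a spatial K-nearest variant is selectable);
with fewer than K candidates all are used and the mean divides by the
actual count; if no pixel reaches the threshold the global maximum is
attended (logged).  c, n, K, the scale set and the threshold are not
published values; all are configurable.

## GrabCut

Energy `E(a, k, θ, z) = U + V` with per-class K = 5 full-covariance color
GMMs (each pixel scored by its best component) and the contrast-adaptive
boundary term over the 8-connected (default) neighborhood.
β defaults to `1 / (2⟨‖z_m − z_n‖²⟩)` over neighbor pairs — the standard
realization of "inversely proportional to image contrast"; γ defaults to 50
(no published value).  Each iteration assigns components, refits them by
moments (weights nₖ/N, sample means, sample covariances + 1e-6·I for
stability on flat regions), and solves an exact s–t min-cut
(Boykov–Kolmogorov via networkx) for the labeling, so the energy trace is
non-increasing; a step that would not lower the energy terminates the loop
(this also absorbs the vanishingly small non-monotonicity the covariance
regularizer could introduce).  Convergence: relative energy change < 1e-3
or 10 iterations.  Pixels outside the user rectangle are hard background,
enforced with uncuttable terminal links.  Boundary smoothing is
morphological opening + closing with a disc, with the structuring radius
backed off until the foreground area changes by at most 5%.

## Fusion

The "generalized" IHS space is realized as a fixed linear transform whose
intensity row is the channel mean and whose two chroma rows are orthogonal
to the gray diagonal (hue/saturation are the polar form of the chroma
pair); it is exactly invertible and gray pixels have zero saturation.  The
multiscale stage is an à-trous (starlet) pyramid — B3-spline smoothing with
dilated kernels, detail = difference of successive smoothings — chosen
because it is shift-invariant, works at any image size and reconstructs
perfectly by a plain sum, which the tests assert at 1e-6.  It is a
deliberate simplification of a nonsubsampled contourlet decomposition,
whose filter banks and direction counts are not published; the fusion rule
(PET low band, max-absolute detail) is unaffected by that substitution.
Registration is out of scope: inputs are generated co-registered.

## Numerical and design choices

* Seeds: one global seed is fanned out to per-stage 31-bit child seeds via
  `numpy` seed sequences; every generator is deterministic under its seed.
* The ROI-level "altered" call used in pattern summaries is a majority rule
  (≥ 2 of 3 metrics significant).  At large simulated n the tiny published
  right-side post-peak differences (≈0.01) become individually significant,
  so a per-cell rule cannot express "no obvious change in the right striatum
  / hippocampus"; the majority rule states that reading precisely and
  reproduces it at n = 200 per group.
* Two published cells (right hippocampus and right thalamus post-peak rate)
  print t = 2.1 where the printed means ± SDs give 2.0.  The discrepancy is
  recorded, not repaired: the reproduction count is 22 of 24 and the tests
  pin the two exceptions.  At df = 38, t = 2.0 is just below the 0.05
  threshold, consistent with the published non-significant calls.
* Repeated SUVmax measurement ("measured 3 times and averaged") is realized
  as repeated extraction under optional random ROI-voxel dropout (jitter);
  with zero jitter all repeats are identical, and extraction short-circuits
  to a single measurement.
* Rates are computed on cerebellum-normalized curves by default (the study
  standardizes before recording); raw-curve metrics are available by flag.
* Problem sizes in the test and acceptance runs — 24³–32³ voxel grids,
  24–64 px scenes, n = 200 per simulated group, 100 round-trip draws — were
  chosen to exercise every code path at desk scale; all are parameters, and
  nothing in the implementation depends on them.

## Known limitations

* No PET physics (attenuation, scatter, partial volume) and no anatomical
  atlas; the label map is a geometric stand-in.
* No kinetic modelling (Patlak/Logan): only the endpoint rates the study
  defines.
* The saliency model omits high-level (e.g. face) cues; the fusion stage is
  2D and assumes co-registration; GrabCut has no interactive brush editing
  or border matting.
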